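"""Shared fixtures: published aggregate tables and a survey reconstructed
from them.

The respondent-level survey behind the published tables is unavailable, so
``published_like_raw`` rebuilds a synthetic stand-in whose *per-variable*
high/low cross-tabulations match the published counts exactly: within each
outcome group every variable's levels are laid out by count (columns are
filled independently, so joint distributions are arbitrary — marginal
cross-tabs are all that downstream screening consumes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from logistic_ism import datasets
from logistic_ism.survey import RawDataset, code_dataset

#: Raw Likert score rendering a high (4) / low (2) outcome in the rebuild.
_HIGH_SCORE, _LOW_SCORE = 4, 2
#: Raw skill scores rendering coded good (4) / bad (2) levels.
_SKILL_SCORE = {"good": 4, "bad": 2}


@pytest.fixture(scope="session")
def published_tables():
    return datasets.effectiveness_crosstabs()


@pytest.fixture(scope="session")
def codebook():
    return datasets.default_codebook()


@pytest.fixture(scope="session")
def published_like_raw(published_tables, codebook) -> RawDataset:
    """Synthetic survey whose every variable cross-tab equals the published one."""
    n_high, n_low = datasets.N_HIGH, datasets.N_LOW
    frame = {
        codebook.outcome_name: np.concatenate(
            [np.full(n_high, _HIGH_SCORE), np.full(n_low, _LOW_SCORE)]
        )
    }
    for spec in codebook.variables:
        table = published_tables[spec.name]
        cells = []
        for col, total in ((0, n_high), (1, n_low)):
            counts = table.counts[:, col]
            assert counts.sum() == total
            values = np.repeat(list(table.row_labels), counts)
            if spec.kind == "likert-5":
                values = np.array([_SKILL_SCORE[v] for v in values])
            cells.append(values)
        frame[spec.name] = np.concatenate(cells)
    return RawDataset(table=pd.DataFrame(frame))


@pytest.fixture(scope="session")
def published_like_coded(published_like_raw, codebook):
    return code_dataset(published_like_raw, codebook)


@pytest.fixture(scope="session")
def expert_matrix():
    return datasets.expert_adjacency()
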