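"""Survey variable definitions, outcome dichotomization, and cross-tabulation.

The analysis starts from a respondent-level table of categorical answers plus
a single 5-point Likert rating of overall emergency-drill effectiveness.  A
:class:`Codebook` declares every variable's levels and which level is the
*adverse* one (coded 1 in the regression, expected to worsen ratings).  The
Likert outcome is mean-split into low (1) / high (0) effectiveness, skill
items rated 1-5 are collapsed to bad/good, and each coded variable can then
be cross-tabulated against the binary outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VARIABLE_KINDS = ("binary", "ordered-categorical", "likert-5")

#: Likert scores collapsed to the "bad" skill category.
BAD_SCORES = (1, 2, 3)
#: Likert scores collapsed to the "good" skill category.
GOOD_SCORES = (4, 5)


class CodingError(ValueError):
    """A record or variable cannot be coded under the codebook."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one explanatory variable.

    Parameters
    ----------
    name
        Column name in the respondent table.
    kind
        ``"binary"``, ``"ordered-categorical"`` or ``"likert-5"``.  Likert
        variables hold raw 1-5 scores that are collapsed to the two levels
        given in ``levels`` (bad, good order).
    levels
        Ordered level labels; this order fixes contingency-table rows.
    adverse_level
        Level coded 1 in the regression design (the exposure expected to
        worsen effectiveness ratings).
    reference_level
        Level coded 0.
    """

    name: str
    kind: str
    levels: tuple[str, ...]
    adverse_level: str
    reference_level: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if not self.levels:
            raise ValueError(f"{self.name}: levels must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate levels")
        if self.adverse_level not in self.levels:
            raise ValueError(f"{self.name}: adverse level not among levels")
        if self.reference_level not in self.levels:
            raise ValueError(f"{self.name}: reference level not among levels")
        if self.adverse_level == self.reference_level:
            raise ValueError(f"{self.name}: adverse and reference levels coincide")
        if self.kind == "likert-5" and len(self.levels) != 2:
            # raw scores are 1-5 but coded levels are the bad/good pair
            raise ValueError(f"{self.name}: likert-5 variables code to exactly 2 levels")

    @property
    def is_binary_coded(self) -> bool:
        return len(self.levels) == 2


@dataclass(frozen=True)
class Codebook:
    """All variable declarations plus the outcome split threshold."""

    outcome_name: str
    variables: tuple[VariableSpec, ...]
    outcome_threshold: float = 3.16

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.outcome_name in names:
            raise ValueError("outcome name collides with a variable name")
        if not 1.0 <= self.outcome_threshold <= 5.0:
            raise ValueError("outcome threshold must lie in [1, 5]")

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "outcome_threshold": self.outcome_threshold,
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "levels": list(v.levels),
                    "adverse_level": v.adverse_level,
                    "reference_level": v.reference_level,
                }
                for v in self.variables
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        return cls(
            outcome_name=d["outcome_name"],
            variables=tuple(
                VariableSpec(
                    name=v["name"],
                    kind=v["kind"],
                    levels=tuple(v["levels"]),
                    adverse_level=v["adverse_level"],
                    reference_level=v["reference_level"],
                )
                for v in d["variables"]
            ),
            outcome_threshold=float(d.get("outcome_threshold", 3.16)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        """Load from a YAML (or JSON, a YAML subset) codebook file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class RawDataset:
    """Respondent-level table; outcome column holds integer scores 1-5."""

    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class CodedDataset:
    """Analysis-ready data: binary outcome plus categorical predictor labels.

    ``outcome`` is 1 for low effectiveness and 0 for high effectiveness;
    ``predictors`` holds level labels (codebook order fixes their ordering).
    """

    outcome: np.ndarray
    predictors: pd.DataFrame
    codebook: Codebook
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return int(self.outcome.size)

    @property
    def n_low(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_high(self) -> int:
        return self.n - self.n_low


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 cross-tabulation of one predictor against high/low effectiveness.

    Columns are (high, low); rows follow the codebook's level order.
    """

    variable: str
    row_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be r x 2")
        if counts.shape[0] != len(self.row_labels):
            raise ValueError("row_labels length must match counts rows")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def dichotomize_outcome(score: int, threshold: float = 3.16) -> int:
    """Split a 1-5 effectiveness score at ``threshold``.

    Returns 1 (low effectiveness) when ``score <= threshold`` and
    0 (high effectiveness) when ``score > threshold``.  With the survey's
    mean threshold of 3.16 this puts scores 1-3 in the low group and 4-5 in
    the high group.
    """
    score = int(score)
    if not 1 <= score <= 5:
        raise ValueError(f"score must be in 1..5, got {score}")
    return 1 if score <= threshold else 0


def recode_skill(score: int) -> str:
    """Collapse a 1-5 skill self-rating to 'bad' (1-3) or 'good' (4-5)."""
    score = int(score)
    if not 1 <= score <= 5:
        raise ValueError(f"score must be in 1..5, got {score}")
    return "bad" if score in BAD_SCORES else "good"


def _code_column(raw: pd.Series, spec: VariableSpec) -> pd.Series:
    if spec.kind == "likert-5":
        scores = pd.to_numeric(raw, errors="raise").astype(int)
        if ((scores < 1) | (scores > 5)).any():
            raise CodingError(f"{spec.name}: scores outside 1..5")
        coded = scores.map(lambda s: recode_skill(s))
    else:
        coded = raw.astype(str)
        bad = set(coded.unique()) - set(spec.levels)
        if bad:
            raise CodingError(f"{spec.name}: unknown levels {sorted(bad)}")
    return coded


def code_dataset(
    raw: RawDataset, codebook: Codebook, on_missing: str = "drop"
) -> CodedDataset:
    """Code a raw respondent table into an analysis-ready dataset.

    The outcome score is dichotomized at the codebook threshold, 1-5 skill
    items are collapsed to bad/good, and remaining variables are validated
    against their declared levels.

    Records with missing entries are excluded whole (the survey's own
    exclusion rule for incomplete questionnaires), with the dropped count
    logged and recorded on the result; with ``on_missing="raise"`` the first
    incomplete record raises :class:`CodingError` naming the variables.
    """
    if on_missing not in ("drop", "raise"):
        raise ValueError("on_missing must be 'drop' or 'raise'")
    needed = [codebook.outcome_name] + codebook.variable_names
    missing_cols = [c for c in needed if c not in raw.table.columns]
    if missing_cols:
        raise CodingError(f"dataset lacks columns {missing_cols}")
    table = raw.table[needed]

    incomplete = table.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        if on_missing == "raise":
            first = table.index[incomplete][0]
            vars_missing = list(table.columns[table.loc[first].isna()])
            raise CodingError(f"record {first} missing {vars_missing}")
        logger.info("excluding %d incomplete records", n_dropped)
        table = table[~incomplete]

    if len(table) == 0:
        return CodedDataset(
            outcome=np.zeros(0, dtype=np.int8),
            predictors=pd.DataFrame(columns=codebook.variable_names),
            codebook=codebook,
            n_dropped=n_dropped,
        )

    scores = pd.to_numeric(table[codebook.outcome_name], errors="raise").astype(int)
    if ((scores < 1) | (scores > 5)).any():
        raise CodingError(f"{codebook.outcome_name}: scores outside 1..5")
    outcome = (scores <= codebook.outcome_threshold).to_numpy(dtype=np.int8)

    coded = {
        spec.name: _code_column(table[spec.name], spec) for spec in codebook.variables
    }
    predictors = pd.DataFrame(coded, index=table.index).reset_index(drop=True)
    return CodedDataset(
        outcome=outcome, predictors=predictors, codebook=codebook, n_dropped=n_dropped
    )


def crosstab(coded: CodedDataset, variable: str) -> ContingencyTable:
    """Cross-tabulate one coded predictor against the binary outcome.

    Rows follow the codebook's level order; columns are (high, low).
    """
    spec = coded.codebook[variable]
    column = coded.predictors[variable]
    counts = np.zeros((len(spec.levels), 2), dtype=int)
    for i, level in enumerate(spec.levels):
        at_level = (column == level).to_numpy()
        counts[i, 1] = int((at_level & (coded.outcome == 1)).sum())
        counts[i, 0] = int(at_level.sum()) - counts[i, 1]
    return ContingencyTable(variable=variable, row_labels=spec.levels, counts=counts)


def low_effectiveness_rate(coded: CodedDataset) -> float:
    """Percentage of respondents rating effectiveness low (score <= threshold)."""
    if coded.n == 0:
        raise ValueError("rate undefined for an empty dataset")
    return 100.0 * coded.n_low / coded.n
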