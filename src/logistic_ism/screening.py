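"""Pearson chi-square screening of coded predictors against the outcome.

Each variable's r x 2 contingency table is tested for independence with the
uncorrected Pearson statistic (no Yates continuity correction — the published
statistics only reproduce without it); variables with p below the
significance threshold pass the screen into the logistic model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .survey import CodedDataset, ContingencyTable, crosstab

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A contingency table has an empty row or column margin."""


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test of one variable vs the binary outcome.

    For a degenerate table (empty margin) ``error`` carries the reason and
    the numeric fields are None.
    """

    variable: str
    statistic: float | None
    df: int | None
    p_value: float | None
    significant: bool
    error: str | None = None


@dataclass(frozen=True)
class ScreeningReport:
    results: tuple[ChiSquareResult, ...]
    alpha: float

    @property
    def selected(self) -> list[str]:
        """Variables significant at ``alpha``, in codebook order."""
        return [r.variable for r in self.results if r.significant]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "selected": self.selected,
                "results": [
                    {
                        "variable": r.variable,
                        "statistic": r.statistic,
                        "df": r.df,
                        "p_value": r.p_value,
                        "significant": r.significant,
                        "error": r.error,
                    }
                    for r in self.results
                ],
            },
            indent=indent,
        )


def pearson_chi_square(table: ContingencyTable, alpha: float = 0.05) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test on an r x 2 table.

    The statistic is sum((O-E)^2/E) with E the product-margin expectation;
    df = r - 1.  Raises :class:`DegenerateTableError`, naming the empty
    level or outcome column, when any margin is zero.  Small expected counts
    (any E < 5) are logged but do not switch to an exact test.
    """
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any():
        empty = [table.row_labels[i] for i in np.flatnonzero(row_sums == 0)]
        raise DegenerateTableError(f"{table.variable}: empty level(s) {empty}")
    if (col_sums == 0).any():
        side = "high" if col_sums[0] == 0 else "low"
        raise DegenerateTableError(f"{table.variable}: no {side}-effectiveness respondents")
    if counts.shape[0] < 2:
        raise DegenerateTableError(f"{table.variable}: only one observed level")

    expected = np.outer(row_sums, col_sums) / counts.sum()
    if (expected < 5).any():
        logger.warning(
            "%s: %d expected counts below 5", table.variable, int((expected < 5).sum())
        )
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        variable=table.variable,
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        significant=bool(p < alpha),
    )


def screen_variables(coded: CodedDataset, alpha: float = 0.05) -> ScreeningReport:
    """Chi-square test every codebook variable; select those with p < alpha.

    Degenerate variables (e.g. a constant predictor) are reported with their
    error message and excluded from selection without aborting the rest.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    results = []
    for name in coded.codebook.variable_names:
        table = crosstab(coded, name)
        # drop levels nobody chose so a sparse sample does not abort the test
        observed = table.counts.sum(axis=1) > 0
        if observed.any() and not observed.all():
            table = ContingencyTable(
                variable=name,
                row_labels=tuple(
                    lab for lab, keep in zip(table.row_labels, observed) if keep
                ),
                counts=table.counts[observed],
            )
        try:
            results.append(pearson_chi_square(table, alpha=alpha))
        except DegenerateTableError as exc:
            logger.warning("screening: %s", exc)
            results.append(
                ChiSquareResult(
                    variable=name,
                    statistic=None,
                    df=None,
                    p_value=None,
                    significant=False,
                    error=str(exc),
                )
            )
    return ScreeningReport(results=tuple(results), alpha=alpha)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the published tables."""
    factor = 10.0**decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


def render_screening_table(
    report: ScreeningReport, tables: dict[str, ContingencyTable] | None = None
) -> str:
    """Plain-text screening table (counts, percentages, chi-square, p)."""
    lines = [
        f"{'Variable':<28}{'Level':<26}{'High n (%)':>14}{'Low n (%)':>14}"
        f"{'Chi2':>8}{'P':>8}"
    ]
    for r in report.results:
        if r.error is not None:
            lines.append(f"{r.variable:<28}{'-- degenerate: ' + r.error}")
            continue
        stat = f"{round_half_up(r.statistic, 1):.1f}"
        p = f"{r.p_value:.3f}"
        if tables and r.variable in tables:
            t = tables[r.variable]
            col = t.counts.sum(axis=0)
            for i, lab in enumerate(t.row_labels):
                hi, lo = t.counts[i]
                cell_h = f"{hi} ({100 * hi / col[0]:.1f})" if col[0] else f"{hi}"
                cell_l = f"{lo} ({100 * lo / col[1]:.1f})" if col[1] else f"{lo}"
                head = r.variable if i == 0 else ""
                tail = f"{stat:>8}{p:>8}" if i == 0 else ""
                lines.append(f"{head:<28}{lab:<26}{cell_h:>14}{cell_l:>14}{tail}")
        else:
            lines.append(f"{r.variable:<28}{'':<26}{'':>14}{'':>14}{stat:>8}{p:>8}")
    return "\n".join(lines) + "\n"
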