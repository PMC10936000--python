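"""Binary logistic regression of low effectiveness on screened predictors.

The event is a *low* effectiveness rating (outcome 1) and every predictor is
an adverse-level indicator, so odds ratios above 1 read "raises the risk of
a low rating".  Fitting is Newton-Raphson on the Bernoulli log-likelihood
(equivalently iteratively reweighted least squares) with step-halving, and
the coefficient covariance is the inverse observed information at the
optimum.  A grouped Hosmer-Lemeshow statistic over deciles of fitted
probability provides the goodness-of-fit check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .survey import CodedDataset

logger = logging.getLogger(__name__)

#: Normal quantile used for 95% Wald intervals.
Z_95 = 1.959964

MAX_ITER = 50
TOL = 1e-8


class SeparationError(RuntimeError):
    """The likelihood has no finite maximum (perfect separation)."""


class CollinearityError(RuntimeError):
    """The design matrix is rank-deficient."""


@dataclass(frozen=True)
class DesignMatrix:
    """Intercept column plus one adverse-level indicator per predictor."""

    X: np.ndarray
    columns: tuple[str, ...]
    adverse_levels: tuple[str | None, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int
    columns: tuple[str, ...]
    fitted: np.ndarray
    outcome: np.ndarray


@dataclass(frozen=True)
class EffectRow:
    predictor: str
    coefficient: float
    se: float
    wald: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class EffectTable:
    rows: tuple[EffectRow, ...]

    def __getitem__(self, predictor: str) -> EffectRow:
        for row in self.rows:
            if row.predictor == predictor:
                return row
        raise KeyError(predictor)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            [
                {
                    "predictor": r.predictor,
                    "coefficient": r.coefficient,
                    "se": r.se,
                    "wald": r.wald,
                    "p_value": r.p_value,
                    "odds_ratio": r.odds_ratio,
                    "ci_95": [r.ci_low, r.ci_high],
                }
                for r in self.rows
            ],
            indent=indent,
        )


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    groups: int


def build_design(coded: CodedDataset, selected: list[str]) -> DesignMatrix:
    """Design matrix: intercept plus adverse-level indicators for ``selected``.

    Every selected variable must be binary-coded; its column is 1 exactly
    where the respondent sits at the codebook's adverse level.
    """
    n = coded.n
    cols = [np.ones(n)]
    names: list[str] = ["intercept"]
    adverse: list[str | None] = [None]
    for name in selected:
        spec = coded.codebook[name]
        if not spec.is_binary_coded:
            raise ValueError(
                f"{name}: only binary-coded variables enter the design "
                f"(has {len(spec.levels)} levels)"
            )
        cols.append(
            (coded.predictors[name] == spec.adverse_level).to_numpy(dtype=float)
        )
        names.append(name)
        adverse.append(spec.adverse_level)
    return DesignMatrix(
        X=np.column_stack(cols), columns=tuple(names), adverse_levels=tuple(adverse)
    )


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design: DesignMatrix, outcome: np.ndarray) -> LogisticFit:
    """Maximum-likelihood fit by Newton-Raphson with step-halving.

    Starts from the zero vector with the intercept at the empirical logit;
    converges when the largest absolute score entry or coefficient change
    drops below 1e-8, within 50 iterations.  Raises
    :class:`CollinearityError` for a rank-deficient design and
    :class:`SeparationError` when coefficients diverge (perfect separation).
    """
    X = design.X
    y = np.asarray(outcome, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("outcome is constant")

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the dependent columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        dep = [design.columns[j] for j in range(k) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise CollinearityError(f"design is rank {rank} < {k}; dependent: {dep}")

    beta = np.zeros(k)
    beta[0] = np.log(ybar / (1 - ybar))
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(eta)
        w = p * (1 - p)
        score = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular during iteration; "
                "likely perfect separation"
            ) from exc
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            eta_trial = X @ trial
            ll_trial = _log_likelihood(eta_trial, y)
            if ll_trial >= ll - 1e-12:
                break
            scale /= 2.0
        delta = scale * step
        beta = beta + delta
        eta = X @ beta
        ll = _log_likelihood(eta, y)
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "coefficients diverging (|beta| > 30); perfect separation"
            )
        # either criterion suffices: a vanishing score is the optimum, and a
        # vanishing accepted step means the likelihood can no longer improve
        # at floating-point resolution
        if np.max(np.abs(score)) < TOL or np.max(np.abs(delta)) < TOL:
            converged = True
            break

    p = expit(eta)
    w = p * (1 - p)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if not converged:
        logger.warning("fit did not converge in %d iterations", MAX_ITER)
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        iterations=it,
        columns=design.columns,
        fitted=p,
        outcome=y.astype(np.int8),
    )


def effect_table(fit: LogisticFit) -> EffectTable:
    """Wald statistics, p-values, odds ratios and 95% CIs per predictor.

    The intercept is excluded; Wald = (beta/SE)^2 referred to chi-square(1),
    CI = exp(beta +/- 1.959964 * SE).
    """
    if not fit.converged:
        raise RuntimeError(
            f"fit not converged after {fit.iterations} iterations; refusing effects"
        )
    rows = []
    for j, name in enumerate(fit.columns):
        if name == "intercept":
            continue
        b = float(fit.coefficients[j])
        s = float(fit.standard_errors[j])
        wald = (b / s) ** 2
        rows.append(
            EffectRow(
                predictor=name,
                coefficient=b,
                se=s,
                wald=wald,
                p_value=float(chi2.sf(wald, 1)),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - Z_95 * s)),
                ci_high=float(np.exp(b + Z_95 * s)),
            )
        )
    return EffectTable(rows=tuple(rows))


def goodness_of_fit(fit: LogisticFit, groups: int = 10) -> GofResult:
    """Hosmer-Lemeshow grouped calibration test.

    Respondents are binned into ``groups`` quantile groups of fitted
    probability (ties stay within one group, so bins can collapse; df is
    reduced accordingly).  The statistic sums (O - E)^2 / (E (1 - pbar))
    over groups, with df = groups - 2.
    """
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if not fit.converged:
        raise RuntimeError("fit not converged; refusing goodness-of-fit")
    p = fit.fitted
    y = fit.outcome
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
    if len(edges) - 1 < groups:
        logger.warning(
            "fitted probabilities support only %d distinct groups (%d requested)",
            len(edges) - 1,
            groups,
        )
    n_groups = len(edges) - 1
    if n_groups < 3:
        raise ValueError("fewer than 3 distinct probability groups; test undefined")
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_groups - 1)
    stat = 0.0
    for g in range(n_groups):
        mask = idx == g
        ng = int(mask.sum())
        if ng == 0:
            continue
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        pbar = exp / ng
        denom = exp * (1 - pbar)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    df = n_groups - 2
    return GofResult(
        statistic=float(stat), df=df, p_value=float(chi2.sf(stat, df)), groups=n_groups
    )


def select_significant(effects: EffectTable, alpha: float = 0.05) -> list[str]:
    """Predictors with Wald p < alpha, ordered by descending odds ratio."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    hits = [r for r in effects.rows if r.p_value < alpha]
    hits.sort(key=lambda r: -r.odds_ratio)
    return [r.predictor for r in hits]


def render_effect_table(effects: EffectTable) -> str:
    """Plain-text effect table (Wald, P, OR, 95% CI)."""
    lines = [f"{'Predictor':<26}{'Wald':>9}{'P':>9}{'OR':>8}{'95% CI':>16}"]
    for r in effects.rows:
        p = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
        lines.append(
            f"{r.predictor:<26}{r.wald:>9.3f}{p:>9}{r.odds_ratio:>8.3f}"
            f"{r.ci_low:>8.3f}{r.ci_high:>8.3f}"
        )
    return "\n".join(lines) + "\n"
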