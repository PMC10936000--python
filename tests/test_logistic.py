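"""Logistic regression: closed-form oracles, recovery, Wald effects, HL fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from logistic_ism.logistic import (
    CollinearityError,
    DesignMatrix,
    EffectRow,
    EffectTable,
    LogisticFit,
    SeparationError,
    build_design,
    effect_table,
    fit_logistic,
    goodness_of_fit,
    render_effect_table,
    select_significant,
)
from logistic_ism import datasets
from logistic_ism.survey import code_dataset
from logistic_ism.synthetic import effects_only_scenario, simulate_responses, true_parameters


def _single_predictor_design(x: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        X=np.column_stack([np.ones(x.size), x]),
        columns=("intercept", "x"),
        adverse_levels=(None, "yes"),
    )


def _fit_scenario(n: int, seed: int, drop: str | None = None):
    config = effects_only_scenario(n=n, seed=seed)
    raw = simulate_responses(config)
    coded = code_dataset(raw, config.codebook)
    predictors = [v for v in coded.codebook.variable_names if v != drop]
    design = build_design(coded, predictors)
    return config, coded, fit_logistic(design, coded.outcome)


class TestBuildDesign:
    def test_adverse_indicator(self, published_like_coded):
        design = build_design(published_like_coded, ["equipment_guarantee"])
        col = design.X[:, 1]
        manual = (
            published_like_coded.predictors["equipment_guarantee"] == "no"
        ).to_numpy()
        assert np.array_equal(col.astype(bool), manual)

    def test_empty_selection_gives_intercept_only(self, published_like_coded):
        design = build_design(published_like_coded, [])
        assert design.X.shape == (published_like_coded.n, 1)
        assert design.columns == ("intercept",)
        assert (design.X == 1).all()

    def test_shape_contract(self, published_like_coded):
        design = build_design(
            published_like_coded, ["gender", "education", "fund_guarantee"]
        )
        assert design.X.shape == (published_like_coded.n, 4)
        assert set(np.unique(design.X[:, 1:])) <= {0.0, 1.0}

    def test_multilevel_variable_rejected(self, published_like_coded):
        with pytest.raises(ValueError, match="age_group"):
            build_design(published_like_coded, ["age_group"])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(500) < 0.3).astype(float)
        design = DesignMatrix(
            X=np.ones((500, 1)), columns=("intercept",), adverse_levels=(None,)
        )
        fit = fit_logistic(design, y)
        r = y.mean()
        assert fit.coefficients[0] == pytest.approx(np.log(r / (1 - r)), abs=1e-8)

    def test_2x2_cross_product_oracle(self):
        """Saturated single-predictor fits equal the cross-product OR."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            a, b, c, d = rng.integers(5, 120, size=4)
            # x=1 rows: a events, b non-events; x=0 rows: c events, d non-events
            x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
            y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
            fit = fit_logistic(_single_predictor_design(x), y)
            fitted_or = np.exp(fit.coefficients[1])
            assert fitted_or == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_score_vanishes_at_optimum(self):
        _, coded, fit = _fit_scenario(5000, seed=2)
        design = build_design(coded, list(coded.codebook.variable_names))
        from scipy.special import expit

        score = design.X.T @ (coded.outcome - expit(design.X @ fit.coefficients))
        assert np.max(np.abs(score)) < 1e-6
        assert fit.converged

    def test_matches_statsmodels(self):
        """Independent cross-check of coefficients and standard errors."""
        sm = pytest.importorskip("statsmodels.api")
        _, coded, fit = _fit_scenario(5000, seed=3)
        design = build_design(coded, list(coded.codebook.variable_names))
        ref = sm.Logit(np.asarray(coded.outcome, float), design.X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_covariance_psd_and_se_consistent(self):
        _, _, fit = _fit_scenario(3000, seed=4)
        eigvals = np.linalg.eigvalsh(fit.covariance)
        assert (eigvals > 0).all()
        np.testing.assert_allclose(
            fit.standard_errors, np.sqrt(np.diag(fit.covariance)), rtol=1e-12
        )

    def test_recovery_error_shrinks_with_n(self):
        """Mean absolute coefficient error decreases across n = 2k, 20k, 200k."""
        sizes = (2_000, 20_000, 200_000)
        n_seeds = 20
        errors = {n: [] for n in sizes}
        for n in sizes:
            for seed in range(n_seeds):
                config, coded, fit = _fit_scenario(n, seed=1000 + seed)
                truth = true_parameters(config)
                design_cols = fit.columns[1:]
                err = np.mean(
                    [
                        abs(fit.coefficients[i + 1] - truth.coefficients[v])
                        for i, v in enumerate(design_cols)
                    ]
                )
                errors[n].append(err)
        means = [np.mean(errors[n]) for n in sizes]
        assert means[0] > means[1] > means[2]

    def test_separation_detected(self):
        x = np.concatenate([np.ones(50), np.zeros(50)])
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(_single_predictor_design(x), y)

    def test_collinearity_detected(self):
        rng = np.random.default_rng(9)
        x = (rng.random(200) < 0.5).astype(float)
        y = (rng.random(200) < 0.5).astype(float)
        design = DesignMatrix(
            X=np.column_stack([np.ones(200), x, x]),
            columns=("intercept", "x1", "x2"),
            adverse_levels=(None, "a", "a"),
        )
        with pytest.raises(CollinearityError):
            fit_logistic(design, y)

    def test_constant_outcome_rejected(self):
        design = DesignMatrix(
            X=np.ones((50, 1)), columns=("intercept",), adverse_levels=(None,)
        )
        with pytest.raises(ValueError):
            fit_logistic(design, np.ones(50))


def _manual_fit(coef, se, columns=("intercept", "x")):
    k = len(coef)
    return LogisticFit(
        coefficients=np.asarray(coef, float),
        standard_errors=np.asarray(se, float),
        covariance=np.diag(np.asarray(se, float) ** 2),
        log_likelihood=0.0,
        converged=True,
        iterations=1,
        columns=columns,
        fitted=np.array([0.5]),
        outcome=np.array([1], dtype=np.int8),
    )


class TestEffectTable:
    def test_equipment_like_row(self):
        """beta 0.8433, SE 0.1070 give OR 2.32 with CI (1.88, 2.87)."""
        effects = effect_table(_manual_fit([0.0, 0.8433], [1.0, 0.1070]))
        row = effects["x"]
        assert row.odds_ratio == pytest.approx(2.324, abs=0.005)
        assert row.ci_low == pytest.approx(1.884, abs=0.005)
        assert row.ci_high == pytest.approx(2.867, abs=0.005)

    def test_null_effect(self):
        row = effect_table(_manual_fit([0.0, 0.0], [1.0, 0.2]))["x"]
        assert row.odds_ratio == 1.0
        assert row.ci_low * row.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_wald_two_sigma(self):
        row = effect_table(_manual_fit([0.0, 0.4], [1.0, 0.2]))["x"]
        assert row.wald == pytest.approx(4.0, rel=1e-12)
        assert row.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_nonconverged_fit_refused(self):
        fit = _manual_fit([0.0, 1.0], [1.0, 0.5])
        from dataclasses import replace

        with pytest.raises(RuntimeError, match="not converged"):
            effect_table(replace(fit, converged=False))

    def test_intercept_excluded(self):
        effects = effect_table(_manual_fit([0.3, 1.0], [0.1, 0.5]))
        assert [r.predictor for r in effects.rows] == ["x"]

    def test_render(self):
        text = render_effect_table(effect_table(_manual_fit([0.0, 0.8433], [1.0, 0.107])))
        assert "OR" in text and "2.324" in text


class TestGoodnessOfFit:
    def test_df_contract(self):
        _, _, fit = _fit_scenario(2000, seed=6)
        gof = goodness_of_fit(fit, groups=3)
        assert gof.df == gof.groups - 2

    def test_calibrated_model_passes(self):
        """Under a correctly specified model the HL test rarely rejects."""
        n_reps, passed = 100, 0
        for seed in range(n_reps):
            _, _, fit = _fit_scenario(50_000, seed=5000 + seed)
            if goodness_of_fit(fit).p_value > 0.05:
                passed += 1
        assert passed >= 90

    def test_miscalibrated_model_fails(self):
        """A main-effects fit to data with a strong omitted interaction is
        detected in the majority of replicates.

        (Omitting an *independent* covariate is not detectable here: the
        refitted logistic re-calibrates the deciles almost perfectly, so the
        miscalibration must distort the link itself.)
        """
        from scipy.special import expit

        rejected = 0
        n_reps = 20
        for seed in range(n_reps):
            config = effects_only_scenario(n=50_000, seed=7000 + seed)
            raw = simulate_responses(config)
            coded = code_dataset(raw, config.codebook)
            design = build_design(coded, list(coded.codebook.variable_names))
            beta_true = np.zeros(design.X.shape[1])
            beta_true[0] = config.intercept
            for i, name in enumerate(design.columns):
                if name != "intercept":
                    beta_true[i] = config.effects.get(
                        (name, design.adverse_levels[i]), 0.0
                    )
            j_eq = design.columns.index("equipment_guarantee")
            j_tq = design.columns.index("training_quality")
            eta = (
                design.X @ beta_true
                + 1.2 * design.X[:, j_eq] * design.X[:, j_tq]
                - 0.6 * design.X[:, j_eq]
            )
            rng = np.random.default_rng(8000 + seed)
            y = (rng.random(eta.size) < expit(eta)).astype(float)
            fit = fit_logistic(design, y)
            if goodness_of_fit(fit).p_value < 0.05:
                rejected += 1
        assert rejected > n_reps / 2

    def test_too_few_groups_rejected(self):
        _, _, fit = _fit_scenario(2000, seed=8)
        with pytest.raises(ValueError):
            goodness_of_fit(fit, groups=2)


class TestSelectSignificant:
    @staticmethod
    def _published_effect_table() -> EffectTable:
        rows = []
        for var, row in datasets.REPORTED_EFFECTS.items():
            beta = np.log(row["or"])
            se = beta / np.sqrt(row["wald"])
            wald = (beta / se) ** 2
            rows.append(
                EffectRow(
                    predictor=var,
                    coefficient=beta,
                    se=se,
                    wald=wald,
                    p_value=float(chi2.sf(wald, 1)),
                    odds_ratio=row["or"],
                    ci_low=row["lo"],
                    ci_high=row["hi"],
                )
            )
        return EffectTable(rows=tuple(rows))

    def test_published_effects_select_seven_equipment_first(self):
        selected = select_significant(self._published_effect_table(), alpha=0.05)
        assert len(selected) == 7
        assert selected[0] == "equipment_guarantee"
        assert selected == sorted(
            selected, key=lambda v: -datasets.REPORTED_EFFECTS[v]["or"]
        )

    def test_all_null_gives_empty(self):
        effects = EffectTable(
            rows=(
                EffectRow("x", 0.0, 1.0, 0.0, 0.5, 1.0, 0.5, 2.0),
                EffectRow("y", 0.0, 1.0, 0.0, 0.5, 1.0, 0.5, 2.0),
            )
        )
        assert select_significant(effects, alpha=0.05) == []

    def test_alpha_one_selects_all(self):
        effects = self._published_effect_table()
        assert len(select_significant(effects, alpha=1.0)) == 7
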