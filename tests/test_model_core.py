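import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import crabias as cb
from crabias.model_core import (
    CohortSchemaError,
    ConfigurationError,
    OutcomeModelSpec,
    bmi_category,
    build_design,
    complete_record_indicator,
    fit_logistic,
)


def _two_by_two(a, b, c, d):
    """Rows for a 2x2 table: a/b exposed cases/controls, c/d unexposed."""
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    return X, y


class TestExpit:
    def test_known_values(self):
        assert cb.expit(0.0) == 0.5
        # direct evaluation of exp(-1) / (1 + exp(-1))
        assert cb.expit(-1.0) == pytest.approx(math.exp(-1) / (1 + math.exp(-1)),
                                               abs=1e-12)
        assert cb.expit(-1.0) == pytest.approx(0.268941, abs=1e-6)

    def test_symmetry_and_overflow_safety(self):
        assert cb.expit(3.7) + cb.expit(-3.7) == pytest.approx(1.0, abs=1e-15)
        assert cb.expit(1000.0) == 1.0
        assert cb.expit(-1000.0) == 0.0


class TestAgeBasis:
    def test_hinge_values(self):
        np.testing.assert_allclose(cb.age_basis(25.0), [[25, 0, 0, 0, 0]][0])
        np.testing.assert_allclose(cb.age_basis(45.0), [45, 15, 5, 0, 0])

    def test_continuity_at_knots(self):
        for k in (30.0, 40.0, 50.0, 60.0):
            left = cb.age_basis(k - 1e-9)
            right = cb.age_basis(k + 1e-9)
            np.testing.assert_allclose(left, right, atol=1e-8)

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ConfigurationError):
            cb.age_basis(40.0, knots=(30, 30, 50))


class TestDesign:
    def test_reference_coding_and_bmi_categories(self):
        spec = OutcomeModelSpec()
        df = pd.DataFrame({
            "id": [0, 1, 2], "y": [0, 1, 0], "x": [0, 1, 2],
            "age": [25.0, 45.0, 55.0], "sex": [1, 0, 1],
            "smoking": [0, 1, 2], "bmi": [22.0, 19.0, 31.0],
            "route": [0, 2, 3],
        })
        dm = build_design(df, spec)
        cols = dict(zip(dm.names, dm.X.T))
        np.testing.assert_array_equal(cols["x_1"], [0, 1, 0])
        np.testing.assert_array_equal(cols["x_2"], [0, 0, 1])
        # bmi 22 -> category 1 of 4 given cutpoints 20/25/30 (left-closed bins)
        np.testing.assert_array_equal(cols["bmi_1"], [1, 0, 0])
        np.testing.assert_array_equal(cols["bmi_3"], [0, 0, 1])
        assert bmi_category(20.0) == 1 and bmi_category(19.999) == 0

    def test_incomplete_rows_dropped_with_count(self):
        spec = OutcomeModelSpec()
        df = pd.DataFrame({
            "id": [0, 1, 2], "y": [0, 1, 0], "x": [0, 1, np.nan],
            "age": [25.0, 45.0, 50.0], "sex": [1, 0, 1],
            "smoking": [0, 1, 2], "bmi": [22.0, np.nan, 27.0],
            "route": [0, 2, 3],
        })
        dm = build_design(df, spec)
        assert dm.n_dropped == 2
        assert dm.X.shape[0] == 1

    def test_unseen_category_names_column(self):
        spec = OutcomeModelSpec()
        df = pd.DataFrame({
            "id": [7], "y": [0], "x": [5], "age": [40.0], "sex": [1],
            "smoking": [0], "bmi": [24.0], "route": [1],
        })
        with pytest.raises(CohortSchemaError, match="'x'.*5"):
            build_design(df, spec)


class TestFitLogistic:
    def test_matches_2x2_closed_form(self, rng):
        """ML fit on a saturated 2x2 table equals log(ad/bc) with the
        classical variance 1/a + 1/b + 1/c + 1/d."""
        for _ in range(50):
            a, b, c, d = rng.integers(5, 80, size=4)
            X, y = _two_by_two(a, b, c, d)
            fit = fit_logistic(X, y, names=["intercept", "x"])
            assert fit.converged
            expected = math.log(a * d / (b * c))
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.params["x"] == pytest.approx(expected, abs=1e-8)
            assert fit.bse["x"] == pytest.approx(se, abs=1e-8)

    def test_no_events_flags_degenerate(self):
        X, y = _two_by_two(0, 30, 0, 30)
        y[:] = 0.0
        fit = fit_logistic(X[:, :1], y)
        assert not fit.ok and fit.separated

    def test_duplicating_rows_halves_information(self, rng):
        a, b, c, d = 12, 20, 9, 30
        X, y = _two_by_two(a, b, c, d)
        fit1 = fit_logistic(X, y)
        fit2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)
        np.testing.assert_allclose(fit2.bse, fit1.bse / math.sqrt(2), atol=1e-8)

    def test_rank_deficiency_raises(self):
        X = np.ones((40, 2))  # duplicated intercept
        y = np.tile([0.0, 1.0], 20)
        with pytest.raises(ConfigurationError, match="rank"):
            fit_logistic(X, y)

    def test_agrees_with_statsmodels(self, preset, preset_cohort):
        sm = pytest.importorskip("statsmodels.api")
        dm = build_design(preset_cohort, preset.outcome)
        fit = fit_logistic(dm.X, dm.y, names=dm.names)
        ref = sm.GLM(dm.y, dm.X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-5)


class TestParameterRecovery:
    def test_recovers_generating_coefficients(self, preset):
        """At n = 10^5 every coefficient is recovered within 4 model SEs."""
        cfg = dataclasses.replace(preset, n=100_000)
        cohort = cb.generate_cohort(cfg, 5)
        fit = cb.fit_outcome_model(cohort, cfg.outcome)
        assert fit.ok
        truth = cfg.outcome.coefficients()
        z = (fit.params - truth) / fit.bse
        assert np.abs(z).max() < 4.0

    def test_row_order_invariance(self, preset, preset_cohort, rng):
        sub = preset_cohort.iloc[:4000]
        perm = sub.iloc[rng.permutation(len(sub))].reset_index(drop=True)
        f1 = cb.fit_outcome_model(sub, preset.outcome)
        f2 = cb.fit_outcome_model(perm, preset.outcome)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-8)


class TestCompleteRecordIndicator:
    def test_matches_brute_force_scan(self, rng):
        n = 500
        df = pd.DataFrame({
            "id": np.arange(n), "y": rng.integers(0, 2, n).astype(float),
            "x": rng.integers(0, 3, n).astype(float),
            "age": rng.uniform(20, 60, n), "sex": rng.integers(0, 2, n).astype(float),
            "smoking": rng.integers(0, 3, n).astype(float),
            "bmi": rng.uniform(18, 35, n), "route": rng.integers(0, 4, n).astype(float),
        })
        for col in ("y", "x", "bmi", "age"):
            df.loc[rng.random(n) < 0.1, col] = np.nan
        variables = ["y", "x", "age", "bmi"]
        r = complete_record_indicator(df, variables)
        brute = np.array([int(all(not pd.isna(df.iloc[i][v]) for v in variables))
                          for i in range(n)])
        np.testing.assert_array_equal(r, brute)
        assert r.sum() == n - df[variables].isna().any(axis=1).sum()

    def test_all_observed_and_single_missing(self):
        df = pd.DataFrame({"id": [0, 1], "y": [0.0, 1.0], "x": [1.0, 2.0],
                           "age": [30.0, 40.0], "sex": [1.0, 0.0],
                           "smoking": [0.0, 1.0], "bmi": [24.0, np.nan],
                           "route": [1.0, 2.0]})
        np.testing.assert_array_equal(
            complete_record_indicator(df, ["y", "x", "age"]), [1, 1])
        np.testing.assert_array_equal(
            complete_record_indicator(df, ["y", "x", "age", "bmi"]), [1, 0])

    def test_unknown_variable_errors(self):
        df = pd.DataFrame({"id": [0], "y": [0.0]})
        with pytest.raises(CohortSchemaError):
            complete_record_indicator(df, ["nope"])
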