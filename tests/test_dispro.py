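"""Crude and adjusted reporting odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvonset as pv
from pvonset.dispro import Z95, TwoByTwo, crude_ror, effects_from_fit, fit_logistic


def hand_ror(a, b, c, d):
    """Independent arithmetic oracle for the 2x2 formula."""
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)


class TestCrudeRor:
    def test_balanced_table_is_null(self):
        e = crude_ror(TwoByTwo(10, 10, 10, 10))
        assert e.or_value == pytest.approx(1.0)
        assert e.ci_low * e.ci_high == pytest.approx(1.0)  # symmetric about 1

    def test_matches_hand_computation(self):
        e = crude_ror(TwoByTwo(10, 90, 5, 95))
        or_, lo, hi = hand_ror(10, 90, 5, 95)
        assert (e.or_value, e.ci_low, e.ci_high) == pytest.approx((or_, lo, hi))

    def test_zero_cell_with_correction(self):
        e = crude_ror(TwoByTwo(0, 10, 10, 10), correction=True)
        or_, lo, hi = hand_ror(0.5, 10.5, 10.5, 10.5)
        assert (e.or_value, e.ci_low, e.ci_high) == pytest.approx((or_, lo, hi))
        assert e.defined

    def test_zero_cell_without_correction_is_flagged(self):
        e = crude_ror(TwoByTwo(0, 10, 10, 10), correction=False)
        assert not e.defined and math.isnan(e.or_value)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 1, 1, 1)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = np.ones((100, 1))
        fit = fit_logistic(y, X)
        assert fit.converged
        assert fit.params[0] == pytest.approx(math.log(30 / 70), abs=1e-9)

    def test_single_covariate_equals_crude_or(self):
        a, b, c, d = 12, 88, 7, 143
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        X = np.c_[np.ones(a + b + c + d), np.r_[np.ones(a + b), np.zeros(c + d)]]
        fit = fit_logistic(y, X)
        expected = crude_ror(TwoByTwo(a, b, c, d), correction=False).or_value
        assert math.exp(fit.params[1]) == pytest.approx(expected, rel=1e-12)

    def test_rank_deficiency_names_columns(self):
        X = np.c_[np.ones(50), np.arange(50), 2 * np.arange(50)]
        y = (np.arange(50) > 25).astype(float)
        with pytest.raises(pv.DesignMatrixError) as exc:
            fit_logistic(y, X, column_names=["intercept", "x", "x_copy"])
        assert exc.value.columns  # at least one collinear column named

    def test_separation_reported_not_hidden(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = (x > 0).astype(float)  # perfectly separated
        X = np.c_[np.ones(60), x]
        with pytest.warns(UserWarning):
            fit = fit_logistic(y, X)
        assert not fit.converged

    def test_row_permutation_invariance(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        X = np.c_[np.ones(300), rng.normal(size=(300, 2))]
        fit1 = fit_logistic(y, X)
        perm = rng.permutation(300)
        fit2 = fit_logistic(y[perm], X[perm])
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)

    def test_recovers_planted_effects_on_large_cohort(self):
        """Full 14-column model on a synthetic cohort recovers the truth."""
        cfg = pv.recovery_config(seed=17)
        rows, b_true, coding = pv.simulate_cohort(cfg, n=50_000)
        y, X, _ = pv.dummy_code(rows)
        fit = fit_logistic(y, X, column_names=list(coding.column_names))
        se = fit.se()
        # every estimate within 4 standard errors of its planted value
        assert np.all(np.abs(fit.params - b_true) < 4 * se)
        # the strong dose effect is estimated to ~10%
        j = coding.column_names.index("cloz_high")
        assert math.exp(fit.params[j]) == pytest.approx(9.81, rel=0.10)


class TestEffects:
    def test_null_coefficient(self):
        fit = pv.LogisticFit(
            params=np.array([0.3, 0.0]),
            cov=np.diag([0.01, 0.01]),
            loglik=-10.0, converged=True, n_iter=3, grad_norm=0.0,
            column_names=["intercept", "x"], n=100,
        )
        coding = pv.Coding(column_names=("intercept", "x"), labels=("x: yes vs no",))
        (e,) = effects_from_fit(fit, coding)
        assert e.or_value == pytest.approx(1.0)
        assert e.ci_low == pytest.approx(math.exp(-Z95 * 0.1))
        assert e.p == pytest.approx(1.0)

    def test_vanishing_se_collapses_ci(self):
        fit = pv.LogisticFit(
            params=np.array([0.0, math.log(2)]),
            cov=np.diag([0.01, 1e-18]),
            loglik=-10.0, converged=True, n_iter=3, grad_norm=0.0,
            column_names=["intercept", "x"], n=100,
        )
        coding = pv.Coding(column_names=("intercept", "x"), labels=("x",))
        (e,) = effects_from_fit(fit, coding)
        assert e.ci_low == pytest.approx(2.0, rel=1e-6)
        assert e.ci_high == pytest.approx(2.0, rel=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        b=st.floats(-3, 3, allow_nan=False),
        se=st.floats(0.01, 2.0, allow_nan=False),
    )
    def test_p_below_05_iff_ci_excludes_one(self, b, se):
        """Wald p-value and Wald CI must agree about significance."""
        fit = pv.LogisticFit(
            params=np.array([0.0, b]),
            cov=np.diag([0.01, se**2]),
            loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
            column_names=["intercept", "x"], n=10,
        )
        coding = pv.Coding(column_names=("intercept", "x"), labels=("x",))
        (e,) = effects_from_fit(fit, coding)
        excludes_one = e.ci_low > 1.0 or e.ci_high < 1.0
        assert (e.p < 0.05) == excludes_one


class TestDummyCode:
    def _row(self, **kw):
        base = dict(
            case_id="X", outcome_seizure=False, sex=pv.Sex.MALE,
            age_cat=pv.AgeCat.LE29, cloz_dose_cat=pv.DoseCat.LOW,
            polypharmacy=False, lithium_cat=pv.LithiumCat.NONE,
            fluvoxamine=False, antiepileptic=False, convulsive_history=False,
        )
        base.update(kw)
        return pv.CohortRow(**base)

    def test_reference_row_is_all_zero(self):
        y, X, coding = pv.dummy_code([self._row()])
        assert X.shape == (1, 14)
        assert X[0, 0] == 1.0 and np.all(X[0, 1:] == 0.0)
        assert y[0] == 0.0

    def test_medium_dose_dummy_vector(self):
        _, X, coding = pv.dummy_code([self._row(cloz_dose_cat=pv.DoseCat.MEDIUM)])
        j_med = coding.column_names.index("cloz_medium")
        j_high = coding.column_names.index("cloz_high")
        assert (X[0, j_med], X[0, j_high]) == (1.0, 0.0)

    def test_column_count_and_sex_reference_flip(self):
        rows = [self._row(), self._row(sex=pv.Sex.FEMALE, outcome_seizure=True)]
        y, X, coding = pv.dummy_code(rows, sex_reference=pv.Sex.FEMALE)
        assert len(coding.column_names) == 14
        assert coding.column_names[1] == "sex_male"
        assert X[0, 1] == 1.0 and X[1, 1] == 0.0
        assert list(y) == [0.0, 1.0]
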