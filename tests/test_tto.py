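"""Time-to-onset: day computation, summaries, Weibull fit, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvonset as pv
from pvonset.tto import FailureType, OnsetSample

from .conftest import make_case


def _sample(days, window=1095):
    days = np.asarray(days, dtype=float)
    return OnsetSample(
        case_ids=[f"c{i}" for i in range(len(days))],
        days=days,
        n_excluded_missing_dates=0,
        n_excluded_beyond_window=0,
        window_days=window,
    )


def _onset_case(case_id, start, onset):
    return make_case(
        case_id=case_id,
        drugs=[("clozapine", "suspected", 300.0, start)],
        reactions=[("Seizure", onset)],
    )


class TestOnsetDays:
    def _run(self, cases, terms, **kw):
        flags = {c.case_id: pv.flag_case(c, terms) for c in cases}
        return pv.onset_days(cases, flags, **kw)

    def test_same_day_onset_is_day_one(self, terms):
        s = self._run([_onset_case("A", (2020, 1, 1), (2020, 1, 1))], terms)
        assert list(s.days) == [1.0]

    def test_beyond_window_excluded(self, terms):
        s = self._run([_onset_case("A", (2020, 1, 1), (2023, 6, 1))], terms)
        assert s.n == 0 and s.n_excluded_beyond_window == 1

    def test_partial_onset_date_counts_as_missing(self, terms):
        s = self._run([_onset_case("A", (2020, 1, 1), (2020, 3))], terms)
        assert s.n == 0 and s.n_excluded_missing_dates == 1

    def test_onset_before_start_is_data_error(self, terms):
        s = self._run([_onset_case("A", (2020, 5, 1), (2020, 3, 1))], terms)
        assert s.n == 0 and s.n_excluded_missing_dates == 1

    def test_earliest_complete_start_used(self, terms):
        case = make_case(
            case_id="A",
            drugs=[
                ("clozapine", "suspected", 300.0, (2020, 2, 1)),
                ("clozapine", "concomitant", None, (2020, 1, 1)),
            ],
            reactions=[("Seizure", (2020, 1, 10))],
        )
        s = self._run([case], terms)
        assert list(s.days) == [10.0]

    def test_half_day_convention(self, terms):
        s = self._run(
            [_onset_case("A", (2020, 1, 1), (2020, 1, 1))], terms,
            convention="half_day",
        )
        assert list(s.days) == [0.5]


class TestSummaries:
    def test_median_of_five(self):
        s = pv.summarize(_sample([1, 2, 3, 4, 5]))
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)

    def test_proportion_within(self):
        days = [100.0] * 182 + [400.0] * 40
        assert pv.proportion_within(_sample(days), 365) == pytest.approx(182 / 222)

    def test_exponential_median_recovered(self, rng):
        days = pv.simulate_onset_sample(10_000, 200.0, 1.0, rng, round_up=False)
        s = pv.summarize(_sample(days, window=10**9))
        assert s.median == pytest.approx(200.0 * math.log(2), rel=0.05)


class TestFitWeibull:
    def test_exponential_data_gives_shape_one(self):
        rng = np.random.default_rng(42)
        days = rng.exponential(100.0, size=10_000)
        fit = pv.fit_weibull(days)
        assert 0.97 < fit.beta < 1.03
        assert fit.alpha == pytest.approx(100.0, rel=0.05)
        assert fit.failure_type is FailureType.RANDOM

    def test_matches_scipy_mle(self, rng):
        """Independent cross-check against scipy's Weibull MLE."""
        from scipy import stats

        days = rng.weibull(1.4, 300) * 80.0
        fit = pv.fit_weibull(days)
        c, _, scale = stats.weibull_min.fit(days, floc=0)
        assert fit.beta == pytest.approx(c, rel=1e-4)
        assert fit.alpha == pytest.approx(scale, rel=1e-4)

    def test_scale_equivariance(self):
        days = np.array([3.0, 17.0, 44.0, 95.0, 260.0, 700.0])
        f1 = pv.fit_weibull(days)
        f2 = pv.fit_weibull(days * 10.0)
        assert f2.alpha == pytest.approx(10.0 * f1.alpha, rel=1e-8)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-8)

    def test_ci_bounds_bracket_estimate(self):
        fit = pv.fit_weibull([5.0, 30.0, 100.0, 200.0, 400.0])
        assert fit.beta_ci[0] <= fit.beta <= fit.beta_ci[1]
        assert fit.alpha_ci[0] <= fit.alpha <= fit.alpha_ci[1]
        assert fit.beta_ci[0] > 0

    def test_too_few_or_degenerate_rejected(self):
        with pytest.raises(pv.FitError):
            pv.fit_weibull([5.0, 10.0])
        with pytest.raises(pv.FitError):
            pv.fit_weibull([7.0, 7.0, 7.0])
        with pytest.raises(pv.FitError):
            pv.fit_weibull([1.0, 0.0, 5.0])


class TestClassifyFailure:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.9, 1.1), FailureType.RANDOM),
            ((1.05, 1.4), FailureType.WEAROUT),
            ((0.6, 0.95), FailureType.EARLY),
            ((1.0, 1.3), FailureType.RANDOM),  # boundary: CI includes 1
            ((0.7, 1.0), FailureType.RANDOM),
        ],
    )
    def test_trichotomy_examples(self, ci, expected):
        assert pv.classify_failure(ci) is expected

    @settings(derandomize=True, max_examples=300)
    @given(
        low=st.floats(0.01, 5.0, allow_nan=False),
        spread=st.floats(0.0, 5.0, allow_nan=False),
    )
    def test_trichotomy_exhaustive_and_exclusive(self, low, spread):
        """Every valid CI gets exactly one label, consistent with the rule."""
        high = low + spread
        label = pv.classify_failure((low, high))
        if low > 1.0:
            assert label is FailureType.WEAROUT
        elif high < 1.0:
            assert label is FailureType.EARLY
        else:
            assert label is FailureType.RANDOM

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError):
            pv.classify_failure((1.2, 0.8))
        with pytest.raises(ValueError):
            pv.classify_failure((0.0, 1.0))


class TestHistogram:
    def test_small_example(self):
        edges, counts = pv.histogram(_sample([10, 20, 40], window=60), 30)
        assert list(counts) == [2, 1]
        assert list(edges) == [0.0, 30.0, 60.0]

    def test_empty_tail_bins_retained(self):
        edges, counts = pv.histogram(_sample([10.0]), 30)
        assert len(counts) == math.ceil(1095 / 30)
        assert counts.sum() == 1

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10**6), width=st.sampled_from([7.0, 30.0, 90.0]))
    def test_counts_conserved(self, seed, width):
        r = np.random.default_rng(seed)
        days = np.ceil(r.uniform(0.01, 1095, size=r.integers(1, 200)))
        _, counts = pv.histogram(_sample(days), width)
        assert counts.sum() == len(days)
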