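"""Iterative baseline estimation and run-length phase calling."""

import statistics

import numpy as np
import pytest
from hypothesis import given, strategies as st

from catcycle import (
    ContractError,
    DegenerateWindowError,
    HormoneSeries,
    InsufficientDataError,
    amh_threshold_compliance,
    call_phases,
    fit_baseline,
    phase_frequency,
)
from catcycle.baseline_phase import BaselineFit
from catcycle.io_model import ExclusionInterval


def brute_force_baseline(values, k=1.5, mode="sd_above_mean"):
    """Independent reference: recompute the full exclusion sequence with the
    statistics module (pure-Python, no shared code with the implementation)."""
    retained = list(values)
    iters = 0
    while True:
        iters += 1
        m = statistics.fmean(retained)
        sd = statistics.stdev(retained) if len(retained) > 1 else 0.0
        thr = m + k * sd if mode == "sd_above_mean" else k * m
        kept = [v for v in retained if not v > thr]
        if len(kept) == len(retained):
            return m, sd, thr, len(retained), iters
        retained = kept


def series_of(values, analyte="E2_fecal", animal="a1"):
    days = np.arange(len(values)) * 2
    return HormoneSeries(animal, analyte, days, np.asarray(values, float), "ng/g")


def fit_of(values, k=1.5, mode="sd_above_mean", **kw):
    s = series_of(values, **kw)
    return fit_baseline(s, (int(s.days[0]), int(s.days[-1]) + 1), k, mode)


class TestFitBaseline:
    def test_constant_series_converges_in_one_iteration(self):
        fit = fit_of([2, 2, 2, 2])
        assert fit.baseline_mean == 2.0
        assert fit.baseline_sd == 0.0
        assert fit.n_retained == 4
        assert fit.n_iterations == 1

    def test_single_outlier_excluded_by_hand_iteration(self):
        # iteration 1: mean 4.4, sample SD sqrt(28.8), threshold ~ 12.45 -> drops 14
        # iteration 2 over [2,2,2,2]: nothing above mean 2 -> converged
        fit = fit_of([2, 2, 2, 2, 14], k=1.5)
        assert fit.n_iterations == 2
        assert fit.baseline_mean == 2.0
        assert fit.baseline_sd == 0.0
        assert fit.n_retained == 4
        assert fit.threshold == 2.0
        assert list(fit.retained_mask) == [True] * 4 + [False]

    def test_huge_k_retains_everything(self):
        fit = fit_of([2, 2, 2, 2, 14], k=100)
        assert fit.n_retained == 5
        assert fit.baseline_mean == pytest.approx(4.4)
        assert fit.n_iterations == 1

    def test_requires_three_samples_in_window(self):
        with pytest.raises(InsufficientDataError):
            fit_of([1.0, 2.0])

    def test_window_restricts_input(self):
        s = series_of([5, 5, 5, 50, 50, 50])
        fit = fit_baseline(s, (0, 5), 1.5)  # days 0,2,4 only
        assert fit.n_input == 3
        assert fit.baseline_mean == 5.0

    def test_order_of_samples_is_irrelevant(self, rng):
        vals = rng.lognormal(0, 0.5, 10)
        f1 = fit_of(vals)
        f2 = fit_of(vals[::-1])
        assert f1.baseline_mean == pytest.approx(f2.baseline_mean)
        assert f1.threshold == pytest.approx(f2.threshold)
        assert f1.n_retained == f2.n_retained

    @given(
        st.lists(st.sampled_from([1.0, 2.0, 5.0, 20.0]), min_size=3, max_size=12),
        st.sampled_from(["sd_above_mean", "fold_of_mean"]),
    )
    def test_matches_brute_force_oracle(self, values, mode):
        m, sd, thr, n_ret, iters = brute_force_baseline(values, 1.5, mode)
        fit = fit_of(values, 1.5, mode)
        assert fit.baseline_mean == pytest.approx(m)
        assert fit.baseline_sd == pytest.approx(sd)
        assert fit.threshold == pytest.approx(thr)
        assert fit.n_retained == n_ret
        assert fit.n_iterations == iters

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=20))
    def test_termination_and_converged_invariants(self, values):
        fit = fit_of(values)
        assert fit.n_iterations <= fit.n_input
        assert fit.n_retained >= 1
        retained = np.asarray(values)[fit.retained_mask]
        assert not np.any(retained > fit.threshold)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=20))
    def test_idempotent_on_retained_points(self, values):
        fit = fit_of(values)
        retained = list(np.asarray(values)[fit.retained_mask])
        if len(retained) < 3:
            return
        refit = fit_of(retained)
        assert refit.n_iterations == 1
        assert refit.baseline_mean == pytest.approx(fit.baseline_mean)
        assert refit.baseline_sd == pytest.approx(fit.baseline_sd)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=20))
    def test_first_iteration_exclusion_shrinks_with_k(self, values):
        v = np.asarray(values)
        m, sd = v.mean(), v.std(ddof=1)
        small = set(np.flatnonzero(v > m + 1.0 * sd))
        large = set(np.flatnonzero(v > m + 2.0 * sd))
        assert large <= small


class TestCallPhases:
    def make_fit(self, threshold, analyte="E2_fecal", animal="a1"):
        return BaselineFit(
            animal_id=animal, analyte=analyte, baseline_mean=threshold / 1.5,
            baseline_sd=0.0, k=1.5, mode="fold_of_mean", threshold=threshold,
            n_input=4, n_retained=4, n_iterations=1,
            retained_mask=np.ones(4, bool),
        )

    def test_hand_enumerated_run(self):
        s = series_of([2, 4, 4, 2, 4, 2])
        calls = call_phases(s, self.make_fit(3.5), "estrous", 2)
        assert len(calls) == 1
        (c,) = calls
        assert (c.start_day, c.end_day, c.n_samples) == (2, 4, 2)
        assert c.peak_value == 4.0

    def test_all_baseline_yields_no_calls(self):
        s = series_of([2, 2, 2, 2])
        assert call_phases(s, self.make_fit(3.5), "estrous", 2) == []

    def test_min_run_threshold(self):
        s = series_of([9, 9, 9, 9, 9])
        assert call_phases(s, self.make_fit(3.5), "luteal", 6) == []
        calls = call_phases(s, self.make_fit(3.5), "luteal", 2)
        assert len(calls) == 1 and calls[0].n_samples == 5

    def test_ties_with_threshold_count_as_baseline(self):
        s = series_of([3.5, 3.5, 4.0, 4.0])
        calls = call_phases(s, self.make_fit(3.5), "estrous", 2)
        assert len(calls) == 1 and calls[0].n_samples == 2

    def test_runs_do_not_span_exclusions(self):
        # elevated days 0..10; exclusion [4, 6) removes day 4 and splits the run
        s = series_of([9, 9, 9, 9, 9, 9])  # days 0,2,4,6,8,10
        ex = [ExclusionInterval(4, 6, "pregnancy")]
        calls = call_phases(s, self.make_fit(3.5), "estrous", 2, ex)
        assert [(c.start_day, c.end_day) for c in calls] == [(0, 2), (6, 10)]

    def test_mismatched_fit_rejected(self):
        s = series_of([1, 2, 3])
        with pytest.raises(ContractError):
            call_phases(s, self.make_fit(3.5, animal="other"), "estrous", 2)

    @given(
        st.lists(st.floats(0.0, 10.0), min_size=1, max_size=40),
        st.integers(1, 4),
    )
    def test_calls_are_maximal_and_disjoint(self, values, min_run):
        s = series_of(values)
        fit = self.make_fit(5.0)
        calls = call_phases(s, fit, "estrous", min_run)
        days = list(s.days)
        for c in calls:
            assert c.n_samples >= min_run
            i, j = days.index(c.start_day), days.index(c.end_day)
            assert all(v > 5.0 for v in s.values[i : j + 1])
            if i > 0:
                assert not s.values[i - 1] > 5.0  # maximal to the left
            if j < len(days) - 1:
                assert not s.values[j + 1] > 5.0  # maximal to the right
        for a, b in zip(calls, calls[1:]):
            assert a.end_day < b.start_day  # disjoint and ordered


class TestPhaseFrequency:
    def call(self, start, phase="luteal"):
        from catcycle.baseline_phase import PhaseCall

        return PhaseCall("a1", phase, start, start + 10, 6, 9.9)

    def test_direct_formula(self):
        calls = [self.call(d) for d in (0, 100, 200, 300)]
        pf = phase_frequency(calls, (0, 360), [], 180)
        assert pf.n_phases == 4
        assert pf.normalized == pytest.approx(2.0)

    def test_zero_calls(self):
        pf = phase_frequency([], (0, 360), [], 180, animal_id="a1", phase_type="luteal")
        assert pf.normalized == 0.0

    def test_exclusions_reduce_effective_days(self):
        calls = [self.call(d, "estrous") for d in (0, 30, 50)]
        ex = [ExclusionInterval(60, 90, "pregnancy")]
        pf = phase_frequency(calls, (0, 90), ex, 30)
        assert pf.effective_days == 60
        assert pf.normalized == pytest.approx(1.5)

    def test_counts_by_start_day_membership(self):
        inside, outside = self.call(359), self.call(360)
        pf = phase_frequency([inside, outside], (0, 360), [], 180)
        assert pf.n_phases == 1

    def test_fully_excluded_window_is_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            phase_frequency([], (0, 30), [ExclusionInterval(0, 30, "lactation")], 30)


class TestAmhCompliance:
    def amh(self, values, days=None):
        days = np.arange(len(values)) * 30 if days is None else np.asarray(days)
        return HormoneSeries("a1", "AMH_serum", days, values, "ug/ml")

    def test_all_above_target(self):
        frac, ok = amh_threshold_compliance(self.amh([0.5, 0.5, 0.5]), 0.25)
        assert (frac, ok) == (1.0, True)

    def test_partial_compliance(self):
        frac, ok = amh_threshold_compliance(self.amh([0.5, 0.2, 0.5]), 0.25)
        assert frac == pytest.approx(2 / 3)
        assert ok is False

    def test_pre_treatment_samples_ignored(self):
        s = self.amh([0.1, 0.5, 0.5], days=[-30, 10, 40])
        frac, ok = amh_threshold_compliance(s, 0.25)
        assert (frac, ok) == (1.0, True)

    def test_no_post_treatment_samples(self):
        s = self.amh([0.5, 0.5], days=[-60, -30])
        with pytest.raises(InsufficientDataError):
            amh_threshold_compliance(s, 0.25)

    def test_wrong_analyte_rejected(self):
        s = HormoneSeries("a1", "E2_fecal", [0, 1], [1.0, 1.0], "ng/g")
        with pytest.raises(ContractError):
            amh_threshold_compliance(s, 0.25)
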