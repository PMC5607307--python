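"""Person-time, rates, Wilson intervals, Kaplan–Meier and kernel hazard."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meshcohort import survival
from meshcohort.synthetic import PiecewiseHazard


class TestPersonYears:
    def test_one_year(self):
        assert survival.person_years([365.25]) == pytest.approx(1.0)

    def test_empty(self):
        assert survival.person_years([]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            survival.person_years([-1.0])


class TestCrudeIncidence:
    @pytest.mark.parametrize("events, py, expected", [
        (2950, 175284, 16.8),
        (4575, 286273, 16.0),
        (2476, 175284, 14.1),
        (0, 1000, 0.0),
    ])
    def test_rates(self, events, py, expected):
        assert survival.crude_incidence(events, py).rate_1dp == expected

    def test_scale_exact(self):
        r = survival.crude_incidence(123, 4567.8)
        assert r.rate * r.person_years / 1000 == pytest.approx(123, abs=1e-9)

    def test_zero_py_rejected(self):
        with pytest.raises(ValueError):
            survival.crude_incidence(1, 0.0)


class TestProportionCI:
    def test_periproc_unconfounded(self):
        pct, lo, hi = survival.proportion_ci(1618, 68002)
        assert (round(pct, 1), round(lo, 1), round(hi, 1)) == (2.4, 2.3, 2.5)

    def test_thirty_day_unconfounded(self):
        pct, lo, hi = survival.proportion_ci(1137, 68002)
        assert (round(pct, 1), round(lo, 1), round(hi, 1)) == (1.7, 1.6, 1.8)

    def test_zero_numerator(self):
        pct, lo, _ = survival.proportion_ci(0, 100)
        assert pct == 0.0 and lo == 0.0

    def test_bad_input(self):
        with pytest.raises(ValueError):
            survival.proportion_ci(5, 0)
        with pytest.raises(ValueError):
            survival.proportion_ci(7, 5)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times {1 event, 2 censored, 3 event}: S = 2/3 on [1,3), 0 at 3
        est = survival.km_fit([1, 2, 3], [True, False, True])
        assert est.survival_at(0.5)[0] == 1.0
        assert est.survival_at(1)[0] == pytest.approx(2 / 3)
        assert est.survival_at(2.9)[0] == pytest.approx(2 / 3)
        assert est.survival_at(3)[0] == 0.0

    def test_all_censored(self):
        with pytest.warns(UserWarning, match="no observed events"):
            est = survival.km_fit([5, 10], [False, False])
        s, lo, hi = est.survival_at(7)
        assert s == 1.0 and lo == 1.0 and hi == 1.0

    def test_greenwood_variance_hand_case(self):
        # single event among n=4 at t=2: Var = S^2 * d/(y(y-d)) = (3/4)^2/12
        est = survival.km_fit([2, 3, 4, 5], [True, False, False, False])
        i = np.searchsorted(est.times, 2)
        assert est.variance[i] == pytest.approx((0.75 ** 2) * (1 / 12))

    def test_ci_brackets_and_bounded(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(2.0, 300)
        c = rng.random(300) < 0.3
        est = survival.km_fit(t, ~c)
        assert (est.ci_lower <= est.survival + 1e-12).all()
        assert (est.ci_upper >= est.survival - 1e-12).all()
        assert (est.ci_lower >= 0).all() and (est.ci_upper <= 1).all()
        assert (np.diff(est.survival) <= 1e-12).all()   # non-increasing
        assert est.survival[0] == 1.0

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_equals_empirical_survival_without_censoring(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 50, 40)
        est = survival.km_fit(t, np.ones(40, bool))
        for q in (5, 15, 30):
            assert est.survival_at(q)[0] == pytest.approx(
                np.mean(t > q), abs=1e-12)

    def test_exponential_recovery(self):
        lam = 0.4
        rng = np.random.default_rng(11)
        t = rng.exponential(1 / lam, 10000)
        est = survival.km_fit(t * 365.25, np.ones(10000, bool))
        s1 = est.survival_at(365.25)[0]
        se = math.sqrt(math.exp(-lam) * (1 - math.exp(-lam)) / 10000)
        assert s1 == pytest.approx(math.exp(-lam), abs=3 * se)

    def test_beyond_last_time_warns(self):
        est = survival.km_fit([1, 2], [True, True])
        with pytest.warns(UserWarning, match="beyond"):
            est.survival_at(10)

    def test_free_at(self):
        est = survival.km_fit([365.25 * 6, 365.25 * 7], [False, False])
        pct, lo, hi = survival.km_free_at(est, 5.0)
        assert pct == 100.0


class TestKernelHazard:
    def test_no_events_zero(self):
        hz = survival.kernel_hazard([100, 200], [False, False])
        assert (hz.hazard == 0).all()

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            survival.kernel_hazard([1], [True], bandwidth_years=0)

    def test_constant_hazard_interior_recovery(self):
        lam = 0.016   # per person-year
        n = 20000
        rng = np.random.default_rng(3)
        t = rng.exponential(1 / lam, n)
        c = rng.uniform(0, 8, n)
        obs = t < c
        time = np.minimum(t, c) * 365.25
        hz = survival.kernel_hazard(time, obs, bandwidth_years=0.5,
                                    grid_years=np.array([2.0, 3.0, 4.0]))
        for v in hz.hazard:
            assert v == pytest.approx(16.0, rel=0.25)

    def test_decreasing_across_known_change_point(self):
        h = PiecewiseHazard((0.0, 2.0), (0.08, 0.01))
        rng = np.random.default_rng(9)
        t = h.sample(rng.random(20000))
        c = rng.uniform(0, 8, 20000)
        obs = t < c
        time = np.minimum(t, c) * 365.25
        hz = survival.kernel_hazard(time, obs, bandwidth_years=0.5,
                                    grid_years=np.array([1.0, 3.5]))
        assert hz.hazard[0] > 2 * hz.hazard[1]
        assert hz.hazard[0] == pytest.approx(80.0, rel=0.2)

    def test_integral_recovers_event_count_at_small_bandwidth(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(3.0, 2000)
        c = rng.uniform(0, 8, 2000)
        obs = t < c
        time_y = np.minimum(t, c)
        grid = np.linspace(0, time_y.max(), 4000)
        hz = survival.kernel_hazard(time_y * 365.25, obs,
                                    bandwidth_years=0.02, grid_years=grid)
        # ∫ h(t) Y(t) dt ≈ number of events as bandwidth -> 0
        y = np.array([(time_y >= g).sum() for g in grid])
        integral = np.trapezoid(hz.hazard / 1000 * y, grid)
        assert integral == pytest.approx(obs.sum(), rel=0.02)

    def test_interior_agrees_with_lifelines_smoothed_nelson_aalen(self):
        """Away from the boundaries the estimator matches lifelines'
        kernel-smoothed Nelson–Aalen hazard (independent implementation)."""
        from lifelines import NelsonAalenFitter

        rng = np.random.default_rng(2)
        n = 5000
        t = rng.exponential(5.0, n)
        c = rng.uniform(0, 8, n)
        obs = t < c
        time = np.minimum(t, c)
        naf = NelsonAalenFitter()
        naf.fit(time, obs)
        smoothed = naf.smoothed_hazard_(0.5)
        grid = np.array([2.0, 3.0, 4.0])
        hz = survival.kernel_hazard(time * 365.25, obs, bandwidth_years=0.5,
                                    grid_years=grid,
                                    boundary_correction=False)
        for g, mine in zip(grid, hz.hazard / 1000):
            theirs = smoothed.iloc[
                np.abs(smoothed.index.values - g).argmin(), 0]
            assert mine == pytest.approx(theirs, rel=1e-3)

    def test_per_interval_crude_rates_within_poisson_intervals(self):
        """Parameter recovery: per-interval crude rates fall inside the 95%
        Poisson interval of the configured hazard in ≥90% of replicates."""
        h = PiecewiseHazard((0.0, 2.0), (0.03, 0.01))
        rng = np.random.default_rng(100)
        hits = 0
        reps = 100
        for _ in range(reps):
            t = h.sample(rng.random(2000))
            c = rng.uniform(0, 8, 2000)
            time = np.minimum(t, c)
            ok = True
            for a, b, rate in ((0, 2, 0.03), (2, 8, 0.01)):
                py = np.clip(time - a, 0, b - a).sum()
                d = int(((t < c) & (t >= a) & (t < b)).sum())
                lo, hi = stats.poisson.interval(0.95, rate * py)
                ok &= lo <= d <= hi
            hits += ok
        assert hits >= 0.90 * reps
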