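import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplecens import (
    AnnouncementFunction,
    ParametricFamily,
    SampleData,
    SimulationSetting,
    estimate_A,
    estimate_probs,
    estimate_r,
    fit_nonparam,
    monotonize,
    plugin_F,
    simulate,
)
from triplecens.nonparam import announced_jumps, silverman_bandwidth


class TestEstimateProbs:
    def test_direct_counts(self, example1_sample):
        assert estimate_probs(example1_sample) == (0.5, 0.25)

    def test_all_served(self):
        data = SampleData(u=[1.0, 2.0], y=[0, 0], delta=[0, 0])
        assert estimate_probs(data) == (1.0, 0.0)

    def test_served_probability_matches_closed_form(self):
        s = SimulationSetting.setting1(n=100_000, seed=13, q=AnnouncementFunction.constant(0.5))
        sample = simulate(s)
        p1 = 8.0 / 9.0
        se = np.sqrt(p1 * (1 - p1) / s.n)
        assert abs(estimate_probs(sample)[0] - p1) < 3 * se


class TestEstimateA:
    def test_no_announced_events_gives_zero(self):
        data = SampleData(u=[1.0, 2.0, 3.0], y=[0, 0, 0], delta=[0, 1, 0])
        np.testing.assert_array_equal(estimate_A(data, [0.5, 1.5, 5.0]), 0.0)

    def test_hand_jump_sum(self):
        """Single announced event at the second-smallest time of four:
        risk set 3/4, so D̂ jumps by 1/3 and Â(t≥2) = 1 - e^{-1/3}."""
        sample = SampleData(u=[1.0, 2.0, 3.0, 4.0], y=[0, 1, 0, 0], delta=[0, 1, 0, 0])
        grid = np.array([0.0, 1.9, 2.0, 4.0, 10.0])
        a = estimate_A(sample, grid)
        np.testing.assert_allclose(a[:2], 0.0)
        np.testing.assert_allclose(a[2:], 1.0 - np.exp(-1.0 / 3.0), rtol=1e-12)

    def test_jumping_observation_in_own_risk_set(self):
        # lone subject announcing: risk set is itself, jump = 1/1
        data = SampleData(u=[2.0], y=[1], delta=[1])
        times, jumps = announced_jumps(data)
        assert times.tolist() == [2.0] and jumps.tolist() == [1.0]

    def test_ties_contribute_separate_jumps_at_common_risk_set(self):
        data = SampleData(u=[1.0, 2.0, 2.0, 3.0], y=[0, 1, 1, 0], delta=[0, 1, 1, 0])
        times, jumps = announced_jumps(data)
        np.testing.assert_allclose(jumps, [1.0 / 3.0, 1.0 / 3.0])

    def test_nelson_aalen_equivalence_when_all_announced(self):
        """With q ≡ 1, the jump-sum D̂ is exactly the Nelson–Aalen cumulative
        hazard of the failure time right-censored by the waiting time."""
        lifelines = pytest.importorskip("lifelines")
        s = SimulationSetting(
            ParametricFamily.exponential(rate=1.0),
            ParametricFamily.exponential(rate=1.0),
            AnnouncementFunction.constant(1.0),
            n=500,
            seed=21,
        )
        sample = simulate(s)
        times, jumps = announced_jumps(sample)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(sample.u, event_observed=sample.delta)
        na = naf.cumulative_hazard_.iloc[:, 0]
        ours = np.cumsum(jumps)
        theirs = na.loc[times].to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_consistent_for_failure_cdf_when_all_announced(self):
        # A(t) = F(t) when q ≡ 1; sup error small at n = 1e5
        s = SimulationSetting(
            ParametricFamily.exponential(rate=1.0),
            ParametricFamily.exponential(rate=1.0),
            AnnouncementFunction.constant(1.0),
            n=100_000,
            seed=2,
        )
        sample = simulate(s)
        grid = np.linspace(0.0, 2.0, 200)
        a = estimate_A(sample, grid)
        assert np.max(np.abs(a - (1.0 - np.exp(-grid)))) < 0.02


class TestKernelEstimator:
    def test_normalizes_on_support(self):
        rng = np.random.default_rng(0)
        data = SampleData(u=rng.exponential(1.0, 2000), y=np.zeros(2000, int), delta=np.zeros(2000, int))
        grid = np.linspace(0.0, 15.0, 2000)
        vals, b = estimate_r(data, 1, grid)
        assert b > 0
        assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=5e-3)

    def test_reflection_preserves_boundary_mass(self):
        # Exp(2) has density 2 at the origin; an unreflected estimate halves it
        rng = np.random.default_rng(1)
        data = SampleData(u=rng.exponential(0.5, 5000), y=np.zeros(5000, int), delta=np.zeros(5000, int))
        vals, _ = estimate_r(data, 1, np.array([0.0]), bandwidth=0.05)
        assert vals[0] > 1.5  # well above the halved value 1.0

    def test_closed_form_category1_density(self):
        # exponential T, W and constant q: r1 is Exp(gamma+theta)
        s = SimulationSetting(
            ParametricFamily.exponential(rate=1.0),
            ParametricFamily.exponential(rate=1.0),
            AnnouncementFunction.constant(0.5),
            n=100_000,
            seed=8,
        )
        sample = simulate(s)
        vals, _ = estimate_r(sample, 1, np.array([1.0]))
        assert vals[0] == pytest.approx(2.0 * np.exp(-2.0), abs=0.02)

    def test_too_few_observations(self):
        data = SampleData(u=[1.0, 2.0], y=[0, 1], delta=[0, 1])
        with pytest.raises(ValueError, match="too few"):
            estimate_r(data, 3, np.linspace(0, 3, 10))

    def test_bandwidth_requires_two_points(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(np.array([1.0]))


class TestPluginF:
    def test_exact_components_reproduce_truth(self):
        """With exact (analytic) ingredients for unit exponentials and q = 1/2
        the plug-in combination is an identity for F(t) = 1 - e^{-t}."""
        grid = np.linspace(0.0, 5.0, 101)
        grid = np.union1d(grid, [np.log(2.0)])
        r1 = 2.0 * np.exp(-2.0 * grid)
        r3 = 2.0 * np.exp(-grid) * (1.0 - np.exp(-grid))
        A = 0.5 * (1.0 - np.exp(-grid))
        F = plugin_F(0.5, 0.25, r1, r3, A, grid)
        np.testing.assert_allclose(F, 1.0 - np.exp(-grid), atol=1e-12)
        i = np.searchsorted(grid, np.log(2.0))
        assert F[i] == pytest.approx(0.5, abs=1e-12)

    def test_no_abandonment_evidence_gives_zero(self):
        grid = np.linspace(0, 3, 10)
        F = plugin_F(1.0, 0.0, np.exp(-grid), np.zeros_like(grid), np.zeros_like(grid), grid)
        np.testing.assert_array_equal(F, 0.0)

    def test_saturated_announcement_gives_one(self):
        grid = np.linspace(0, 3, 10)
        F = plugin_F(0.5, 0.25, np.exp(-grid), np.exp(-grid), np.ones_like(grid), grid)
        np.testing.assert_allclose(F, 1.0)

    def test_degenerate_denominator_carries_forward(self):
        grid = np.linspace(0, 3, 4)
        r1 = np.array([1.0, 1.0, 0.0, 0.0])
        r3 = np.array([1.0, 1.0, 0.0, 0.0])
        A = np.array([0.1, 0.4, 0.9, 0.9])
        F = plugin_F(0.5, 0.5, r1, r3, A, grid)
        assert F[2] == F[1] and F[3] == F[1]


class TestMonotonize:
    def test_running_max_example(self):
        np.testing.assert_allclose(
            monotonize([0.1, 0.3, 0.2, 0.4]), [0.1, 0.3, 0.3, 0.4]
        )

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, values):
        arr = np.asarray(values)
        mono = monotonize(arr)
        assert np.all(np.diff(mono) >= 0)
        assert np.all(mono >= arr)
        np.testing.assert_array_equal(monotonize(mono), mono)


class TestFitNonparam:
    def test_fit_structure_and_invariants(self, setting1_sample):
        f = fit_nonparam(setting1_sample, tau_quantile=1.0)
        assert f.grid[0] == 0.0 and f.grid[-1] == pytest.approx(f.tau)
        assert f.A_hat[0] == 0.0
        assert np.all(np.diff(f.A_hat) >= -1e-15)
        assert np.all(f.A_hat < 1.0)
        assert np.all(np.diff(f.F_mono) >= 0)
        assert np.all(f.F_mono >= f.F_raw - 1e-15)
        assert 0 <= f.p_right_hat <= 1 and 0 <= f.p_silent_hat <= 1

    def test_accuracy_on_study_conditions(self, setting1_sample):
        f = fit_nonparam(setting1_sample, tau_quantile=0.95)
        truth = 1.0 - np.exp(-f.grid / 16.0)
        assert np.max(np.abs(f.F_mono - truth)) < 0.1

    def test_minimum_sample_size(self):
        data = SampleData(u=[1.0, 2.0], y=[0, 1], delta=[0, 1])
        with pytest.raises(ValueError, match="at least"):
            fit_nonparam(data)

    def test_no_abandonment_evidence_degenerates_to_zero(self):
        rng = np.random.default_rng(3)
        n = 50
        data = SampleData(u=rng.exponential(1, n), y=np.zeros(n, int), delta=np.zeros(n, int))
        f = fit_nonparam(data)
        np.testing.assert_array_equal(f.F_mono, 0.0)

    def test_unstable_silent_category_warns(self):
        rng = np.random.default_rng(4)
        n = 60
        u = rng.exponential(1, n)
        delta = np.zeros(n, int)
        y = np.zeros(n, int)
        delta[:3] = 1  # three silent abandonments only
        data = SampleData(u=u, y=y, delta=delta)
        with pytest.warns(UserWarning, match="unstable"):
            fit_nonparam(data)

    def test_survival_extension_beyond_tau(self, setting1_sample):
        f = fit_nonparam(setting1_sample)
        far = f.survival(np.array([f.tau * 10]))
        assert far[0] == pytest.approx(1.0 - f.F_mono[-1])

    def test_sup_error_shrinks_with_n(self):
        med = []
        for n in (1000, 4000, 16000):
            errs = []
            for r in range(8):
                sample = simulate(SimulationSetting.setting1(n=n, seed=300 + r))
                f = fit_nonparam(sample, tau_quantile=0.95)
                truth = 1.0 - np.exp(-f.grid / 16.0)
                errs.append(np.max(np.abs(f.F_mono - truth)))
            med.append(np.median(errs))
        assert med[2] < med[0]
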