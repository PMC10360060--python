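"""Residence-time statistics, recovery, ratio curves and rate inference."""

import numpy as np
import pytest

from eopemd.errors import AnalysisError, ConfigurationError
from eopemd.fixtures import lognormal_replicates, make_fixture
from eopemd.readouts import (CalibrationSweep, SteadyStateWarning,
                             first_moment, infer_rate_constant,
                             measurable_k_range, peclet_number, ratio_curves,
                             recovery_ratio, rtd_from_step_response,
                             survival_fraction, sweep_rate_constants,
                             time_to_fraction, transit_first_moment)
from eopemd.transport import BreakthroughCurve


def exponential_curve(tau=60.0, t_end=1200.0, n=1201, c0=1.0):
    t = np.linspace(0.0, t_end, n)
    return BreakthroughCurve("P", "s", t, c0 * (1 - np.exp(-t / tau)))


class TestRtd:
    def test_delayed_step_gives_delta_at_tau(self):
        t = np.linspace(0, 300, 3001)
        c = np.where(t >= 90.0, 1.0, 0.0)
        curve = BreakthroughCurve("P", "s", t, c)
        times, f = rtd_from_step_response(curve)
        assert np.trapezoid(f, times) == pytest.approx(1.0, abs=1e-9)
        assert first_moment(times, f) == pytest.approx(90.0, abs=0.2)

    def test_exponential_step_gives_exponential_rtd(self):
        tau = 60.0
        curve = exponential_curve(tau=tau)
        times, f = rtd_from_step_response(curve)
        expected = np.exp(-times / tau) / tau
        assert np.max(np.abs(f - expected)) < 0.02 / tau
        assert first_moment(times, f) == pytest.approx(tau, rel=0.02)

    def test_no_plateau_rejected(self):
        t = np.linspace(0, 100, 101)
        curve = BreakthroughCurve("P", "s", t, t / 100.0)  # still rising
        with pytest.raises(AnalysisError, match="plateau"):
            rtd_from_step_response(curve)

    def test_unnormalized_distribution_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(AnalysisError):
            first_moment(t, np.ones(11))

    def test_device_rtd_unimodal_unit_area(self, run_k0):
        """The simulated sink-orifice RTD is unimodal with unit area."""
        times, f = rtd_from_step_response(run_k0.curve("SINK_ORIFICE",
                                                       "yaGfl"))
        assert np.trapezoid(f, times) == pytest.approx(1.0, abs=1e-6)
        peak = int(np.argmax(f))
        # single interior maximum: nondecreasing before, nonincreasing after
        # (tolerate discretization jitter of 2% of the peak)
        jitter = 0.02 * f[peak]
        assert np.all(np.diff(f[:peak + 1]) >= -jitter)
        assert np.all(np.diff(f[peak:]) <= jitter)

    def test_transit_moment_composes(self):
        up = exponential_curve(tau=20.0)
        down = exponential_curve(tau=80.0)
        # moments compose additively: segment moment = m_down - m_up
        assert transit_first_moment(up, down) == pytest.approx(60.0, rel=0.03)


class TestTimeToFraction:
    def test_exponential_three_tau(self):
        curve = exponential_curve(tau=100.0, t_end=2400.0, n=2401)
        t95 = time_to_fraction(curve, 0.95, t_ref=2400.0)
        assert t95 == pytest.approx(300.0, rel=0.01)

    def test_immediate_step(self):
        t = np.linspace(0, 100, 101)
        curve = BreakthroughCurve("P", "s", t, np.ones(101))
        assert time_to_fraction(curve, 0.95, t_ref=100.0) == 0.0

    def test_unreached_fraction(self):
        t = np.linspace(0, 100, 101)
        c = np.where(t < 50, 0.0, 1.0) + 0.0
        curve = BreakthroughCurve("P", "s", t, c)
        with pytest.raises(AnalysisError):
            time_to_fraction(curve, 0.95, t_ref=200.0)


class TestPeclet:
    def test_published_operating_points(self):
        """Pe = L^2/(m1 D_eff) reproduces the operating table within ~10%."""
        d_eff = 5.4e-10 / 1.61**2
        assert peclet_number(84.0, 269e-6, d_eff) == pytest.approx(3.9,
                                                                   rel=0.10)
        assert peclet_number(108.0, 269e-6, d_eff) == pytest.approx(3.0,
                                                                    rel=0.10)

    def test_diffusion_dominated_limit(self):
        assert peclet_number(84.0, 269e-6, 1e-3) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            peclet_number(0.0, 269e-6, 1e-10)


class TestSurvival:
    def test_plug_flow_decay_quadrature(self):
        """Survival integral over a near-delta RTD matches exp(-k tau)."""
        case = make_fixture("plug_flow_decay")
        s = survival_fraction(case.extras["rtd_times"], case.extras["rtd"],
                              case.extras["rate_constant"])
        expected, tol = case.expected["survival"]
        assert s == pytest.approx(expected, rel=5e-4)

    def test_no_decay(self):
        case = make_fixture("plug_flow_decay", rate_constant=0.0)
        s = survival_fraction(case.extras["rtd_times"], case.extras["rtd"],
                              0.0)
        assert s == pytest.approx(1.0, abs=1e-9)


class TestRecovery:
    def test_zero_infusion_rejected(self):
        curve = exponential_curve()
        with pytest.raises(AnalysisError):
            recovery_ratio(curve, 0.0)

    def test_nonsteady_warns(self):
        tau = 400.0
        curve = exponential_curve(tau=tau, t_end=500.0, n=501)
        with pytest.warns(SteadyStateWarning):
            recovery_ratio(curve, 1.0)

    def test_plateaued_recovery(self):
        curve = exponential_curve(tau=20.0, t_end=1200.0)
        assert recovery_ratio(curve, 2.0) == pytest.approx(0.5, rel=1e-3)


class TestRatioCurves:
    def test_equal_d_ratio_is_unity(self, mini_model, mini_fields):
        from dataclasses import replace
        from eopemd.transport import solve_transport
        sub, std = mini_model.species_subset(("YGGFL", "yaGfl"))
        std_eq = replace(std, free_diffusion_coefficient=dict(
            sub.free_diffusion_coefficient))
        res = solve_transport(mini_model.grid, mini_model.matmap,
                              mini_fields.velocity, [sub, std_eq],
                              replace(mini_model.reaction,
                                      rate_constant_k=0.0),
                              mini_model.transport_config(),
                              probes=mini_model.probes)
        out = ratio_curves(res, "MD_OUTLET")
        ratio = out["YGGFL"]
        assert ratio.mask.any()  # early masked region exists
        assert np.allclose(ratio.compressed(), 1.0, atol=1e-9)

    def test_missing_standard_rejected(self, mini_model, mini_fields):
        from dataclasses import replace
        from eopemd.transport import solve_transport
        res = solve_transport(mini_model.grid, mini_model.matmap,
                              mini_fields.velocity,
                              mini_model.species_subset(("YGGFL",)),
                              replace(mini_model.reaction,
                                      rate_constant_k=0.0),
                              mini_model.transport_config(),
                              probes=mini_model.probes)
        with pytest.raises(AnalysisError):
            ratio_curves(res, "MD_OUTLET")


def analytic_sweep(k_grid=None):
    """Synthetic monotone calibration: S/IS from an exponential-RTD
    survival, P/IS its complement scaled by an incomplete recovery."""
    if k_grid is None:
        k_grid = np.logspace(-4, 0, 13)
    tau = 84.0
    s = 1.0 / (1.0 + k_grid * tau)  # survival of an exponential RTD
    p = 0.92 * (1.0 - s)
    return CalibrationSweep(k_grid=k_grid, s_over_is=s, p_over_is=p)


class TestCalibrationSweep:
    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            sweep_rate_constants(lambda k: (1.0, 0.0), [1e-3])

    def test_sweep_is_evaluated_sorted(self):
        calls = []

        def fake(k):
            calls.append(k)
            return 1.0 / (1.0 + 84.0 * k), 0.9 * 84.0 * k / (1 + 84.0 * k)

        sweep = sweep_rate_constants(fake, [1e-2, 1e-4, 1e-3])
        assert calls == sorted(calls)
        assert np.all(np.diff(sweep.s_over_is) <= 0)


class TestInference:
    def test_unreacted_substrate_maps_to_zero(self):
        sweep = analytic_sweep()
        est = infer_rate_constant({"s_over_is": 1.0}, sweep)
        assert est.k_hat == 0.0

    def test_grid_point_identity(self):
        sweep = analytic_sweep()
        k_true = sweep.k_grid[6]
        est = infer_rate_constant({"s_over_is": sweep.s_over_is[6],
                                   "p_over_is": sweep.p_over_is[6]},
                                  sweep, cv=0.0)
        assert est.k_hat == pytest.approx(k_true, rel=0.01)
        assert not est.extrapolated

    def test_extrapolation_flagged(self):
        sweep = analytic_sweep()
        est = infer_rate_constant({"p_over_is": 0.9999}, sweep)
        assert est.extrapolated

    def test_closed_loop_recovery_with_noise(self):
        """Noisy measurements generated off-grid are inverted to within
        x/1.5 of truth at 5% CV."""
        sweep = analytic_sweep()
        rng = np.random.default_rng(1234)
        tau = 84.0
        for k_true in (5e-4, 5e-3, 5e-2):
            s = 1.0 / (1.0 + k_true * tau)
            p = 0.92 * (1.0 - s)
            est = infer_rate_constant(
                {"s_over_is": lognormal_replicates(s, 0.05, 20, rng),
                 "p_over_is": lognormal_replicates(p, 0.05, 20, rng)},
                sweep, cv=0.05)
            assert k_true / 1.5 <= est.k_hat <= k_true * 1.5
            assert est.interval[0] <= est.k_hat <= est.interval[1]

    def test_measurable_range(self):
        sweep = analytic_sweep(np.logspace(-5, 1, 19))
        k_lo, k_hi = measurable_k_range(sweep, floor=0.005)
        assert k_lo < 1e-3 < 1e-1 < k_hi


class TestNoiseGenerator:
    def test_zero_cv_identity(self):
        rng = np.random.default_rng(0)
        assert np.all(lognormal_replicates(0.7, 0.0, 5, rng) == 0.7)

    def test_seed_reproducibility(self):
        a = lognormal_replicates(0.7, 0.05, 10, np.random.default_rng(42))
        b = lognormal_replicates(0.7, 0.05, 10, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_cv_scale(self):
        draws = lognormal_replicates(1.0, 0.05, 4000,
                                     np.random.default_rng(7))
        assert np.std(draws) / np.mean(draws) == pytest.approx(0.05,
                                                               rel=0.15)
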