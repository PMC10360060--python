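"""Advection-diffusion-reaction transport: oracles and conservation."""

from dataclasses import replace

import numpy as np
import pytest

from eopemd.errors import AnalysisError, ConfigurationError
from eopemd.fieldflow import (electroosmotic_velocity, solve_electric_field,
                              solve_pressure_and_velocity)
from eopemd.fixtures import (advection_diffusion_step, channel_probe,
                             make_fixture)
from eopemd.materials import SpeciesSpec
from eopemd.transport import (BreakthroughCurve, TransportConfig,
                              solve_transport, solve_transport_steady,
                              steady_state_fraction)


def _channel_velocity(case):
    pot, _ = solve_electric_field(case.grid, case.matmap, case.current)
    veo = electroosmotic_velocity(case.grid, case.matmap, pot)
    _, vel = solve_pressure_and_velocity(case.grid, case.matmap, veo,
                                         capillary_network=None)
    return vel


class TestBreakthrough1D:
    @pytest.mark.parametrize("resolution", [1, 2])
    def test_step_response_matches_closed_form(self, resolution):
        """Uniform-velocity channel breakthrough agrees with the flux-inlet
        advection-diffusion solution to < 2% of the inlet concentration."""
        case = make_fixture("breakthrough_1d", resolution=resolution)
        vel = _channel_velocity(case)
        probes = channel_probe(case.grid, case.extras["x_probe"])
        tracer = SpeciesSpec("tracer",
                             {37.0: case.extras["diffusivity"]},
                             infused_concentration=1.0)
        cfg = TransportConfig(duration=600.0, output_interval=5.0,
                              dt_tiers=((float("inf"), 0.5),),
                              tissue_farfield="no_flux")
        res = solve_transport(case.grid, case.matmap, vel, [tracer], None,
                              cfg, probes=probes)
        analytic = case.extras["analytic"](res.times)
        numeric = res.curves[("PROBE", "tracer")]
        assert np.max(np.abs(numeric - analytic)) < 0.02

    def test_closed_form_limits(self):
        """The analytic step response is 0 before flow arrives and -> 1
        far behind the front."""
        v, d = 3e-6, 5.4e-10
        early = advection_diffusion_step(1e-3, np.array([1.0]), v, d)
        late = advection_diffusion_step(1e-4, np.array([1e6]), v, d)
        assert early[0] < 1e-6
        assert late[0] == pytest.approx(1.0, abs=1e-3)


class TestReaction:
    def test_identical_species_same_field(self, mini_model, mini_fields):
        """With k = 0 and equal D, substrate and standard solve the same
        equation and must match exactly."""
        sub, std = mini_model.species_subset(("YGGFL", "yaGfl"))
        std_eq = replace(std, free_diffusion_coefficient=dict(
            sub.free_diffusion_coefficient))
        res = solve_transport(mini_model.grid, mini_model.matmap,
                              mini_fields.velocity, [sub, std_eq],
                              replace(mini_model.reaction, rate_constant_k=0.0),
                              mini_model.transport_config(),
                              probes=mini_model.probes)
        assert np.allclose(res.final_fields["YGGFL"],
                           res.final_fields["yaGfl"], rtol=1e-12, atol=1e-15)

    def test_equal_d_superposition(self, superposition_runs):
        """With D_P = D_S, C_S + C_P reproduces the unreactive substrate
        field to < 0.5% at every cell (linear superposition)."""
        res_k, res_0 = superposition_runs
        total = res_k.final_fields["YGGFL"] + res_k.final_fields["GGFL"]
        ref = res_0.final_fields["YGGFL"]
        assert np.max(np.abs(total - ref)) < 0.005 * ref.max()

    def test_mass_balance_conservative(self, run_k0):
        """k = 0: inflow - outflow - stored closes to < 0.5% of inflow."""
        for name, bal in run_k0.mass_balance.items():
            assert bal.inflow > 0
            assert bal.residual < 0.005

    def test_mass_balance_reactive(self, mini_model, mini_fields):
        """k > 0: the substrate deficit equals the integrated reaction term
        to < 1%, and product gain mirrors substrate loss exactly."""
        sub, prod = mini_model.species_subset(("YGGFL", "GGFL"))
        rxn = replace(mini_model.reaction, rate_constant_k=0.01)
        res = solve_transport(mini_model.grid, mini_model.matmap,
                              mini_fields.velocity, [sub, prod], rxn,
                              mini_model.transport_config(),
                              probes=mini_model.probes)
        s_bal = res.mass_balance["YGGFL"]
        p_bal = res.mass_balance["GGFL"]
        assert s_bal.reacted > 0
        assert s_bal.residual < 0.01
        assert p_bal.reacted == pytest.approx(-s_bal.reacted, rel=1e-9)
        assert p_bal.residual < 0.01

    def test_maximum_principle(self, run_k0):
        """Conservative species stay below the infused concentration."""
        c_in = max(s.infused_concentration for s in run_k0.species)
        for conc in run_k0.final_fields.values():
            assert conc.max() <= c_in * (1 + 1e-9)
            assert conc.min() >= 0.0

    def test_steady_substrate_monotone_in_k(self, mini_model, mini_fields):
        """Steady substrate at every probe is non-increasing in k."""
        previous = None
        for k in (0.0, 0.003, 0.03, 0.3):
            res = solve_transport_steady(
                mini_model.grid, mini_model.matmap, mini_fields.velocity,
                mini_model.species,
                replace(mini_model.reaction, rate_constant_k=k),
                probes=mini_model.probes)
            values = {key: v for key, v in res["probe"].items()
                      if key[1] == "YGGFL"}
            if previous is not None:
                for key in values:
                    assert values[key] <= previous[key] * (1 + 1e-9)
            previous = values


class TestInternalStandard:
    def test_surrogate_tracks_substrate(self, run_k0):
        """With true (unequal) D, steady substrate/standard ratio at the
        probe outlet stays within 10% of unity in the unreactive case."""
        s = run_k0.curves[("MD_OUTLET", "YGGFL")][-1]
        std = run_k0.curves[("MD_OUTLET", "yaGfl")][-1]
        assert s / std == pytest.approx(1.0, abs=0.10)


class TestSteadyStateFraction:
    def test_plateaued_curve(self):
        t = np.linspace(0, 100, 51)
        curve = BreakthroughCurve("P", "s", t, np.full(51, 2.5))
        frac = steady_state_fraction(curve, t_ref=100.0)
        assert np.allclose(frac, 1.0)

    def test_exponential_fraction(self):
        tau = 50.0
        t = np.linspace(0, 500, 501)
        curve = BreakthroughCurve("P", "s", t, 1 - np.exp(-t / tau))
        frac = steady_state_fraction(curve, t_ref=500.0)
        assert frac[np.searchsorted(t, 3 * tau)] == pytest.approx(0.95,
                                                                  abs=0.005)

    def test_zero_curve_flagged(self):
        t = np.linspace(0, 10, 11)
        curve = BreakthroughCurve("P", "s", t, np.zeros(11))
        with pytest.raises(AnalysisError):
            steady_state_fraction(curve, t_ref=10.0)


class TestConfigValidation:
    def test_bad_durations(self):
        with pytest.raises(ConfigurationError):
            TransportConfig(duration=-1.0)
        with pytest.raises(ConfigurationError):
            TransportConfig(duration=100.0, output_interval=200.0)

    def test_dt_must_divide_output_interval(self):
        with pytest.raises(ConfigurationError):
            TransportConfig(output_interval=30.0,
                            dt_tiers=((float("inf"), 7.0),))

    def test_curve_validation(self):
        with pytest.raises(ConfigurationError):
            BreakthroughCurve("P", "s", np.array([0.0, 1.0, 1.0]),
                              np.array([0.0, 0.1, 0.2]))
        with pytest.raises(ConfigurationError):
            BreakthroughCurve("P", "s", np.array([0.0, 1.0]),
                              np.array([0.5, -0.5]))
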