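"""Current conduction, electroosmotic coupling, Darcy flow, lumped
capillary backpressure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eopemd.errors import ConfigurationError, SolverError
from eopemd.fieldflow import (CapillaryNetwork, CurrentProgram,
                              ReynoldsWarning, darcy_velocity,
                              electroosmotic_velocity,
                              hagen_poiseuille_backpressure,
                              interface_pressures, solve_electric_field,
                              solve_pressure_and_velocity)
from eopemd.fixtures import make_fixture
from eopemd.geometry import Region
from eopemd.materials import default_material

UL_PER_MIN = 1e-9 / 60.0


class TestHagenPoiseuille:
    def test_published_backpressure(self):
        """The three bench capillaries give ~9.39 kPa at 0.5 uL/min."""
        net = CapillaryNetwork(segments=((0.050, 0.04e-3), (1.0, 0.10e-3),
                                         (0.140, 0.10e-3)))
        dp = hagen_poiseuille_backpressure(net, 0.5 * UL_PER_MIN)
        assert dp == pytest.approx(9.39e3, rel=0.08)

    def test_zero_flow(self):
        net = CapillaryNetwork(segments=((0.05, 0.04e-3),))
        assert hagen_poiseuille_backpressure(net, 0.0) == 0.0

    @given(length=st.floats(0.01, 2.0), diam=st.floats(2e-5, 5e-4),
           flow=st.floats(1e-13, 1e-10))
    @settings(max_examples=40, deadline=None)
    def test_fourth_power_diameter_law(self, length, diam, flow):
        one = CapillaryNetwork(segments=((length, diam),))
        two = CapillaryNetwork(segments=((length, 2 * diam),))
        dp1 = hagen_poiseuille_backpressure(one, flow)
        dp2 = hagen_poiseuille_backpressure(two, flow)
        assert dp1 == pytest.approx(16.0 * dp2, rel=1e-9)

    def test_zero_diameter_rejected(self):
        net = CapillaryNetwork(segments=((0.05, 0.0),))
        with pytest.raises(ConfigurationError):
            hagen_poiseuille_backpressure(net, 1e-12)

    def test_turbulence_warning(self):
        net = CapillaryNetwork(segments=((0.05, 0.04e-3),))
        with pytest.warns(ReynoldsWarning):
            hagen_poiseuille_backpressure(net, 1e-7)  # 6 mL/min


class TestDarcy:
    def test_published_tissue_velocity(self):
        """14.2 Pa across the orifice separation drives 7.5e-8 m/s."""
        v = darcy_velocity(14.2, 269e-6, 1.0e-15, 0.00070)
        assert v == pytest.approx(7.5e-8, rel=0.01)

    def test_pressure_transit_is_an_hour(self):
        v = darcy_velocity(14.2, 269e-6, 1.0e-15, 0.00070)
        assert 269e-6 / v / 60.0 == pytest.approx(60.0, rel=0.05)


class TestCurrentProgram:
    def test_compliance_enforced(self):
        CurrentProgram(applied_current=30e-6)
        with pytest.raises(ConfigurationError):
            CurrentProgram(applied_current=200e-6)


class TestConduction:
    def test_two_slab_series_field_ratio(self):
        """E2/E1 equals sigma1/sigma2 for equal-length slabs in series."""
        case = make_fixture("slab_conduction")
        pot, ef = solve_electric_field(case.grid, case.matmap, case.current)
        n = case.grid.nx
        ex = ef.cell_E[:, 0]
        e1 = np.abs(ex[n // 8: 3 * n // 8]).mean()
        e2 = np.abs(ex[5 * n // 8: 7 * n // 8]).mean()
        expected, tol = case.expected["field_ratio_E2_over_E1"]
        assert e2 / e1 == pytest.approx(expected, rel=1e-6)

    def test_zero_current_means_zero_field(self):
        case = make_fixture("slab_conduction")
        pot, ef = solve_electric_field(case.grid, case.matmap,
                                       CurrentProgram(applied_current=0.0))
        assert np.allclose(pot.V, 0.0)
        assert np.allclose(ef.cell_E, 0.0)

    def test_linearity_in_current(self):
        case = make_fixture("channel_eo")
        pot1, _ = solve_electric_field(case.grid, case.matmap, case.current)
        pot2, _ = solve_electric_field(
            case.grid, case.matmap,
            CurrentProgram(2 * case.current.applied_current))
        assert np.allclose(pot2.V, 2 * pot1.V, rtol=1e-10)

    def test_device_current_conservation(self, fields_10ua):
        assert fields_10ua.potential.balance_residual < 1e-6

    def test_device_lumen_field_magnitude(self, fields_10ua):
        """Mean field in the 50-um source lumen is ~3000 V/m at 10 uA."""
        mean_e = fields_10ua.efield.mean_region_magnitude(Region.SOURCE_LUMEN)
        assert 2.7e3 <= mean_e <= 3.1e3


class TestElectroosmosis:
    def test_channel_flow_per_current(self):
        """Q/I = eps |zeta| / (mu sigma), independent of cross section."""
        case = make_fixture("channel_eo")
        pot, _ = solve_electric_field(case.grid, case.matmap, case.current)
        veo = electroosmotic_velocity(case.grid, case.matmap, pot)
        q_out = veo.q_boundary["dialysate_outlet"].sum()
        expected, _ = case.expected["q_per_current_m3_per_C"]
        assert q_out / case.current.applied_current == pytest.approx(
            expected, rel=1e-9)

    def test_zero_zeta_no_flow(self):
        case = make_fixture("channel_eo")
        dead = {r: m.with_overrides(zeta_potential=0.0)
                for r, m in case.matmap.items()}
        pot, _ = solve_electric_field(case.grid, dead, case.current)
        veo = electroosmotic_velocity(case.grid, dead, pot)
        assert np.allclose(veo.q_interior, 0.0)

    def test_porous_velocity_reduction(self):
        """At equal E, superficial EO velocity in a porous medium is the
        open-channel value scaled by alpha/lambda^2 (0.0772 for cortex)."""
        open_mat = default_material("fluidic_channels", 37.0).with_overrides(
            zeta_potential=-0.0228)
        porous = open_mat.with_overrides(porosity_alpha=0.2,
                                         tortuosity_lambda=1.61)
        ratios = {}
        for tag, mat in (("open", open_mat), ("porous", porous)):
            case = make_fixture("channel_eo")
            matmap = {r: mat for r in case.matmap}
            pot, ef = solve_electric_field(case.grid, matmap, case.current)
            veo = electroosmotic_velocity(case.grid, matmap, pot)
            v = veo.q_boundary["dialysate_outlet"].sum() / (100e-6) ** 2
            e = ef.mean_region_magnitude(Region.SOURCE_LUMEN)
            ratios[tag] = v / e
        assert ratios["porous"] / ratios["open"] == pytest.approx(
            0.2 / 1.61**2, rel=1e-6)


class TestPressureFlow:
    def test_matched_zeta_gives_no_pressure(self):
        """A uniform channel (no zeta/sigma mismatch, both ends at the
        reservoir) develops no pressure and purely EO flow."""
        case = make_fixture("channel_eo")
        pot, _ = solve_electric_field(case.grid, case.matmap, case.current)
        veo = electroosmotic_velocity(case.grid, case.matmap, pot)
        pres, vel = solve_pressure_and_velocity(case.grid, case.matmap, veo,
                                                capillary_network=None)
        assert np.max(np.abs(pres.P)) < 1e-6  # Pa
        assert vel.flow_through("dialysate_outlet") == pytest.approx(
            veo.q_boundary["dialysate_outlet"].sum(), rel=1e-9)

    def test_device_mass_conservation(self, fields_10ua):
        vel = fields_10ua.velocity
        assert vel.mass_residual < 1e-6
        total = sum(q.sum() for q in vel.q_boundary.values())
        inflow = -vel.flow_through("source_inlet") - vel.flow_through(
            "dialysate_inlet")
        assert abs(total) / inflow < 1e-4

    def test_device_flow_magnitude(self, fields_10ua):
        """Net perfusion through tissue is ~0.8 nL/min per uA at 10 uA."""
        q_nl_min = -fields_10ua.velocity.flow_through("source_inlet") \
            * 1e12 * 60
        assert q_nl_min / 10.0 == pytest.approx(0.8, rel=0.15)

    def test_zeta_mismatch_pressure_signs(self, device_model):
        """The more negative conduit zeta pumps harder than tissue carries:
        positive pressure at the source interface, negative at the sink."""
        fields = device_model.solve_fields(30e-6)
        p_src, p_sink = interface_pressures(device_model.grid,
                                            device_model.geometry,
                                            fields.pressure)
        assert p_src > 0 > p_sink

    def test_pressure_plays_small_role(self, device_model,
                                       current_sweep_summaries):
        """Transit by the mismatch pressure alone (superficial Darcy
        velocity across the gap, the published convention) is >10x slower
        than the observed total source-to-sink residence time."""
        fields30 = device_model.solve_fields(30e-6)
        p_src, p_sink = interface_pressures(device_model.grid,
                                            device_model.geometry,
                                            fields30.pressure)
        tissue = device_model.matmap[Region.TISSUE]
        sep = device_model.geometry.source_sink_orifice_separation
        v_p = darcy_velocity(p_src - p_sink, sep, tissue.permeability_kappa,
                             tissue.viscosity)
        t_pressure = sep / v_p
        m1_total = current_sweep_summaries[30e-6]["m1_source_to_sink_s"]
        assert t_pressure > 10 * m1_total

    def test_disconnected_path_raises(self):
        """A severed conductive path makes the conduction problem singular."""
        from eopemd.geometry import BoundaryFaces, StructuredGrid
        n, w = 20, 100e-6
        label = np.full((n, 1, 1), int(Region.SOURCE_LUMEN), dtype=np.int8)
        label[n // 2] = int(Region.WALL)
        severed = StructuredGrid(xf=np.linspace(0, 1e-3, n + 1),
                                 yf=np.array([0.0, w]),
                                 zf=np.array([0.0, w]), label=label)
        for name, i, side in (("source_inlet", 0, -1),
                              ("dialysate_outlet", n - 1, +1)):
            severed.named_faces[name] = BoundaryFaces(
                cells=np.array([severed.index[i, 0, 0]]), axis=0, side=side,
                area=np.array([w * w]),
                dist=np.array([0.5 * severed.dx[i]]))
        matmap = {Region.SOURCE_LUMEN: default_material("fluidic_channels",
                                                        37.0)}
        with pytest.raises(SolverError):
            solve_electric_field(severed, matmap,
                                 CurrentProgram(applied_current=1e-6))
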