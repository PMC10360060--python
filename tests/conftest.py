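"""Shared fixtures.

The coupled 3D solves are the expensive part, so everything downstream of a
flow/transport solve is session-scoped and shared between the unit,
property and acceptance tests. The "mini" device is a geometrically valid
but smaller probe used where only correctness (not the published operating
point) is being checked.
"""

from __future__ import annotations

import numpy as np
import pytest

from eopemd.config import RunConfig
from eopemd.pipeline import DeviceModel, summarize

#: applied currents of the published operating table, amperes
SWEEP_CURRENTS = (5e-6, 10e-6, 15e-6, 30e-6)

MINI_GEOMETRY = {
    "tissue_box": ["0.8 mm", "0.4 mm", "0.8 mm"],
    "source_feed_length": "0.2 mm",
    "sink_conduit_length": "0.5 mm",
    "membrane_active_length": "0.6 mm",
    "chamber_entry_length": "0.2 mm",
}


@pytest.fixture(scope="session")
def device_model() -> DeviceModel:
    """Full published device at base resolution."""
    return DeviceModel(RunConfig())


@pytest.fixture(scope="session")
def fields_10ua(device_model):
    return device_model.solve_fields(10e-6)


@pytest.fixture(scope="session")
def run_k0(device_model):
    """40-min unreactive run at 10 uA with substrate + internal standard."""
    return device_model.run_transport(current=10e-6, k=0.0,
                                      species_names=("YGGFL", "yaGfl"))


@pytest.fixture(scope="session")
def summary_k0(device_model, fields_10ua, run_k0):
    return summarize(device_model, fields_10ua, run_k0)


@pytest.fixture(scope="session")
def run_k0005(device_model):
    """40-min run at 10 uA with the substrate hydrolyzed at k = 0.005/s."""
    return device_model.run_transport(current=10e-6, k=0.005,
                                      species_names=("YGGFL",))


@pytest.fixture(scope="session")
def current_sweep_summaries(device_model, summary_k0):
    """Summaries of unreactive runs across the published current table."""
    out = {10e-6: summary_k0}
    for i_app in SWEEP_CURRENTS:
        if i_app in out:
            continue
        fields = device_model.solve_fields(i_app)
        res = device_model.run_transport(current=i_app, k=0.0,
                                         species_names=("yaGfl",))
        out[i_app] = summarize(device_model, fields, res)
    return out


#: calibration k grid: two points per decade over 1e-5 .. 10^0.5 1/s —
#: wide enough for the dynamic-range property, dense enough for inversion
CALIBRATION_K_GRID = np.logspace(-5.0, 0.5, 12)


@pytest.fixture(scope="session")
def calibration_sweep(device_model):
    return device_model.calibration_sweep(CALIBRATION_K_GRID, current=10e-6)


@pytest.fixture(scope="session")
def wide_sweep(calibration_sweep):
    return calibration_sweep


@pytest.fixture(scope="session")
def mini_model() -> DeviceModel:
    return DeviceModel(RunConfig(geometry=MINI_GEOMETRY, duration="5 min"))


@pytest.fixture(scope="session")
def mini_fields(mini_model):
    return mini_model.solve_fields(10e-6)


@pytest.fixture(scope="session")
def superposition_runs(mini_model, mini_fields):
    """Reactive run with the product's D forced equal to the substrate's,
    plus the matching unreactive run: the exact-superposition pair."""
    from dataclasses import replace
    from eopemd.transport import solve_transport
    sub, prod = mini_model.species_subset(("YGGFL", "GGFL"))
    prod_eq = replace(prod, free_diffusion_coefficient=dict(
        sub.free_diffusion_coefficient))
    rxn = replace(mini_model.reaction, rate_constant_k=0.005)
    res_k = solve_transport(mini_model.grid, mini_model.matmap,
                            mini_fields.velocity, [sub, prod_eq], rxn,
                            mini_model.transport_config(),
                            probes=mini_model.probes)
    res_0 = solve_transport(mini_model.grid, mini_model.matmap,
                            mini_fields.velocity, [sub],
                            replace(rxn, rate_constant_k=0.0),
                            mini_model.transport_config(),
                            probes=mini_model.probes)
    return res_k, res_0
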