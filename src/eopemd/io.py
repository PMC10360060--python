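"""Result serialization: CSV summaries/curves and VTK rectilinear fields.

The VTK writer emits plain-ASCII XML ``.vtr`` (RectilinearGrid with cell
data), which ParaView and VisIt read natively; it is deliberately minimal
(structured grids with cell scalars are all this package produces).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_summary_csv(path, summary: dict) -> None:
    pd.DataFrame([summary]).to_csv(path, index=False)


def write_curves_csv(path, result, probe: str) -> None:
    """One CSV per probe point: t plus one concentration column per species."""
    data = {"time_s": result.times}
    for s in result.species:
        key = (probe, s.name)
        if key in result.curves:
            data[f"{s.name}_mol_m3"] = result.curves[key]
    pd.DataFrame(data).to_csv(path, index=False)


def read_curves_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_vtr(path, grid, cell_data: dict) -> None:
    """ASCII VTK XML rectilinear grid with named cell-data arrays.

    ``cell_data`` maps name -> full (nx, ny, nz) array (NaN in walls).
    """
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="RectilinearGrid" version="0.1" '
             'byte_order="LittleEndian">',
             f'  <RectilinearGrid WholeExtent="0 {nx} 0 {ny} 0 {nz}">',
             f'    <Piece Extent="0 {nx} 0 {ny} 0 {nz}">',
             '      <Coordinates>']
    for name, arr in (("x", grid.xf), ("y", grid.yf), ("z", grid.zf)):
        lines.append(f'        <DataArray type="Float64" Name="{name}" '
                     'format="ascii">')
        lines.append("          " + " ".join(f"{v:.9e}" for v in arr))
        lines.append("        </DataArray>")
    lines.append("      </Coordinates>")
    lines.append("      <CellData>")
    for name, arr in cell_data.items():
        flat = np.asarray(arr).transpose(2, 1, 0).ravel()  # VTK x-fastest
        lines.append(f'        <DataArray type="Float64" Name="{name}" '
                     'format="ascii">')
        lines.append("          " + " ".join(f"{v:.6e}" for v in flat))
        lines.append("        </DataArray>")
    lines += ["      </CellData>", "    </Piece>", "  </RectilinearGrid>",
              "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_fields_vtr(path, grid, fields, result=None) -> None:
    """Potential, pressure, region labels, velocity magnitude and (when
    available) final concentrations on the full grid."""
    vel = fields.velocity.cell_velocity()
    data = {
        "region": grid.label.astype(float),
        "potential_V": grid.expand(fields.potential.V, fill=np.nan),
        "pressure_Pa": grid.expand(fields.pressure.P, fill=np.nan),
        "speed_m_s": grid.expand(np.linalg.norm(vel, axis=1), fill=np.nan),
        "E_magnitude_V_m": grid.expand(fields.efield.magnitude(), fill=np.nan),
    }
    if result is not None:
        for name, conc in result.final_fields.items():
            data[f"C_{name}_mol_m3"] = grid.expand(conc, fill=np.nan)
    write_vtr(path, grid, data)
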