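"""Finite-volume assembly helpers shared by the conduction, pressure and
transport solvers.

All operators live on the active (non-WALL) cells of a
:class:`~eopemd.geometry.StructuredGrid`. Face transmissibilities use the
two-point flux approximation with distance-weighted harmonic averaging of
the cell coefficient, which conserves flux exactly across material
interfaces (tissue/membrane/channel).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import SolverError
from .geometry import BoundaryFaces, StructuredGrid


def face_transmissibility(grid: StructuredGrid, coef: np.ndarray) -> np.ndarray:
    """Harmonic-mean transmissibility T_f = A / (d_a/c_a + d_b/c_b) per
    interior face; zero where either coefficient vanishes."""
    f = grid.faces
    ca = coef[f["ia"]]
    cb = coef[f["ib"]]
    T = np.zeros(ca.shape)
    ok = (ca > 0) & (cb > 0)
    T[ok] = f["area"][ok] / (f["da"][ok] / ca[ok] + f["db"][ok] / cb[ok])
    return T


def boundary_transmissibility(bf: BoundaryFaces, coef: np.ndarray) -> np.ndarray:
    """Half-cell transmissibility for Dirichlet boundary faces."""
    c = coef[bf.cells]
    T = np.zeros(c.shape)
    ok = c > 0
    T[ok] = bf.area[ok] * c[ok] / bf.dist[ok]
    return T


def assemble_diffusion(grid: StructuredGrid, coef: np.ndarray
                       ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse operator L with (L u)_i = sum_f T_f (u_i - u_j) and the face
    transmissibilities used."""
    f = grid.faces
    T = face_transmissibility(grid, coef)
    ia, ib = f["ia"], f["ib"]
    n = grid.n_active
    rows = np.concatenate([ia, ib, ia, ib])
    cols = np.concatenate([ia, ib, ib, ia])
    vals = np.concatenate([T, T, -T, -T])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A, T


def dirichlet_terms(bf: BoundaryFaces, coef: np.ndarray, value: float, n: int
                    ) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Diagonal contribution, rhs contribution and boundary
    transmissibilities for a Dirichlet surface."""
    Tb = boundary_transmissibility(bf, coef)
    diag = sp.coo_matrix((Tb, (bf.cells, bf.cells)), shape=(n, n)).tocsr()
    rhs = np.zeros(n)
    np.add.at(rhs, bf.cells, Tb * value)
    return diag, rhs, Tb


def upwind_advection(grid: StructuredGrid, q_interior: np.ndarray,
                     boundary_flows: dict[str, np.ndarray]
                     ) -> tuple[sp.csr_matrix, dict[str, np.ndarray]]:
    """First-order upwind advection operator from signed face flows.

    ``q_interior`` is the volumetric flow (m^3/s) per interior face, positive
    a -> b; ``boundary_flows`` maps surface name to per-face flow positive
    out of the domain. Returns the operator and, per surface, the outflow
    part (positive part of the boundary flow; inflow must be handled through
    the rhs by the caller since it needs a boundary concentration).
    """
    f = grid.faces
    ia, ib = f["ia"], f["ib"]
    q = q_interior
    qp = np.maximum(q, 0.0)   # a -> b
    qm = np.maximum(-q, 0.0)  # b -> a
    n = grid.n_active
    rows = np.concatenate([ia, ib, ib, ia])
    cols = np.concatenate([ia, ia, ib, ib])
    vals = np.concatenate([qp, -qp, qm, -qm])
    outflows = {}
    brow, bval = [], []
    for name, (bf, qb) in boundary_flows.items():
        q_out = np.maximum(qb, 0.0)
        brow.append(bf.cells)
        bval.append(q_out)
        outflows[name] = q_out
    if brow:
        rows = np.concatenate([rows] + brow)
        cols = np.concatenate([cols] + brow)
        vals = np.concatenate([vals] + bval)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A, outflows


def scatter_face_divergence(grid: StructuredGrid, q_interior: np.ndarray,
                            boundary_flows: dict[str, np.ndarray]) -> np.ndarray:
    """Net outflow per cell from signed face flows (discrete divergence)."""
    n = grid.n_active
    f = grid.faces
    out = np.zeros(n)
    np.add.at(out, f["ia"], q_interior)
    np.add.at(out, f["ib"], -q_interior)
    for name, (bf, qb) in boundary_flows.items():
        np.add.at(out, bf.cells, qb)
    return out


def direct_solve(A: sp.csr_matrix, b: np.ndarray, what: str = "system",
                 rtol: float = 1e-8) -> np.ndarray:
    """Deterministic sparse-direct solve with a residual check."""
    try:
        lu = splu(A.tocsc())
        x = lu.solve(b)
    except RuntimeError as exc:  # singular factorization
        raise SolverError(f"{what}: sparse factorization failed ({exc}); "
                          "is the conductive/fluid path connected?") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError(f"{what}: solution contains non-finite values")
    scale = np.linalg.norm(b) if np.linalg.norm(b) > 0 else 1.0
    res = np.linalg.norm(A @ x - b) / scale
    if res > rtol:
        raise SolverError(f"{what}: relative residual {res:.3e} exceeds {rtol:.1e}",
                          residual=res)
    return x
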