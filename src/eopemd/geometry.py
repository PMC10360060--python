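"""Reduced device geometry and its structured-grid discretization.

The physical device is a two-photon-polymerized probe: a source conduit
infusing peptide into a block of cortex, a sink conduit 269 um away that
collects the perfusate, and an external chamber holding a microdialysis
probe (hollow-fiber membrane perfused with saline at 0.5 uL/min).

The model geometry unrolls the fluid path along a single axis (x):

    source reservoir -> source lumen -> tissue gap -> sink lumen ->
    chamber channel | membrane | dialysate lumen (planar exchanger)

Cylindrical cross sections are represented as squares/slabs of equal area,
so lumen electric fields (I/(sigma*A)) and electroosmotic flow per current
are preserved; the probe-in-chamber annulus becomes a planar co-laminated
exchanger whose channel areas and membrane exchange area match the
cylindrical values to within ~10%. The dialysate runs counter-current to
the captured perfusate, as in the physical probe (inlet at the top of the
lumen, outlet next to the glue plug at the bottom).

Regions are labeled per cell; everything not fluid or porous is WALL and is
excluded from all solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .errors import GeometryError

# side of the equal-area square for a circle of diameter d: d * sqrt(pi)/2
_SQ = math.sqrt(math.pi) / 2.0


class Region(IntEnum):
    WALL = 0
    TISSUE = 1
    SOURCE_LUMEN = 2
    SINK_LUMEN = 3
    CHAMBER_FLUID = 4
    MEMBRANE = 5
    DIALYSATE_LUMEN = 6


FLUID_REGIONS = (Region.TISSUE, Region.SOURCE_LUMEN, Region.SINK_LUMEN,
                 Region.CHAMBER_FLUID, Region.MEMBRANE, Region.DIALYSATE_LUMEN)


@dataclass(frozen=True)
class DeviceGeometry:
    """Dimensions of the reduced EOP-EMD model, SI meters.

    The tissue block and the conduit, chamber and membrane diameters are the
    published device dimensions; the conduit lengths and the feed length are
    documented approximations (the full print is not dimensioned in the
    sources available here) and may be overridden.
    """

    tissue_box: tuple[float, float, float] = (1.0e-3, 0.6e-3, 1.67e-3)  # x, y, z
    conduit_inner_diameter: float = 50e-6
    conduit_outer_diameter: float = 90e-6
    source_sink_orifice_separation: float = 269e-6
    chamber_diameter: float = 290e-6
    membrane_inner_diameter: float = 200e-6
    membrane_outer_diameter: float = 220e-6
    membrane_active_length: float = 1.0e-3
    dialysate_capillary_id: float = 40e-6
    #: approximation: straight feed section of the source conduit upstream of
    #: the tissue (the real capillary continues to a reservoir; only its
    #: electrical/advective entrance matters here)
    source_feed_length: float = 0.3e-3
    #: approximation: sink-conduit path length from orifice to chamber base
    sink_conduit_length: float = 1.0e-3
    #: approximation: chamber base below the active membrane (glue plug and
    #: outlet-capillary clearance) — dead volume the perfusate crosses
    #: before any membrane exchange
    chamber_entry_length: float = 0.35e-3
    #: vertical offset between source and sink orifices (not dimensioned in
    #: the sources; defaults to coaxial)
    source_sink_vertical_offset: float = 0.0
    #: capillaries in series downstream of the probe outlet (length, i.d.)
    lumped_capillary_network: tuple[tuple[float, float], ...] = (
        (0.050, 0.04e-3), (1.000, 0.10e-3), (0.140, 0.10e-3))

    def __post_init__(self):
        dims = (*self.tissue_box, self.conduit_inner_diameter,
                self.conduit_outer_diameter, self.source_sink_orifice_separation,
                self.chamber_diameter, self.membrane_inner_diameter,
                self.membrane_outer_diameter, self.membrane_active_length,
                self.dialysate_capillary_id, self.source_feed_length,
                self.sink_conduit_length)
        if any(d <= 0 for d in dims):
            raise GeometryError("all geometry dimensions must be > 0")
        if self.chamber_entry_length < 0:
            raise GeometryError("chamber_entry_length must be >= 0")
        if self.conduit_inner_diameter >= self.conduit_outer_diameter:
            raise GeometryError("conduit i.d. must be smaller than o.d.")
        if self.membrane_inner_diameter >= self.membrane_outer_diameter:
            raise GeometryError("membrane i.d. must be smaller than o.d. "
                                "(zero-thickness membrane is degenerate)")
        if self.membrane_outer_diameter > self.chamber_diameter:
            raise GeometryError("membrane must fit inside the chamber")
        if self.source_sink_orifice_separation >= self.tissue_box[0]:
            raise GeometryError("orifice separation must be smaller than the "
                                "tissue extent along the source-sink axis")
        for length, diam in self.lumped_capillary_network:
            if length <= 0 or diam <= 0:
                raise GeometryError("capillary network lengths/diameters must be > 0")

    def with_overrides(self, **kwargs) -> "DeviceGeometry":
        return replace(self, **kwargs)

    # Derived planar-exchanger dimensions -------------------------------
    @property
    def channel_half_width(self) -> float:
        """Half-side of the equal-area square conduit lumen."""
        return self.conduit_inner_diameter * _SQ / 2.0

    @property
    def conduit_wall_half_width(self) -> float:
        return self.conduit_outer_diameter * _SQ / 2.0

    @property
    def membrane_thickness(self) -> float:
        return (self.membrane_outer_diameter - self.membrane_inner_diameter) / 2.0

    @property
    def chamber_annulus_area(self) -> float:
        """Flow area between membrane o.d. and chamber wall."""
        return math.pi / 4.0 * (self.chamber_diameter**2
                                - self.membrane_outer_diameter**2)

    @property
    def lumen_area(self) -> float:
        return math.pi / 4.0 * self.membrane_inner_diameter**2

    @property
    def chamber_depth(self) -> float:
        """z-depth of the planar exchanger, set so the chamber channel width
        can equal the conduit channel width while conserving flow area."""
        return self.chamber_annulus_area / (2.0 * self.channel_half_width)

    @property
    def dialysate_lumen_width(self) -> float:
        return self.lumen_area / self.chamber_depth

    @property
    def membrane_exchange_area(self) -> float:
        """Planar membrane area; the cylindrical value is
        pi * mean(membrane o.d., i.d.) * active length."""
        return self.membrane_active_length * self.chamber_depth

    # Axial landmarks ---------------------------------------------------
    @property
    def x_tissue(self) -> tuple[float, float]:
        x0 = self.source_feed_length
        return (x0, x0 + self.tissue_box[0])

    @property
    def x_source_orifice(self) -> float:
        x0, x1 = self.x_tissue
        return x0 + (self.tissue_box[0] - self.source_sink_orifice_separation) / 2.0

    @property
    def x_sink_orifice(self) -> float:
        return self.x_source_orifice + self.source_sink_orifice_separation

    @property
    def x_chamber(self) -> tuple[float, float]:
        x0 = self.x_sink_orifice + self.sink_conduit_length
        return (x0, x0 + self.chamber_entry_length
                + self.membrane_active_length)

    @property
    def x_membrane_start(self) -> float:
        return self.x_chamber[0] + self.chamber_entry_length

    @property
    def extent(self) -> tuple[float, float, float]:
        return (self.x_chamber[1], self.tissue_box[1], self.tissue_box[2])


def build_default_geometry(**overrides) -> DeviceGeometry:
    """The published device dimensions, optionally overridden per field."""
    return DeviceGeometry(**overrides)


# --- structured grid ----------------------------------------------------

@dataclass
class BoundaryFaces:
    """A named set of boundary faces of active cells.

    ``cells`` are *active* (compressed) cell indices; ``axis`` in {0,1,2};
    ``side`` is -1 for the lower face, +1 for the upper; ``area`` m^2;
    ``dist`` the cell-center-to-face distance.
    """
    cells: np.ndarray
    axis: int
    side: int
    area: np.ndarray
    dist: np.ndarray


@dataclass
class StructuredGrid:
    """Tensor-product hexahedral grid with per-cell region labels."""

    xf: np.ndarray  # face coordinates, length nx+1
    yf: np.ndarray
    zf: np.ndarray
    label: np.ndarray  # (nx, ny, nz) int8 of Region values
    named_faces: dict[str, BoundaryFaces] = field(default_factory=dict)
    resolution: int = 1

    def __post_init__(self):
        self.nx, self.ny, self.nz = self.label.shape
        self.dx = np.diff(self.xf)
        self.dy = np.diff(self.yf)
        self.dz = np.diff(self.zf)
        if np.any(self.dx <= 0) or np.any(self.dy <= 0) or np.any(self.dz <= 0):
            raise GeometryError("grid face coordinates must be strictly increasing")
        self.xc = 0.5 * (self.xf[:-1] + self.xf[1:])
        self.yc = 0.5 * (self.yf[:-1] + self.yf[1:])
        self.zc = 0.5 * (self.zf[:-1] + self.zf[1:])
        self.active = self.label != Region.WALL
        self.n_active = int(self.active.sum())
        # compressed index: -1 for WALL
        self.index = -np.ones(self.label.shape, dtype=np.int64)
        self.index[self.active] = np.arange(self.n_active)
        # per-active-cell lookups
        ii, jj, kk = np.nonzero(self.active)
        self.cell_ijk = np.stack([ii, jj, kk], axis=1)
        vol3 = (self.dx[:, None, None] * self.dy[None, :, None]
                * self.dz[None, None, :])
        self.cell_volume = vol3[self.active]
        self.cell_region = self.label[self.active].astype(np.int64)
        self._faces = None

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    def region_volume(self, region: Region) -> float:
        return float(self.cell_volume[self.cell_region == int(region)].sum())

    def cell_centers(self) -> np.ndarray:
        """(n_active, 3) centers of active cells."""
        i, j, k = self.cell_ijk.T
        return np.stack([self.xc[i], self.yc[j], self.zc[k]], axis=1)

    def expand(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter an active-cell vector onto the full (nx, ny, nz) array."""
        out = np.full(self.label.shape, fill, dtype=float)
        out[self.active] = values
        return out

    # -- interior faces ---------------------------------------------------
    @property
    def faces(self) -> dict:
        """Interior faces between pairs of active cells.

        Arrays: ``ia``/``ib`` active indices, ``axis``, ``area``,
        ``da``/``db`` center-to-face distances.
        """
        if self._faces is None:
            ia, ib, axis, area, da, db = [], [], [], [], [], []
            for ax in range(3):
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                sl_a[ax] = slice(None, -1)
                sl_b[ax] = slice(1, None)
                both = self.active[tuple(sl_a)] & self.active[tuple(sl_b)]
                idx_a = self.index[tuple(sl_a)][both]
                idx_b = self.index[tuple(sl_b)][both]
                ii, jj, kk = np.nonzero(both)
                if ax == 0:
                    ar = self.dy[jj] * self.dz[kk]
                    d_a = 0.5 * self.dx[ii]
                    d_b = 0.5 * self.dx[ii + 1]
                elif ax == 1:
                    ar = self.dx[ii] * self.dz[kk]
                    d_a = 0.5 * self.dy[jj]
                    d_b = 0.5 * self.dy[jj + 1]
                else:
                    ar = self.dx[ii] * self.dy[jj]
                    d_a = 0.5 * self.dz[kk]
                    d_b = 0.5 * self.dz[kk + 1]
                ia.append(idx_a)
                ib.append(idx_b)
                axis.append(np.full(idx_a.shape, ax, dtype=np.int8))
                area.append(ar)
                da.append(d_a)
                db.append(d_b)
            self._faces = {
                "ia": np.concatenate(ia), "ib": np.concatenate(ib),
                "axis": np.concatenate(axis), "area": np.concatenate(area),
                "da": np.concatenate(da), "db": np.concatenate(db),
            }
        return self._faces


def _axis_faces_simple(segments, resolution):
    """Face coordinates from (start, end, target size) segments.

    Cell counts are ``ceil(length/target)`` at resolution 1 and scale
    linearly with resolution, so refinement multiplies every axis's cell
    count exactly.
    """
    faces = [segments[0][0]]
    for (a, b, h) in segments:
        n = max(1, math.ceil((b - a) / h - 1e-9)) * resolution
        faces.extend(np.linspace(a, b, n + 1)[1:].tolist())
    return np.asarray(faces)


def discretize(geometry: DeviceGeometry, resolution: int = 1) -> StructuredGrid:
    """Label the reduced geometry on a graded tensor-product grid.

    Cell-size targets refine near the orifices (<= conduit radius / 2 at
    resolution 1) and across the thin membrane; increasing ``resolution``
    multiplies every axis's cell count by that factor.
    """
    if resolution < 1:
        raise GeometryError("resolution must be >= 1")
    g = geometry
    a = g.channel_half_width
    b = g.conduit_wall_half_width
    tm = g.membrane_thickness
    xs, xk = g.x_source_orifice, g.x_sink_orifice
    xt0, xt1 = g.x_tissue
    xc0, xc1 = g.x_chamber
    ly, lz = g.tissue_box[1], g.tissue_box[2]
    dch = g.chamber_depth
    wl = g.dialysate_lumen_width
    if dch > lz or (a + tm + wl) > ly / 2:
        raise GeometryError("chamber exchanger does not fit in the domain cross "
                            "section; enlarge the tissue box or shrink the chamber")
    if g.source_sink_vertical_offset:
        if abs(g.source_sink_vertical_offset) + b > lz / 2:
            raise GeometryError("vertical offset pushes a conduit outside the box")
    zoff = g.source_sink_vertical_offset

    fine = min(12e-6, g.conduit_inner_diameter / 4.0)  # near-orifice target
    x_segments = [
        (0.0, xt0, 50e-6),
        (xt0, xs - 5 * fine, 30e-6),
        (xs - 5 * fine, xs, fine),
        (xs, xk, fine),
        (xk, xk + 5 * fine, fine),
        (xk + 5 * fine, xt1, 30e-6),
        (xt1, xc0, 60e-6),
    ]
    if g.chamber_entry_length > 0:
        x_segments.append((xc0, g.x_membrane_start, 50e-6))
    x_segments.append((g.x_membrane_start, xc1, 55e-6))
    y_edge = (ly / 2 - (a + tm + wl))
    y_segments = [
        (-ly / 2, -b, 60e-6),
        (-b, -a, 10e-6),
        (-a, a, 11.5e-6),
        (a, a + tm, tm / 2.0),
        (a + tm, b, b - a - tm + 1e-9),
        (b, a + tm + wl, 15e-6),
        (a + tm + wl, ly / 2, y_edge / 4.0),
    ]
    z_lines = sorted({-lz / 2, -dch / 2, -b + zoff, -a + zoff, a + zoff,
                      b + zoff, dch / 2, lz / 2})
    z_segments = []
    for za, zb in zip(z_lines[:-1], z_lines[1:]):
        width = zb - za
        if width <= 2 * (b - a):
            h = width / 2.0 if width > 1.5 * (b - a) else width
        elif width <= 2 * a + 1e-12:
            h = 11.5e-6
        elif width < 0.35e-3:
            h = 50e-6
        else:
            h = 90e-6
        z_segments.append((za, zb, h))

    xf = _axis_faces_simple(x_segments, resolution)
    yf = _axis_faces_simple(y_segments, resolution)
    zf = _axis_faces_simple(z_segments, resolution)

    xcn = 0.5 * (xf[:-1] + xf[1:])
    ycn = 0.5 * (yf[:-1] + yf[1:])
    zcn = 0.5 * (zf[:-1] + zf[1:])
    X = xcn[:, None, None]
    Y = ycn[None, :, None]
    Z = zcn[None, None, :]

    label = np.zeros((len(xcn), len(ycn), len(zcn)), dtype=np.int8)

    in_channel_yz = (np.abs(Y) < a) & (np.abs(Z - zoff) < a)
    in_wall_yz = (np.abs(Y) < b) & (np.abs(Z - zoff) < b)

    # tissue block
    label[(X > xt0) & (X < xt1) & np.broadcast_to(True, label.shape)] = Region.TISSUE
    # conduit walls displace tissue along the conduit runs
    src_run = (X < xs)
    sink_run = (X > xk)
    label[np.broadcast_to(src_run & in_wall_yz, label.shape)
          & (label == Region.TISSUE)] = Region.WALL
    label[np.broadcast_to(sink_run & in_wall_yz, label.shape)
          & (label == Region.TISSUE)] = Region.WALL
    # lumens
    label[np.broadcast_to((X < xs) & in_channel_yz, label.shape)] = Region.SOURCE_LUMEN
    label[np.broadcast_to((X > xk) & (X < xc0) & in_channel_yz,
                          label.shape)] = Region.SINK_LUMEN
    # chamber exchanger; the membrane and dialysate lumen start after the
    # dead entry section at the chamber base
    xm0 = g.x_membrane_start
    in_ch_x = (X > xc0) & (X < xc1)
    in_mem_x = (X > xm0) & (X < xc1)
    in_depth = np.abs(Z) < dch / 2
    annulus_y = np.abs(Y) < a
    membrane_y = (Y > a) & (Y < a + tm)
    lumen_y = (Y > a + tm) & (Y < a + tm + wl)
    label[np.broadcast_to(in_ch_x & annulus_y & in_depth,
                          label.shape)] = Region.CHAMBER_FLUID
    label[np.broadcast_to(in_mem_x & membrane_y & in_depth,
                          label.shape)] = Region.MEMBRANE
    label[np.broadcast_to(in_mem_x & lumen_y & in_depth,
                          label.shape)] = Region.DIALYSATE_LUMEN

    for required in (Region.TISSUE, Region.SOURCE_LUMEN, Region.SINK_LUMEN,
                     Region.CHAMBER_FLUID, Region.MEMBRANE,
                     Region.DIALYSATE_LUMEN):
        if not np.any(label == required):
            raise GeometryError(f"region {required.name} is empty on this grid; "
                                "geometry inconsistent with labeling")

    grid = StructuredGrid(xf=xf, yf=yf, zf=zf, label=label, resolution=resolution)
    _tag_named_faces(grid)
    return grid


def _tag_named_faces(grid: StructuredGrid) -> None:
    """Tag the four open boundary-face sets of the default device."""
    lab = grid.label
    dy, dz, dx = grid.dy, grid.dz, grid.dx

    def face_set(mask_cells, axis, side):
        ii, jj, kk = np.nonzero(mask_cells)
        cells = grid.index[ii, jj, kk]
        if axis == 0:
            area = dy[jj] * dz[kk]
            dist = 0.5 * dx[ii]
        elif axis == 1:
            area = dx[ii] * dz[kk]
            dist = 0.5 * dy[jj]
        else:
            area = dx[ii] * dy[jj]
            dist = 0.5 * dz[kk]
        return BoundaryFaces(cells=cells, axis=axis, side=side,
                             area=area, dist=dist)

    m = np.zeros_like(lab, dtype=bool)
    m[0, :, :] = lab[0, :, :] == Region.SOURCE_LUMEN
    grid.named_faces["source_inlet"] = face_set(m, 0, -1)

    m = np.zeros_like(lab, dtype=bool)
    m[-1, :, :] = lab[-1, :, :] == Region.CHAMBER_FLUID
    grid.named_faces["waste_outlet"] = face_set(m, 0, +1)

    m = np.zeros_like(lab, dtype=bool)
    m[-1, :, :] = lab[-1, :, :] == Region.DIALYSATE_LUMEN
    grid.named_faces["dialysate_inlet"] = face_set(m, 0, +1)

    # dialysate outlet: lumen cells whose -x neighbor is WALL (chamber base)
    m = np.zeros_like(lab, dtype=bool)
    m[1:, :, :] = ((lab[1:, :, :] == Region.DIALYSATE_LUMEN)
                   & (lab[:-1, :, :] == Region.WALL))
    grid.named_faces["dialysate_outlet"] = face_set(m, 0, -1)

    # outer tissue faces: the surrounding perfused brain acts as a diffusive
    # far field for solutes (no current or fluid crosses; transport may apply
    # an absorbing condition here)
    for tag, axis, side in (("ym", 1, -1), ("yp", 1, +1),
                            ("zm", 2, -1), ("zp", 2, +1)):
        m = np.zeros_like(lab, dtype=bool)
        if axis == 1:
            sl = (slice(None), 0 if side < 0 else -1, slice(None))
        else:
            sl = (slice(None), slice(None), 0 if side < 0 else -1)
        m[sl] = lab[sl] == Region.TISSUE
        grid.named_faces[f"tissue_farfield_{tag}"] = face_set(m, axis, side)

    for name, bf in grid.named_faces.items():
        if bf.cells.size == 0 and not name.startswith("tissue_farfield"):
            raise GeometryError(f"boundary surface {name!r} is empty")


# --- probe points -------------------------------------------------------

@dataclass(frozen=True)
class ProbePoint:
    name: str
    region: Region
    cell: int  # active index
    position: tuple[float, float, float]


@dataclass(frozen=True)
class ProbePointSet:
    points: dict[str, ProbePoint]

    def __getitem__(self, name: str) -> ProbePoint:
        return self.points[name]

    def __iter__(self):
        return iter(self.points.values())


def _nearest_cell_in_region(grid: StructuredGrid, region: Region,
                            target: np.ndarray) -> int:
    mask = grid.cell_region == int(region)
    if not np.any(mask):
        raise GeometryError(f"region {region.name} absent from grid")
    centers = grid.cell_centers()[mask]
    idx = np.argmin(((centers - target) ** 2).sum(axis=1))
    return int(np.nonzero(mask)[0][idx])


def probe_points(grid: StructuredGrid, geometry: DeviceGeometry) -> ProbePointSet:
    """The named sampling points.

    SOURCE_ORIFICE: last source-lumen cell before the tissue (references
    residence times to solute entering the tissue rather than the
    reservoir); SINK_ORIFICE: first sink-lumen cell at the tissue interface
    (the "Tissue" curve); CHAMBER_ENTRANCE: chamber channel cell at the
    chamber base; MD_OUTLET: dialysate-lumen cell adjacent to the probe
    outlet (readouts additionally use the flow-weighted outlet-face
    average).
    """
    zoff = geometry.source_sink_vertical_offset
    pts = {}
    for name, region, target in (
            ("SOURCE_ORIFICE", Region.SOURCE_LUMEN,
             np.array([geometry.x_source_orifice, 0.0, zoff])),
            ("SINK_ORIFICE", Region.SINK_LUMEN,
             np.array([geometry.x_sink_orifice, 0.0, zoff])),
            ("CHAMBER_ENTRANCE", Region.CHAMBER_FLUID,
             np.array([geometry.x_chamber[0], 0.0, 0.0])),
            ("MD_OUTLET", Region.DIALYSATE_LUMEN,
             np.array([geometry.x_chamber[0],
                       geometry.channel_half_width + geometry.membrane_thickness
                       + geometry.dialysate_lumen_width / 2, 0.0]))):
        cell = _nearest_cell_in_region(grid, region, target)
        pos = tuple(grid.cell_centers()[cell])
        pts[name] = ProbePoint(name=name, region=region, cell=cell, position=pos)
    return ProbePointSet(points=pts)


def check_connectivity(grid: StructuredGrid) -> bool:
    """Breadth-first search: every active cell reachable from the source
    inlet through face-shared active neighbors; raises on a disconnected
    fluid path (source -> tissue -> sink -> chamber -> membrane -> dialysate)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    f = grid.faces
    n = grid.n_active
    adj = coo_matrix((np.ones(f["ia"].size), (f["ia"], f["ib"])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    start = grid.named_faces["source_inlet"].cells[0]
    end = grid.named_faces["dialysate_outlet"].cells[0]
    if labels[start] != labels[end]:
        raise GeometryError("fluid path source -> dialysate outlet is disconnected")
    return True
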