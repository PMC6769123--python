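"""Programmatic mesh generation and rule-based fiber architecture.

All computational geometries are generated in code, deterministically:

* structured hexahedral plates (the stretch-induced-excitation benchmark),
* a unit cube for isotonic contraction,
* a synthetic truncated-ellipsoid left ventricle (LV) with a rule-based
  transmural fiber field, emulating a rat LV at the correct scale.  The real
  geometry of interest is MRI-derived and not reproducible here; the
  ellipsoidal stand-in keeps the wall thickness, cavity size and fiber helix
  architecture (+80 deg on the endocardium to -70 deg on the epicardium,
  linear in wall depth) at rat scale.

Coordinates are Cartesian mm.  Meshes carry per-element orthonormal
fiber/sheet/normal frames and named node sets used by the experiment
protocols (base fixation, apex probe, basal stimulus patch, plate load
region, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .constitutive import Frame, make_frame

__all__ = ["Mesh", "LVGeometrySpec", "make_plate", "make_cube", "make_lv",
           "assign_fibers"]


@dataclass
class Mesh:
    """Unstructured mesh: nodes [mm], connectivity, node sets, element frames."""

    points: np.ndarray                      # (N, 3)
    cells: np.ndarray                       # (E, 8) hex8 or (E, 4) tet4
    cell_type: str                          # "hex8" | "tet4"
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    frames: Frame | None = None             # per-element (E, 3) vectors
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def validate(self) -> None:
        if self.cell_type not in ("hex8", "tet4"):
            raise ValueError(f"unknown cell type {self.cell_type}")
        if self.cells.max() >= self.n_nodes or self.cells.min() < 0:
            raise ValueError("connectivity references unknown nodes")
        for name, ids in self.node_sets.items():
            if len(ids) and (ids.max() >= self.n_nodes or ids.min() < 0):
                raise ValueError(f"node set '{name}' out of range")
        if self.frames is not None:
            self.frames.check(tol=1e-8)

    def cell_volumes(self) -> np.ndarray:
        """Element volumes; tet4 exact, hex8 by 2x2x2 Gauss quadrature."""
        X = self.points[self.cells]
        if self.cell_type == "tet4":
            d = X[:, 1:] - X[:, :1]
            return np.linalg.det(d) / 6.0
        from .fem_core import hex8_reference
        dN, w = hex8_reference()
        Jg = np.einsum("qam,ean->eqmn", dN, X)
        return np.einsum("eq,q->e", np.linalg.det(Jg), w)


# --------------------------------------------------------------------------
# plates and cubes
# --------------------------------------------------------------------------

def _structured_hex_grid(dim, div):
    Lx, Ly, Lz = dim
    nx, ny, nz = div
    xs = np.linspace(0.0, Lx, nx + 1)
    ys = np.linspace(0.0, Ly, ny + 1)
    zs = np.linspace(0.0, Lz, nz + 1)
    Xg, Yg, Zg = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([Xg.ravel(), Yg.ravel(), Zg.ravel()])
    nid = np.arange(points.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    # vtk hex8 ordering: bottom quad ccw, then top quad
    c = np.empty((nx, ny, nz, 8), dtype=int)
    c[..., 0] = nid[:-1, :-1, :-1]
    c[..., 1] = nid[1:, :-1, :-1]
    c[..., 2] = nid[1:, 1:, :-1]
    c[..., 3] = nid[:-1, 1:, :-1]
    c[..., 4] = nid[:-1, :-1, 1:]
    c[..., 5] = nid[1:, :-1, 1:]
    c[..., 6] = nid[1:, 1:, 1:]
    c[..., 7] = nid[:-1, 1:, 1:]
    return points, c.reshape(-1, 8), nid


def make_plate(dim=(100.0, 100.0, 12.0), divisions=(21, 21, 2)) -> Mesh:
    """Structured hex8 plate with in-plane fiber (x) / sheet (y) directions.

    Node sets:
      ``midplane_edges`` -- boundary-edge nodes of the mid-plane z = Lz/2
      (fixed in z), ``pin_xy`` -- node (0,0,0), ``pin_y`` -- node (Lx,0,0),
      ``load`` -- nodes of the central parallelepiped spanning 20% of the
      in-plane extent through the full thickness, ``probe_center`` -- node
      nearest the plate center.
    """
    if min(divisions) < 1:
        raise ValueError("divisions must be >= 1 in every direction")
    Lx, Ly, Lz = dim
    points, cells, nid = _structured_hex_grid(dim, divisions)
    x, y, z = points.T
    tol = 1e-9 * max(dim)
    mid = np.abs(z - Lz / 2.0) < tol
    on_edge = (np.abs(x) < tol) | (np.abs(x - Lx) < tol) \
        | (np.abs(y) < tol) | (np.abs(y - Ly) < tol)
    midplane_edges = np.flatnonzero(mid & on_edge)
    pin_xy = np.array([int(np.argmin(x ** 2 + y ** 2 + z ** 2))])
    pin_y = np.array([int(np.argmin((x - Lx) ** 2 + y ** 2 + z ** 2))])
    inload = (np.abs(x - Lx / 2.0) <= 0.1 * Lx + tol) \
        & (np.abs(y - Ly / 2.0) <= 0.1 * Ly + tol)
    load = np.flatnonzero(inload)
    center = np.array([int(np.argmin((x - Lx / 2) ** 2 + (y - Ly / 2) ** 2
                                     + (z - Lz) ** 2))])
    E = cells.shape[0]
    frames = make_frame(np.tile([1.0, 0, 0], (E, 1)), np.tile([0, 1.0, 0], (E, 1)))
    mesh = Mesh(points=points, cells=cells, cell_type="hex8",
                node_sets={"midplane_edges": midplane_edges, "pin_xy": pin_xy,
                           "pin_y": pin_y, "load": load,
                           "probe_center": center},
                frames=frames, meta={"dim": dim, "divisions": divisions})
    mesh.validate()
    return mesh


def make_cube(edge: float = 1.0, n: int = 1) -> Mesh:
    """Unit-cube hex mesh with uniform x-fibers and minimal rigid pinning.

    The 3-2-1 pinning (corner fixed, one edge neighbor fixed in y,z, one in
    z) removes rigid-body motion while leaving homogeneous axis-aligned
    deformation unconstrained - the isotonic-contraction configuration.
    """
    points, cells, nid = _structured_hex_grid((edge,) * 3, (n,) * 3)
    x, y, z = points.T
    def node_at(px, py, pz):
        return np.array([int(np.argmin((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2))])
    E = cells.shape[0]
    frames = make_frame(np.tile([1.0, 0, 0], (E, 1)), np.tile([0, 1.0, 0], (E, 1)))
    mesh = Mesh(points=points, cells=cells, cell_type="hex8",
                node_sets={"pin_xyz": node_at(0, 0, 0),
                           "pin_yz": node_at(edge, 0, 0),
                           "pin_z": node_at(0, edge, 0),
                           "probe_corner": node_at(edge, edge, edge)},
                frames=frames, meta={"edge": edge, "n": n})
    mesh.validate()
    return mesh


# --------------------------------------------------------------------------
# synthetic left ventricle
# --------------------------------------------------------------------------

@dataclass
class LVGeometrySpec:
    """Synthetic rat-scale truncated-ellipsoid LV (clearly synthetic; the
    reference geometry is MRI-derived and unavailable).

    Semi-axes in mm; the wall is the region between the endocardial and
    epicardial ellipsoids, truncated by the base plane z = 0 (apex at
    negative z).  Fiber helix angle runs linearly from ``angle_endo`` at the
    endocardium to ``angle_epi`` at the epicardium, measured against the
    circumferential direction.
    """

    a_endo: float = 2.5
    c_endo: float = 4.5
    a_epi: float = 4.25
    c_epi: float = 6.25
    target_size: float = 1.5          # mm
    angle_endo: float = 80.0          # deg
    angle_epi: float = -70.0          # deg
    element_type: str = "tet4"        # "tet4" | "hex8"
    n_stimulus: int = 7

    def __post_init__(self):
        if self.a_epi <= self.a_endo or self.c_epi <= self.c_endo:
            raise ValueError("epicardial semi-axes must exceed endocardial ones")
        if self.target_size <= 0:
            raise ValueError("target size must be positive")
        for ang in (self.angle_endo, self.angle_epi):
            if not (-90.0 < ang <= 90.0):
                raise ValueError("fiber angles must lie in (-90, 90] degrees")

    def divisions(self):
        """(n_theta, n_v, n_w) resolved from the target element size."""
        a_mid = 0.5 * (self.a_endo + self.a_epi)
        c_mid = 0.5 * (self.c_endo + self.c_epi)
        circ = 2.0 * np.pi * a_mid
        arc = 0.25 * np.pi * (a_mid + c_mid)          # quarter-ellipse estimate
        wall = 0.5 * ((self.a_epi - self.a_endo) + (self.c_epi - self.c_endo))
        n_theta = max(8, int(round(circ / self.target_size)))
        n_theta += n_theta % 2                         # parity split needs even
        n_v = max(3, int(round(arc / self.target_size)))
        n_w = max(2, int(round(wall / self.target_size)))
        return n_theta, n_v, n_w

    def surface_point(self, theta, v, w):
        """Point at longitude theta, colatitude v (0=apex .. pi/2=base),
        transmural fraction w (0=endo, 1=epi)."""
        a = (1.0 - w) * self.a_endo + w * self.a_epi
        c = (1.0 - w) * self.c_endo + w * self.c_epi
        return np.stack([a * np.sin(v) * np.cos(theta),
                         a * np.sin(v) * np.sin(theta),
                         -c * np.cos(v)], axis=-1)


# 5-tet decomposition of a hex, alternating parity for face conformity
_TET_SPLIT_EVEN = [(0, 1, 3, 4), (2, 3, 1, 6), (5, 4, 6, 1), (7, 6, 4, 3),
                   (1, 3, 4, 6)]
_TET_SPLIT_ODD = [(1, 2, 0, 5), (3, 0, 2, 7), (4, 5, 7, 0), (6, 7, 5, 2),
                  (0, 2, 5, 7)]


def make_lv(spec: LVGeometrySpec | None = None) -> Mesh:
    """Build the truncated-ellipsoid LV shell mesh.

    The structured (theta, v, w) grid collapses to a pole line at the apex;
    pole-adjacent cells are wedges (degenerate sub-tets are dropped for the
    tet4 variant, kept as collapsed hexes for hex8).  Node sets: ``base``
    (all base-ring nodes, mechanically fixed), ``apex`` (epicardial apex
    probe node A), ``stimulus`` (contiguous patch of ``n_stimulus`` nodes on
    the basal endocardial rim).
    """
    spec = spec or LVGeometrySpec()
    n_t, n_v, n_w = spec.divisions()
    thetas = np.arange(n_t) * (2.0 * np.pi / n_t)
    vs = np.linspace(0.0, np.pi / 2.0, n_v + 1)
    ws = np.linspace(0.0, 1.0, n_w + 1)

    # node numbering: pole line first (one node per w layer), then rings
    points = []
    node_theta, node_v, node_w = [], [], []
    nid = np.full((n_v + 1, n_t, n_w + 1), -1, dtype=int)
    for k, w in enumerate(ws):
        points.append(spec.surface_point(0.0, 0.0, w))
        node_theta.append(np.nan)
        node_v.append(0.0)
        node_w.append(w)
        nid[0, :, k] = k
    idx = n_w + 1
    for i in range(1, n_v + 1):
        for j in range(n_t):
            for k in range(n_w + 1):
                points.append(spec.surface_point(thetas[j], vs[i], ws[k]))
                node_theta.append(thetas[j])
                node_v.append(vs[i])
                node_w.append(ws[k])
                nid[i, j, k] = idx
                idx += 1
    points = np.asarray(points)

    hexes, parities = [], []
    for i in range(n_v):
        for j in range(n_t):
            jp = (j + 1) % n_t
            for k in range(n_w):
                corn = [nid[i, j, k], nid[i, jp, k], nid[i + 1, jp, k],
                        nid[i + 1, j, k], nid[i, j, k + 1], nid[i, jp, k + 1],
                        nid[i + 1, jp, k + 1], nid[i + 1, j, k + 1]]
                hexes.append(corn)
                parities.append((i + j + k) % 2)
    hexes = np.asarray(hexes)
    parities = np.asarray(parities)

    if spec.element_type == "hex8":
        cells = hexes
        cell_type = "hex8"
    elif spec.element_type == "tet4":
        tets = []
        for h, par in zip(hexes, parities):
            split = _TET_SPLIT_ODD if par else _TET_SPLIT_EVEN
            for tet in split:
                nodes = h[list(tet)]
                if len(set(nodes.tolist())) < 4:
                    continue                       # collapsed at the pole
                d = points[nodes[1:]] - points[nodes[0]]
                vol = np.linalg.det(d) / 6.0
                if abs(vol) < 1e-12:
                    continue
                if vol < 0:
                    nodes = nodes[[0, 2, 1, 3]]
                tets.append(nodes)
        cells = np.asarray(tets)
        cell_type = "tet4"
    else:
        raise ValueError(f"unknown element type {spec.element_type}")

    x, y, z = points.T
    base = np.flatnonzero(np.abs(z) < 1e-9 * spec.c_epi)
    apex = np.array([n_w])                       # epicardial pole node
    stim = np.array([nid[n_v, j, 0] for j in range(min(spec.n_stimulus, n_t))])
    mesh = Mesh(points=points, cells=cells, cell_type=cell_type,
                node_sets={"base": base, "apex": apex, "stimulus": stim},
                meta={"spec": spec, "node_theta": np.asarray(node_theta),
                      "node_v": np.asarray(node_v),
                      "node_w": np.asarray(node_w),
                      "divisions": (n_t, n_v, n_w)})
    assign_fibers(mesh, spec)
    mesh.validate()
    return mesh


def helix_angle(d, spec: LVGeometrySpec) -> np.ndarray:
    """Linear transmural helix angle [deg]: d=0 endo -> angle_endo, d=1 epi."""
    return spec.angle_endo + np.asarray(d) * (spec.angle_epi - spec.angle_endo)


def assign_fibers(mesh: Mesh, spec: LVGeometrySpec) -> Mesh:
    """Attach rule-based per-element fiber/sheet frames to an LV mesh.

    The fiber direction is the circumferential direction rotated by the
    transmural helix angle about the local transmural (radial) axis; the
    sheet direction is transmural (standard rule-based choice).  The
    circumferential direction is undefined on the apex axis itself; pole-
    adjacent elements use their (off-axis) centroid longitude, which is
    always well defined.
    """
    cen = mesh.points[mesh.cells].mean(axis=1)
    w_nodes = mesh.meta["node_w"]
    d = w_nodes[mesh.cells].mean(axis=1)
    theta = np.arctan2(cen[:, 1], cen[:, 0])
    rho = np.hypot(cen[:, 0], cen[:, 1])
    # colatitude of the centroid on the mid-wall ellipsoid (for the radial dir)
    a_mid = (1.0 - d) * spec.a_endo + d * spec.a_epi
    c_mid = (1.0 - d) * spec.c_endo + d * spec.c_epi
    v = np.arctan2(rho / a_mid, np.clip(-cen[:, 2], 1e-12, None) / c_mid)

    circ = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    trans = spec.surface_point(theta, v, 1.0) - spec.surface_point(theta, v, 0.0)
    trans /= np.linalg.norm(trans, axis=-1, keepdims=True)
    lon = np.cross(trans, circ)
    lon /= np.linalg.norm(lon, axis=-1, keepdims=True)
    # orient longitudinal apex -> base
    flip = np.sign(lon[:, 2:3] + 1e-300)
    lon = lon * np.where(flip == 0, 1.0, flip)

    ang = np.deg2rad(helix_angle(d, spec))
    f0 = np.cos(ang)[:, None] * circ + np.sin(ang)[:, None] * lon
    mesh.frames = make_frame(f0, trans)
    mesh.meta["transmural_depth"] = d
    return mesh
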