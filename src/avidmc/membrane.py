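"""Triangulated fluid-membrane patch with Helfrich energetics.

The membrane is a fixed-connectivity triangulated surface, periodic in the
(x, y) plane, carrying a discrete Helfrich Hamiltonian

    E = (kappa/2) * sum_v (2 H_v)^2 A_v  +  E_area(A)

where the integral mean curvature at a vertex is discretized with cotangent
weights and barycentric dual areas (Meyer-style scheme).  The area term is
either a tension ``sigma * (A - A_p)`` or a stiff harmonic restraint that
clamps the curvilinear area to a target value; the clamp is how presets
impose a prescribed excess area A_ex = (A - A_p)/A at fixed projected area.

Membrane fluidity is carried by the mobile receptors; link connectivity is
fixed.  Closed meshes (``box=None``, e.g. spheres used to certify the
curvature discretization against the 8*pi*kappa result) use the same code
path without periodic wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MembraneMesh",
    "LatticeInfo",
    "TopologyReport",
    "helfrich_energy",
    "bending_energy",
    "area_energy",
    "total_area",
    "excess_area",
    "vertex_move",
    "VertexMoveResult",
    "mesh_topology_check",
    "surface_sample",
    "surface_sample_one",
    "triangular_lattice_patch",
]

_DEGENERATE_AREA = 1e-9


@dataclass
class LatticeInfo:
    """Structured-lattice metadata for periodic patches built on a triangular
    lattice (odd rows shifted by half a spacing)."""

    nx: int
    ny: int
    ax: float
    ay: float


@dataclass
class MembraneMesh:
    """Triangulated membrane surface.

    Parameters
    ----------
    vertices : (N, 3) float array, nm
    triangles : (M, 3) int array, consistently oriented vertex triples
    box : float or None
        In-plane periodic box length L (nm); ``None`` for closed meshes.
    kappa : float
        Bending rigidity (k_BT).
    sigma : float
        Frame tension (k_BT/nm^2), used in ``area_mode='tension'``.
    area_mode : {'tension', 'clamp'}
    target_area : float or None
        Clamped curvilinear area (nm^2) when ``area_mode='clamp'``.
    clamp_stiffness : float
        Harmonic restraint stiffness (k_BT per unit relative deviation^2).
    vertex_mass : float
        Mass per vertex (kg); enters the membrane fluctuation entropy only.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    box: Optional[float] = None
    kappa: float = 20.0
    sigma: float = 0.0
    area_mode: str = "tension"
    target_area: Optional[float] = None
    clamp_stiffness: float = 1.0e6
    vertex_mass: float = 5.5e-22
    lattice: Optional[LatticeInfo] = None

    # adjacency caches (built once; connectivity is conserved by all moves)
    _v_tris_indptr: np.ndarray = field(init=False, repr=False)
    _v_tris_data: np.ndarray = field(init=False, repr=False)
    _edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.area_mode not in ("tension", "clamp"):
            raise ValueError(f"unknown area_mode {self.area_mode!r}")
        self._build_adjacency()

    # -- geometry helpers -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    @property
    def n_links(self) -> int:
        return int(self._edges.shape[0])

    @property
    def projected_area(self) -> Optional[float]:
        return None if self.box is None else float(self.box) ** 2

    def _build_adjacency(self) -> None:
        tris = self.triangles
        n = self.n_vertices
        counts = np.bincount(tris.ravel(), minlength=n)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        data = np.empty(indptr[-1], dtype=np.int64)
        cursor = indptr[:-1].copy()
        for t in range(tris.shape[0]):
            for v in tris[t]:
                data[cursor[v]] = t
                cursor[v] += 1
        self._v_tris_indptr = indptr
        self._v_tris_data = data
        e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        self._edges = np.unique(np.sort(e, axis=1), axis=0)
        self._move_caches = {}

    def incident_triangles(self, v: int) -> np.ndarray:
        lo, hi = self._v_tris_indptr[v], self._v_tris_indptr[v + 1]
        return self._v_tris_data[lo:hi]

    def move_cache(self, v: int):
        """Static local-connectivity data for vertex-move energy evaluation
        (built lazily; connectivity is conserved by all moves)."""
        cache = self._move_caches.get(v)
        if cache is None:
            star_v = self.incident_triangles(v)
            ring = np.unique(self.triangles[star_v])
            tri_set = self.star_triangles(ring)
            tris = self.triangles[tri_set]
            vset, inv = np.unique(tris, return_inverse=True)
            ltris = inv.reshape(tris.shape).astype(np.int64)
            in_star = np.isin(tri_set, star_v)
            ring_loc = np.searchsorted(vset, ring)
            v_loc = int(np.searchsorted(vset, v))
            cache = (vset, ltris, in_star, ring_loc, v_loc)
            self._move_caches[v] = cache
        return cache

    def star_triangles(self, verts: Sequence[int]) -> np.ndarray:
        chunks = [self.incident_triangles(v) for v in np.atleast_1d(verts)]
        return np.unique(np.concatenate(chunks))

    def wrap_deltas(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image in-plane displacement for periodic patches."""
        if self.box is not None:
            d = d.copy()
            d[..., :2] -= self.box * np.round(d[..., :2] / self.box)
        return d


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def _triangle_geometry(mesh: MembraneMesh, tri_idx: np.ndarray,
                       positions: np.ndarray):
    """Edge vectors (minimum image), per-corner cotangents and areas for the
    given triangles."""
    tris = mesh.triangles[tri_idx]
    p = positions
    e_ab = mesh.wrap_deltas(p[tris[:, 1]] - p[tris[:, 0]])
    e_ac = mesh.wrap_deltas(p[tris[:, 2]] - p[tris[:, 0]])
    e_bc = e_ac - e_ab
    cross = _cross_rows(e_ab, e_ac)
    double_area = np.sqrt(np.einsum("ij,ij->i", cross, cross))
    area = 0.5 * double_area
    inv = np.where(double_area > 0, 1.0 / np.maximum(double_area, 1e-300), 0.0)
    cot_a = np.einsum("ij,ij->i", e_ab, e_ac) * inv
    cot_b = np.einsum("ij,ij->i", -e_ab, e_bc) * inv
    cot_c = np.einsum("ij,ij->i", -e_ac, -e_bc) * inv
    return tris, e_ab, e_ac, e_bc, area, cot_a, cot_b, cot_c


def _vertex_bending_terms(mesh: MembraneMesh, tri_idx: np.ndarray,
                          positions: np.ndarray, compact: bool = False):
    """Mean-curvature vectors K_v = 1/2 sum (cot+cot)(x_v - x_j) and
    barycentric dual areas, accumulated over ``tri_idx`` only.

    The returned values are exact for any vertex whose full incident-triangle
    star is contained in ``tri_idx``.  With ``compact=True`` returns
    ``(uniq, K_local, A_local, area)`` indexed by the sorted unique vertices
    of the triangle subset (avoids O(N) allocation for local moves).
    """
    tris_g, e_ab, e_ac, e_bc, area, cot_a, cot_b, cot_c = _triangle_geometry(
        mesh, tri_idx, positions)
    if compact:
        uniq, inv = np.unique(tris_g, return_inverse=True)
        tris = inv.reshape(tris_g.shape)
        n = uniq.size
    else:
        tris = tris_g
        n = mesh.n_vertices
    K = np.zeros((n, 3))
    A = np.zeros(n)
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    # corner a is opposite edge (b, c): contributes cot_a * (x_b - x_c) terms
    np.add.at(K, b, 0.5 * cot_a[:, None] * (-e_bc))
    np.add.at(K, c, 0.5 * cot_a[:, None] * e_bc)
    np.add.at(K, a, 0.5 * cot_b[:, None] * (-e_ac))
    np.add.at(K, c, 0.5 * cot_b[:, None] * e_ac)
    np.add.at(K, a, 0.5 * cot_c[:, None] * (-e_ab))
    np.add.at(K, b, 0.5 * cot_c[:, None] * e_ab)
    third = area / 3.0
    np.add.at(A, a, third)
    np.add.at(A, b, third)
    np.add.at(A, c, third)
    if compact:
        return uniq, K, A, area
    return K, A, area


def vertex_bending_energies(mesh: MembraneMesh, verts: np.ndarray,
                            tri_idx: Optional[np.ndarray] = None,
                            positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-vertex bending energies (kappa/2)(2H_v)^2 A_v for ``verts``."""
    verts = np.atleast_1d(np.asarray(verts, dtype=np.int64))
    if positions is None:
        positions = mesh.vertices
    if tri_idx is None:
        tri_idx = mesh.star_triangles(verts)
    uniq, K, A, _ = _vertex_bending_terms(mesh, tri_idx, positions,
                                          compact=True)
    loc = np.searchsorted(uniq, verts)
    Kv = K[loc]
    Av = A[loc]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 0.5 * mesh.kappa * np.einsum("ij,ij->i", Kv, Kv) / Av
    return np.where(Av > 0, e, 0.0)


def bending_energy(mesh: MembraneMesh,
                   positions: Optional[np.ndarray] = None) -> float:
    """Total discrete Helfrich bending energy (k_BT)."""
    if positions is None:
        positions = mesh.vertices
    all_tris = np.arange(mesh.n_triangles)
    K, A, _ = _vertex_bending_terms(mesh, all_tris, positions)
    mask = A > 0
    return float(0.5 * mesh.kappa *
                 np.sum(np.einsum("ij,ij->i", K[mask], K[mask]) / A[mask]))


def total_area(mesh: MembraneMesh,
               positions: Optional[np.ndarray] = None) -> float:
    """Curvilinear area A (nm^2)."""
    if positions is None:
        positions = mesh.vertices
    *_, area, _, _, _ = _triangle_geometry(
        mesh, np.arange(mesh.n_triangles), positions)
    return float(area.sum())


def area_energy(mesh: MembraneMesh, area: float) -> float:
    """Area-dependent part of the Hamiltonian (k_BT)."""
    if mesh.area_mode == "clamp":
        if mesh.target_area is None:
            raise ValueError("area_mode='clamp' requires target_area")
        rel = (area - mesh.target_area) / mesh.target_area
        return 0.5 * mesh.clamp_stiffness * rel * rel
    ap = mesh.projected_area
    if ap is None:
        return mesh.sigma * area
    return mesh.sigma * (area - ap)


def helfrich_energy(mesh: MembraneMesh,
                    positions: Optional[np.ndarray] = None) -> float:
    """Bending plus area energy of the full surface (k_BT).

    Invariant under rigid in-plane translation (periodic wrap) and under
    vertex relabeling.
    """
    a = total_area(mesh, positions)
    return bending_energy(mesh, positions) + area_energy(mesh, a)


def excess_area(mesh: MembraneMesh,
                positions: Optional[np.ndarray] = None) -> float:
    """A_ex = (A - A_p)/A, the area stored in undulations."""
    ap = mesh.projected_area
    if ap is None or ap <= 0:
        raise ValueError("excess area requires a periodic patch (A_p > 0)")
    a = total_area(mesh, positions)
    if a < ap * (1.0 - 1e-9):
        raise ValueError(f"unphysical configuration: A={a} < A_p={ap}")
    return max(0.0, (a - ap) / a)


# ---------------------------------------------------------------------------
# trial moves
# ---------------------------------------------------------------------------

@dataclass
class VertexMoveResult:
    delta_energy: float
    delta_area: float
    ok: bool
    reason: str = ""


def _local_ring_terms(mesh: MembraneMesh, p: np.ndarray, ltris: np.ndarray,
                      in_star: np.ndarray, ring_loc: np.ndarray):
    """Ring bending energy and star-triangle areas from local coordinates."""
    a, b, c = ltris[:, 0], ltris[:, 1], ltris[:, 2]
    e_ab = p[b] - p[a]
    e_ac = p[c] - p[a]
    if mesh.box is not None:
        L = mesh.box
        e_ab[:, :2] -= L * np.round(e_ab[:, :2] / L)
        e_ac[:, :2] -= L * np.round(e_ac[:, :2] / L)
    e_bc = e_ac - e_ab
    cross = _cross_rows(e_ab, e_ac)
    double_area = np.sqrt(np.einsum("ij,ij->i", cross, cross))
    area = 0.5 * double_area
    inv = 1.0 / np.maximum(double_area, 1e-300)
    cot_a = np.einsum("ij,ij->i", e_ab, e_ac) * inv
    cot_b = -np.einsum("ij,ij->i", e_ab, e_bc) * inv
    cot_c = np.einsum("ij,ij->i", e_ac, e_bc) * inv
    nv = p.shape[0]
    K = np.zeros((nv, 3))
    A = np.zeros(nv)
    np.add.at(K, b, 0.5 * cot_a[:, None] * (-e_bc))
    np.add.at(K, c, 0.5 * cot_a[:, None] * e_bc)
    np.add.at(K, a, 0.5 * cot_b[:, None] * (-e_ac))
    np.add.at(K, c, 0.5 * cot_b[:, None] * e_ac)
    np.add.at(K, a, 0.5 * cot_c[:, None] * (-e_ab))
    np.add.at(K, b, 0.5 * cot_c[:, None] * e_ab)
    third = area / 3.0
    np.add.at(A, a, third)
    np.add.at(A, b, third)
    np.add.at(A, c, third)
    Kr, Ar = K[ring_loc], A[ring_loc]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 0.5 * mesh.kappa * np.einsum("ij,ij->i", Kr, Kr) / Ar
    return float(np.where(Ar > 0, e, 0.0).sum()), area[in_star]


def vertex_move(mesh: MembraneMesh, vertex_index: int,
                displacement: np.ndarray,
                current_area: Optional[float] = None) -> VertexMoveResult:
    """Energy change of a trial vertex displacement, without mutating state.

    The local evaluation (star of the vertex plus its one-ring) equals a
    global energy recomputation to numerical tolerance, because the cotangent
    mean curvature at a vertex depends only on its one-ring positions.
    """
    v = int(vertex_index)
    disp = np.asarray(displacement, dtype=np.float64)
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement must be finite")
    vset, ltris, in_star, ring_loc, v_loc = mesh.move_cache(v)

    p_local = mesh.vertices[vset]
    e_before, area_star_before = _local_ring_terms(
        mesh, p_local, ltris, in_star, ring_loc)
    p_new = p_local.copy()
    p_new[v_loc] += disp
    e_after, area_star_after = _local_ring_terms(
        mesh, p_new, ltris, in_star, ring_loc)
    if np.any(area_star_after < _DEGENERATE_AREA):
        return VertexMoveResult(math.inf, 0.0, False, "degenerate triangle")

    d_area = float(area_star_after.sum() - area_star_before.sum())
    if current_area is None:
        current_area = total_area(mesh)
    d_e = (e_after - e_before
           + area_energy(mesh, current_area + d_area)
           - area_energy(mesh, current_area))
    return VertexMoveResult(float(d_e), d_area, True)


# ---------------------------------------------------------------------------
# topology audit
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    ok: bool
    n_vertices: int
    n_links: int
    n_triangles: int
    defects: list

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def mesh_topology_check(mesh: MembraneMesh) -> TopologyReport:
    """Verify manifoldness and orientation consistency.  Pure function.

    For a closed (periodic or spherical) surface every undirected link must be
    shared by exactly two triangles, and every directed edge must appear
    exactly once (consistent global orientation).
    """
    defects = []
    tris = mesh.triangles
    directed = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    d_unique, d_counts = np.unique(directed, axis=0, return_counts=True)
    dup = d_unique[d_counts > 1]
    for e in dup[:20]:
        defects.append(("orientation", tuple(int(x) for x in e),
                        "directed edge repeated"))
    und = np.sort(directed, axis=1)
    u_unique, u_counts = np.unique(und, axis=0, return_counts=True)
    bad = u_unique[u_counts != 2]
    for e in bad[:20]:
        defects.append(("manifold", tuple(int(x) for x in e),
                        f"link shared by {int(u_counts[np.all(u_unique == e, axis=1)][0])} triangles"))
    used = np.unique(tris.ravel())
    if used.size != mesh.n_vertices:
        defects.append(("isolated", None, "vertices not referenced by any triangle"))
    return TopologyReport(len(defects) == 0, mesh.n_vertices, mesh.n_links,
                          mesh.n_triangles, defects)


# ---------------------------------------------------------------------------
# structured-lattice construction
# ---------------------------------------------------------------------------

def triangular_lattice_patch(L: float, nx: int, ny: int, **mesh_kwargs) -> MembraneMesh:
    """Flat periodic patch on a triangular lattice (odd rows offset by ax/2).

    ``ny`` must be even so the periodic wrap in y preserves the row parity.
    The resulting closed (toroidal) triangulation has N_links = 3 N_v and
    N_triangles = 2 N_v.
    """
    if ny % 2 != 0:
        raise ValueError("ny must be even for a periodic triangular lattice")
    ax = L / nx
    ay = L / ny
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    xs = (ii + 0.5 * (jj % 2)) * ax
    ys = jj * ay
    verts = np.zeros((nx * ny, 3))
    verts[:, 0] = xs.ravel()
    verts[:, 1] = ys.ravel()

    def vid(i, j):
        return (j % ny) * nx + (i % nx)

    tris = []
    for j in range(ny):
        for i in range(nx):
            if j % 2 == 0:
                tris.append((vid(i, j), vid(i + 1, j), vid(i, j + 1)))
                tris.append((vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)))
            else:
                tris.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
                tris.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    mesh_kwargs.setdefault("box", float(L))
    return MembraneMesh(vertices=verts, triangles=np.asarray(tris),
                        lattice=LatticeInfo(nx=nx, ny=ny, ax=ax, ay=ay),
                        **mesh_kwargs)


# ---------------------------------------------------------------------------
# structured-lattice surface interpolation
# ---------------------------------------------------------------------------

@dataclass
class SurfaceSample:
    """Interpolated surface data at in-plane query points."""

    nodes: np.ndarray     # (Q, 3) vertex ids of the containing triangles
    weights: np.ndarray   # (Q, 3) barycentric weights
    z: np.ndarray         # (Q,) surface height
    normals: np.ndarray   # (Q, 3) unit normals, +z oriented
    e1xy: np.ndarray      # (Q, 2) in-plane edge vectors of the triangle
    e2xy: np.ndarray

    def reevaluate(self, zv: np.ndarray):
        """Height and normal for new vertex heights ``zv`` (same triangles)."""
        z_nodes = zv[self.nodes]
        z = np.einsum("qk,qk->q", self.weights, z_nodes)
        dz1 = z_nodes[:, 1] - z_nodes[:, 0]
        dz2 = z_nodes[:, 2] - z_nodes[:, 0]
        nrm = np.empty((self.nodes.shape[0], 3))
        nrm[:, 0] = self.e1xy[:, 1] * dz2 - dz1 * self.e2xy[:, 1]
        nrm[:, 1] = dz1 * self.e2xy[:, 0] - self.e1xy[:, 0] * dz2
        nrm[:, 2] = (self.e1xy[:, 0] * self.e2xy[:, 1]
                     - self.e1xy[:, 1] * self.e2xy[:, 0])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        nrm[nrm[:, 2] < 0] *= -1.0
        return z, nrm


def surface_sample(mesh: MembraneMesh, xy: np.ndarray) -> "SurfaceSample":
    """Locate in-plane points on a lattice patch and interpolate the surface.

    Returns a :class:`SurfaceSample` with the containing-triangle vertex ids,
    barycentric weights, interpolated height and unit surface normal
    (+z oriented) per query.  Only available for meshes built on the
    structured triangular lattice (``mesh.lattice`` set).
    """
    lat = mesh.lattice
    if lat is None:
        raise ValueError("surface_sample requires a structured lattice mesh")
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    L = mesh.box
    x = np.mod(xy[:, 0], L)
    y = np.mod(xy[:, 1], L)
    j = np.floor(y / lat.ay).astype(np.int64)
    f = y / lat.ay - j
    j = np.mod(j, lat.ny)
    odd = (j % 2).astype(bool)
    s = x / lat.ax - np.where(odd, 0.5, 0.0)
    t = s - 0.5 * f
    i = np.floor(t).astype(np.int64)
    w = t - i
    up = w <= (1.0 - f)

    nodes = np.empty((xy.shape[0], 3), dtype=np.int64)
    # local 2-D coordinates of the triangle corners, in nm, relative to a
    # common frame (s measured on row j's grid)
    loc = np.empty((xy.shape[0], 3, 2))
    jp = np.mod(j + 1, lat.ny)

    def vid(ii, jj):
        return jj * lat.nx + np.mod(ii, lat.nx)

    # even rows, up triangle: (i,j),(i+1,j),(i,j+1) with apex at s=i+0.5
    # odd rows,  up triangle: (i,j),(i+1,j),(i+1,j+1) with apex at s=i+0.5
    up_apex_even = vid(i, jp)
    up_apex_odd = vid(i + 1, jp)
    m_up = up
    nodes[m_up, 0] = vid(i, j)[m_up]
    nodes[m_up, 1] = vid(i + 1, j)[m_up]
    nodes[m_up, 2] = np.where(odd, up_apex_odd, up_apex_even)[m_up]
    loc[m_up, 0] = np.stack([i * lat.ax, np.zeros_like(f)], axis=1)[m_up]
    loc[m_up, 1] = np.stack([(i + 1.0) * lat.ax, np.zeros_like(f)], axis=1)[m_up]
    loc[m_up, 2] = np.stack([(i + 0.5) * lat.ax, np.full_like(f, lat.ay)], axis=1)[m_up]

    # down triangle right of up-triangle i:
    # even rows: (i+1,j),(i+1,j+1),(i,j+1) -> s-coords i+1, i+1.5, i+0.5
    # odd rows:  (i+1,j),(i+2,j+1),(i+1,j+1) -> s-coords i+1, i+1.5, i+0.5
    m_dn = ~up
    dn_b_even, dn_c_even = vid(i + 1, jp), vid(i, jp)
    dn_b_odd, dn_c_odd = vid(i + 2, jp), vid(i + 1, jp)
    nodes[m_dn, 0] = vid(i + 1, j)[m_dn]
    nodes[m_dn, 1] = np.where(odd, dn_b_odd, dn_b_even)[m_dn]
    nodes[m_dn, 2] = np.where(odd, dn_c_odd, dn_c_even)[m_dn]
    loc[m_dn, 0] = np.stack([(i + 1.0) * lat.ax, np.zeros_like(f)], axis=1)[m_dn]
    loc[m_dn, 1] = np.stack([(i + 1.5) * lat.ax, np.full_like(f, lat.ay)], axis=1)[m_dn]
    loc[m_dn, 2] = np.stack([(i + 0.5) * lat.ax, np.full_like(f, lat.ay)], axis=1)[m_dn]

    # barycentric weights in the local frame
    px = s * lat.ax
    py = f * lat.ay
    x0, y0 = loc[:, 0, 0], loc[:, 0, 1]
    x1, y1 = loc[:, 1, 0], loc[:, 1, 1]
    x2, y2 = loc[:, 2, 0], loc[:, 2, 1]
    det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
    w0 = ((y1 - y2) * (px - x2) + (x2 - x1) * (py - y2)) / det
    w1 = ((y2 - y0) * (px - x2) + (x0 - x2) * (py - y2)) / det
    w2 = 1.0 - w0 - w1
    weights = np.stack([w0, w1, w2], axis=1)

    e1xy = np.stack([x1 - x0, y1 - y0], axis=1)
    e2xy = np.stack([x2 - x0, y2 - y0], axis=1)
    sample = SurfaceSample(nodes=nodes, weights=weights,
                           z=np.zeros(xy.shape[0]),
                           normals=np.zeros((xy.shape[0], 3)),
                           e1xy=e1xy, e2xy=e2xy)
    sample.z, sample.normals = sample.reevaluate(mesh.vertices[:, 2])
    return sample


def surface_sample_one(mesh: MembraneMesh, x: float, y: float) -> "SurfaceSample":
    """Scalar fast path of :func:`surface_sample` for a single query point."""
    lat = mesh.lattice
    if lat is None:
        raise ValueError("surface_sample requires a structured lattice mesh")
    L = mesh.box
    x = x % L
    y = y % L
    jf = y / lat.ay
    j = int(jf)
    f = jf - j
    j %= lat.ny
    odd = j % 2
    s = x / lat.ax - (0.5 if odd else 0.0)
    t = s - 0.5 * f
    i = math.floor(t)
    w = t - i
    jp = (j + 1) % lat.ny
    nxl = lat.nx

    def vid(ii, jj):
        return jj * nxl + (ii % nxl)

    if w <= 1.0 - f:      # up triangle: two base corners on row j
        n0, n1 = vid(i, j), vid(i + 1, j)
        n2 = vid(i + 1, jp) if odd else vid(i, jp)
        lx0, lx1, lx2 = i * lat.ax, (i + 1) * lat.ax, (i + 0.5) * lat.ax
        ly0, ly1, ly2 = 0.0, 0.0, lat.ay
    else:                 # down triangle: one base corner on row j
        n0 = vid(i + 1, j)
        n1 = vid(i + 2, jp) if odd else vid(i + 1, jp)
        n2 = vid(i + 1, jp) if odd else vid(i, jp)
        lx0, lx1, lx2 = (i + 1) * lat.ax, (i + 1.5) * lat.ax, (i + 0.5) * lat.ax
        ly0, ly1, ly2 = 0.0, lat.ay, lat.ay
    px, py = s * lat.ax, f * lat.ay
    det = (ly1 - ly2) * (lx0 - lx2) + (lx2 - lx1) * (ly0 - ly2)
    w0 = ((ly1 - ly2) * (px - lx2) + (lx2 - lx1) * (py - ly2)) / det
    w1 = ((ly2 - ly0) * (px - lx2) + (lx0 - lx2) * (py - ly2)) / det
    w2 = 1.0 - w0 - w1
    zv = mesh.vertices[:, 2]
    z0, z1, z2 = zv[n0], zv[n1], zv[n2]
    e1x, e1y, dz1 = lx1 - lx0, ly1 - ly0, z1 - z0
    e2x, e2y, dz2 = lx2 - lx0, ly2 - ly0, z2 - z0
    nx_ = e1y * dz2 - dz1 * e2y
    ny_ = dz1 * e2x - e1x * dz2
    nz_ = e1x * e2y - e1y * e2x
    nn = math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
    nx_, ny_, nz_ = nx_ / nn, ny_ / nn, nz_ / nn
    if nz_ < 0:
        nx_, ny_, nz_ = -nx_, -ny_, -nz_
    return SurfaceSample(
        nodes=np.array([[n0, n1, n2]], dtype=np.int64),
        weights=np.array([[w0, w1, w2]]),
        z=np.array([w0 * z0 + w1 * z1 + w2 * z2]),
        normals=np.array([[nx_, ny_, nz_]]),
        e1xy=np.array([[e1x, e1y]]),
        e2xy=np.array([[e2x, e2y]]))
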