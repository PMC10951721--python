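"""Hexahedral wall meshing of a centerline tree.

Each branch is swept as a thick-walled tube: structured node grid
``(station, radial layer, circumferential index)`` with parallel-transport
frames along the centerline.  End-to-end continuations (``attach_arclength
== 1.0``) share the interface node ring with the parent (welded, literally
watertight).  Lateral branches are mounted butt-style: the root node
annulus is projected onto the parent's outer surface (a saddle curve, like
a pipe welded on a tank) and every root node carries a bilinear tie
constraint to the parent surface face beneath it; the solver bonds the
two bodies through these constraints.

All mesh coordinates are SI metres; the tree is authored in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import Branch, CenterlineTree, GeometryError

MM_TO_M = 1.0e-3

#: (n_circumferential, n_axial_per_mm, n_radial) used by the pipeline.
DEFAULT_RESOLUTION: tuple[int, float, int] = (16, 0.35, 2)


class MeshError(ValueError):
    """Mesh construction or validation failure."""


@dataclass
class Cap:
    """Artificial lumen cap at a branch end (generated, flagged).

    ``ring`` is the ordered inner node ring; ``orientation`` +1 when the
    outward-of-lumen normal points along the branch tangent (end cap),
    -1 at the start.  ``kind`` is one of ``opening`` (fixed vessel
    truncation), ``weld`` (interface shared with the welded neighbour) or
    ``tie_root`` (lateral mount; its volume-change contribution is
    attributed to the upstream/parent region).
    """

    ring: np.ndarray
    orientation: int
    region: str
    kind: str
    upstream: Optional[str] = None


@dataclass
class Ties:
    """Multi-point constraints bonding lateral branch roots to parents."""

    slave_nodes: np.ndarray    # (ns,)
    master_nodes: np.ndarray   # (ns, 4)
    weights: np.ndarray        # (ns, 4)

    @classmethod
    def empty(cls) -> "Ties":
        return cls(np.zeros(0, dtype=np.int64),
                   np.zeros((0, 4), dtype=np.int64),
                   np.zeros((0, 4)))

    def __len__(self) -> int:
        return len(self.slave_nodes)


@dataclass
class WallMesh:
    """Labelled hexahedral solid mesh of the arterial wall (SI metres)."""

    points: np.ndarray                      # (n, 3) m
    cells: np.ndarray                       # (m, 8) int64, VTK hexahedron order
    cell_region: np.ndarray                 # (m,) int codes into region_names
    region_names: list[str]
    facet_sets: dict[str, np.ndarray]       # name -> (k, 4) node quads
    inner_facets_by_region: dict[str, np.ndarray] = field(default_factory=dict)
    caps: list[Cap] = field(default_factory=list)
    ties: Ties = field(default_factory=Ties.empty)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def region_of_cells(self) -> np.ndarray:
        return np.asarray([self.region_names[c] for c in self.cell_region])

    def opening_names(self) -> list[str]:
        return sorted(n for n in self.facet_sets if n.startswith("opening_"))

    def opening_nodes(self) -> np.ndarray:
        """Unique node ids belonging to any opening facet set."""
        quads = [self.facet_sets[n] for n in self.opening_names()]
        if not quads:
            return np.zeros(0, dtype=np.int64)
        return np.unique(np.concatenate([q.ravel() for q in quads]))

    # -- validation -----------------------------------------------------

    def jacobians(self) -> np.ndarray:
        """Corner Jacobian determinants, (m, 8)."""
        return _corner_jacobians(self.points, self.cells)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise MeshError("non-finite node coordinates")
        det = self.jacobians()
        if np.any(det <= 0):
            bad = int(np.argmin(det.min(axis=1)))
            region = self.region_names[self.cell_region[bad]]
            raise MeshError(
                f"non-positive Jacobian in cell {bad} (region {region!r}); "
                "the swept tube self-intersects or the resolution is too coarse")
        # connectivity (tie constraints bond lateral branches)
        n = self.n_nodes
        rows = np.repeat(self.cells[:, 0], 7)
        cols = self.cells[:, 1:].ravel()
        if len(self.ties):
            rows = np.concatenate([rows, self.ties.slave_nodes])
            cols = np.concatenate([cols, self.ties.master_nodes[:, 0]])
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise MeshError(f"mesh is not connected ({ncomp} components)")


def _corner_jacobians(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Jacobian determinant of the trilinear map at the 8 hex corners."""
    corners = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
    X = points[cells]  # (m, 8, 3)
    det = np.empty((len(cells), 8))
    for c, (xi, eta, zeta) in enumerate(corners):
        dN = _hex_shape_gradients(xi, eta, zeta)          # (8, 3)
        J = np.einsum("eai,aj->eji", X, dN)               # (m, 3, 3)
        det[:, c] = np.linalg.det(J)
    return det


def _hex_shape_gradients(xi: float, eta: float, zeta: float) -> np.ndarray:
    """d N_a / d (xi, eta, zeta) for the 8-node hex, VTK corner order."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
    g = np.empty((8, 3))
    for a, (sx, sy, sz) in enumerate(signs):
        g[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
        g[a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta)
        g[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta)
    return g


# ---------------------------------------------------------------------------
# sweeping machinery
# ---------------------------------------------------------------------------

def _parallel_transport(tangents: np.ndarray, e1_0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimal-twist frames along a tangent sequence."""
    n = len(tangents)
    e1 = np.empty((n, 3))
    e2 = np.empty((n, 3))
    v = e1_0 - np.dot(e1_0, tangents[0]) * tangents[0]
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise GeometryError("initial frame vector parallel to tangent")
    e1[0] = v / nv
    e2[0] = np.cross(tangents[0], e1[0])
    for k in range(1, n):
        t0, t1 = tangents[k - 1], tangents[k]
        c = np.cross(t0, t1)
        s = np.linalg.norm(c)
        d = float(np.dot(t0, t1))
        if s < 1e-12:
            e1[k] = e1[k - 1]
        else:
            axis = c / s
            e1[k] = _rotate(e1[k - 1], axis, np.arctan2(s, d))
        e1[k] -= np.dot(e1[k], t1) * t1
        e1[k] /= np.linalg.norm(e1[k])
        e2[k] = np.cross(t1, e1[k])
    return e1, e2


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


@dataclass
class _BranchMesh:
    """Book-keeping for one swept branch (coordinates still in mm)."""

    branch: Branch
    stations: np.ndarray       # (K+1,) arclengths mm
    centers: np.ndarray        # (K+1, 3)
    tangents: np.ndarray       # (K+1, 3)
    e1: np.ndarray
    e2: np.ndarray
    radii: np.ndarray          # (K+1,) inner radius at stations
    ids: np.ndarray            # (K+1, n_rad+1, n_circ) node ids
    start_kind: str = "opening"    # opening | weld | tie_root
    end_kind: str = "opening"      # opening | weld_parent (shared with child)

    def nearest(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Arclength and closest point on the station polyline."""
        P = self.centers
        seg = P[1:] - P[:-1]
        L2 = np.einsum("ij,ij->i", seg, seg)
        t = np.clip(np.einsum("ij,ij->i", x - P[:-1], seg) / np.maximum(L2, 1e-30),
                    0.0, 1.0)
        proj = P[:-1] + t[:, None] * seg
        d2 = np.einsum("ij,ij->i", x - proj, x - proj)
        i = int(np.argmin(d2))
        s = self.stations[i] + t[i] * (self.stations[i + 1] - self.stations[i])
        return float(s), proj[i]

    def outer_radius_at(self, s: float) -> float:
        frac = np.clip(s / self.stations[-1], 0.0, 1.0)
        return float(self.branch.radius_at(frac)) + self.branch.wall_thickness

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (center, e1, e2) at arclength s."""
        f = np.clip(s / self.stations[-1], 0.0, 1.0) * (len(self.stations) - 1)
        i = int(np.clip(np.floor(f), 0, len(self.stations) - 2))
        w = f - i
        C = (1 - w) * self.centers[i] + w * self.centers[i + 1]
        e1 = (1 - w) * self.e1[i] + w * self.e1[i + 1]
        e2 = (1 - w) * self.e2[i] + w * self.e2[i + 1]
        e1 /= np.linalg.norm(e1)
        e2 -= np.dot(e2, e1) * e1
        e2 /= np.linalg.norm(e2)
        return C, e1, e2


def mesh_tree(tree: CenterlineTree,
              resolution: tuple[int, float, int] = DEFAULT_RESOLUTION) -> WallMesh:
    """Sweep every branch of ``tree`` into a labelled hexahedral wall mesh.

    ``resolution`` is ``(n_circumferential, n_axial_per_mm, n_radial)``.
    Deterministic: identical inputs give identical meshes.
    """
    n_circ, n_ax_per_mm, n_rad = int(resolution[0]), float(resolution[1]), int(resolution[2])
    if n_circ < 8:
        raise MeshError(
            f"n_circumferential={n_circ} is too coarse to resolve a tube; need >= 8")
    if n_rad < 1:
        raise MeshError("n_radial must be >= 1")
    if n_ax_per_mm <= 0:
        raise MeshError("n_axial_per_mm must be > 0")

    order = _topological_order(tree)
    built: dict[str, _BranchMesh] = {}
    points: list[np.ndarray] = []        # growing (chunks)
    n_nodes = 0
    cells: list[np.ndarray] = []
    cell_region: list[np.ndarray] = []
    region_names = [b.name for b in order]
    inner_facets: dict[str, np.ndarray] = {}
    outer_facets: list[np.ndarray] = []
    facet_sets: dict[str, np.ndarray] = {}
    caps: list[Cap] = []
    tie_slaves: list[np.ndarray] = []
    tie_masters: list[np.ndarray] = []
    tie_weights: list[np.ndarray] = []

    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    for code, branch in enumerate(order):
        pos, s_dense = branch.polyline()
        L = s_dense[-1]
        K = max(2, int(round(L * n_ax_per_mm)))
        stations = np.linspace(0.0, L, K + 1)
        centers = np.empty((K + 1, 3))
        for c in range(3):
            centers[:, c] = np.interp(stations, s_dense, pos[:, c])
        tangents = np.gradient(centers, stations, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        radii = np.asarray(branch.radius_at(stations / L), dtype=float)
        t_wall = branch.wall_thickness

        _check_self_intersection(branch, centers, stations, radii + t_wall)

        parent_bm = built.get(branch.parent) if branch.parent else None
        if branch.is_weld:
            assert parent_bm is not None
            # continue the parent's frame across the interface
            pe1 = parent_bm.e1[-1]
            pt = parent_bm.tangents[-1]
            c = np.cross(pt, tangents[0])
            sn = np.linalg.norm(c)
            if sn < 1e-12:
                e1_0 = pe1
            else:
                e1_0 = _rotate(pe1, c / sn, np.arctan2(sn, float(np.dot(pt, tangents[0]))))
            e1, e2 = _parallel_transport(tangents, e1_0)
        else:
            seed = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(seed, tangents[0])) > 0.9:
                seed = np.array([0.0, 1.0, 0.0])
            e1, e2 = _parallel_transport(tangents, seed)

        # nominal node positions (K+1, n_rad+1, n_circ, 3)
        rho = radii[:, None, None] + t_wall * (
            np.arange(n_rad + 1)[None, :, None] / n_rad)          # (K+1, n_rad+1, 1)
        ring = (cos_t[:, None] * e1[:, None, None, :]
                + sin_t[:, None] * e2[:, None, None, :])           # broadcast below
        # build explicitly to keep shapes clear
        nominal = (centers[:, None, None, :]
                   + rho[:, :, :, None]
                   * (np.cos(theta)[None, None, :, None] * e1[:, None, None, :]
                      + np.sin(theta)[None, None, :, None] * e2[:, None, None, :]))

        ids = np.full((K + 1, n_rad + 1, n_circ), -1, dtype=np.int64)
        k_start = 0
        start_kind = "opening"
        if branch.is_weld:
            ids[0] = parent_bm.ids[-1]
            parent_bm.end_kind = "weld_parent"
            k_start = 1
            start_kind = "weld"
        elif branch.parent is not None:
            start_kind = "tie_root"

        new_count = (K + 1 - k_start) * (n_rad + 1) * n_circ
        new_ids = n_nodes + np.arange(new_count, dtype=np.int64)
        ids[k_start:] = new_ids.reshape(K + 1 - k_start, n_rad + 1, n_circ)
        coords = nominal[k_start:].reshape(-1, 3).copy()

        if start_kind == "tie_root":
            # project the root annulus onto the parent outer surface and
            # blend the offset out over a transition length
            d0 = tangents[0]
            root = nominal[0].reshape(-1, 3)
            proj = np.empty_like(root)
            for i, x0 in enumerate(root):
                proj[i] = _project_to_parent_surface(x0, d0, parent_bm, branch.name)
            delta = (proj - root).reshape(n_rad + 1, n_circ, 3)
            L_blend = min(3.0 * (radii[0] + t_wall), 0.6 * L)
            w = np.maximum(0.0, 1.0 - stations / L_blend)          # (K+1,)
            offs = w[:, None, None, None] * delta[None, :, :, :]
            nominal = nominal + offs
            coords = nominal[k_start:].reshape(-1, 3).copy()
            # tie every root node to the parent face beneath it
            sl, ms, ws = _build_ties(nominal[0].reshape(-1, 3),
                                     ids[0].reshape(-1), parent_bm)
            tie_slaves.append(sl)
            tie_masters.append(ms)
            tie_weights.append(ws)

        points.append(coords)
        n_nodes += new_count

        bm = _BranchMesh(branch, stations, centers, tangents, e1, e2, radii, ids,
                         start_kind=start_kind)
        built[branch.name] = bm

        # --- cells -----------------------------------------------------
        jp = (np.arange(n_circ) + 1) % n_circ
        hexes = np.empty((K, n_rad, n_circ, 8), dtype=np.int64)
        for k in range(K):
            for r in range(n_rad):
                hexes[k, r, :, 0] = ids[k, r, :]
                hexes[k, r, :, 1] = ids[k, r + 1, :]
                hexes[k, r, :, 2] = ids[k, r + 1, jp]
                hexes[k, r, :, 3] = ids[k, r, jp]
                hexes[k, r, :, 4] = ids[k + 1, r, :]
                hexes[k, r, :, 5] = ids[k + 1, r + 1, :]
                hexes[k, r, :, 6] = ids[k + 1, r + 1, jp]
                hexes[k, r, :, 7] = ids[k + 1, r, jp]
        cells.append(hexes.reshape(-1, 8))
        cell_region.append(np.full(K * n_rad * n_circ, code, dtype=np.int64))

        # --- lateral facets, oriented away from the centerline ----------
        inner = np.empty((K, n_circ, 4), dtype=np.int64)
        outer = np.empty((K, n_circ, 4), dtype=np.int64)
        for k in range(K):
            inner[k, :, 0] = ids[k, 0, :]
            inner[k, :, 1] = ids[k, 0, jp]
            inner[k, :, 2] = ids[k + 1, 0, jp]
            inner[k, :, 3] = ids[k + 1, 0, :]
            outer[k, :, 0] = ids[k, n_rad, :]
            outer[k, :, 1] = ids[k, n_rad, jp]
            outer[k, :, 2] = ids[k + 1, n_rad, jp]
            outer[k, :, 3] = ids[k + 1, n_rad, :]
        inner_facets[branch.name] = inner.reshape(-1, 4)
        outer_facets.append(outer.reshape(-1, 4))

    # --- openings, caps --------------------------------------------------
    for name, bm in built.items():
        K = len(bm.stations) - 1
        n_rad_l = bm.ids.shape[1] - 1
        for end, k_end, kind in (("start", 0, bm.start_kind),
                                 ("end", K, bm.end_kind)):
            orientation = -1 if end == "start" else 1
            ring = bm.ids[k_end, 0, :]
            if kind == "opening":
                annulus = np.empty((n_rad_l, n_circ, 4), dtype=np.int64)
                jp = (np.arange(n_circ) + 1) % n_circ
                for r in range(n_rad_l):
                    annulus[r, :, 0] = bm.ids[k_end, r, :]
                    annulus[r, :, 1] = bm.ids[k_end, r + 1, :]
                    annulus[r, :, 2] = bm.ids[k_end, r + 1, jp]
                    annulus[r, :, 3] = bm.ids[k_end, r, jp]
                facet_sets[f"opening_{name}_{end}"] = annulus.reshape(-1, 4)
                caps.append(Cap(ring.copy(), orientation, name, "opening"))
            elif kind in ("weld", "weld_parent"):
                caps.append(Cap(ring.copy(), orientation, name, "weld"))
            elif kind == "tie_root":
                caps.append(Cap(ring.copy(), orientation, name, "tie_root",
                                upstream=bm.branch.parent))

    pts = np.concatenate(points, axis=0) * MM_TO_M
    facet_sets["inner_surface"] = np.concatenate(
        [inner_facets[b.name] for b in order], axis=0)
    facet_sets["outer_surface"] = np.concatenate(outer_facets, axis=0)

    ties = Ties(
        np.concatenate(tie_slaves) if tie_slaves else np.zeros(0, dtype=np.int64),
        np.concatenate(tie_masters) if tie_masters else np.zeros((0, 4), dtype=np.int64),
        np.concatenate(tie_weights) if tie_weights else np.zeros((0, 4)))

    mesh = WallMesh(pts, np.concatenate(cells, axis=0),
                    np.concatenate(cell_region), region_names,
                    facet_sets, inner_facets, caps, ties)
    mesh.validate()
    return mesh


def _topological_order(tree: CenterlineTree) -> list[Branch]:
    order: list[Branch] = []
    placed: set[str] = set()
    pending = list(tree.branches)
    while pending:
        progressed = False
        for b in list(pending):
            if b.parent is None or b.parent in placed:
                order.append(b)
                placed.add(b.name)
                pending.remove(b)
                progressed = True
        if not progressed:
            raise GeometryError("cyclic parent relations in tree")
    return order


def _check_self_intersection(branch: Branch, centers: np.ndarray,
                             stations: np.ndarray, outer_radii: np.ndarray) -> None:
    """A swept tube self-intersects when the centerline curvature radius
    drops below the outer tube radius."""
    if len(centers) < 3:
        return
    d1 = np.gradient(centers, stations, axis=0)
    d2 = np.gradient(d1, stations, axis=0)
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(speed ** 3, 1e-30)
    with np.errstate(divide="ignore"):
        r_curv = np.where(kappa > 1e-12, 1.0 / kappa, np.inf)
    if np.any(r_curv < outer_radii):
        raise MeshError(
            f"branch {branch.name!r}: centerline bend radius "
            f"{r_curv.min():.2f} mm is smaller than the outer tube radius; "
            "the swept tube self-intersects")


def _project_to_parent_surface(x0: np.ndarray, d: np.ndarray,
                               parent: _BranchMesh, child_name: str) -> np.ndarray:
    """Slide ``x0`` along -d until it sits on the parent's outer surface."""

    def gap(alpha: float) -> float:
        x = x0 - alpha * d
        s, proj = parent.nearest(x)
        return float(np.linalg.norm(x - proj)) - parent.outer_radius_at(s)

    a_max = parent.outer_radius_at(parent.stations[-1] / 2) + \
        2.0 * parent.branch.wall_thickness + 25.0
    grid = np.linspace(-a_max, a_max, 241)
    vals = np.array([gap(a) for a in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(gap, grid[i], grid[i + 1], xtol=1e-10))
    if not roots:
        raise MeshError(
            f"branch {child_name!r}: root ring does not project onto parent "
            f"{parent.branch.name!r} outer surface")
    alpha = min(roots, key=abs)
    return x0 - alpha * d


def _build_ties(root_coords: np.ndarray, root_ids: np.ndarray,
                parent: _BranchMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear tie of each root node to the parent outer-surface face
    beneath it, located through the parent's (arclength, angle) grid."""
    K = len(parent.stations) - 1
    n_circ = parent.ids.shape[2]
    outer_ids = parent.ids[:, -1, :]                   # (K+1, n_circ)
    slaves = np.asarray(root_ids, dtype=np.int64)
    masters = np.empty((len(slaves), 4), dtype=np.int64)
    weights = np.empty((len(slaves), 4))
    for i, x in enumerate(root_coords):
        s, _ = parent.nearest(x)
        C, e1, e2 = parent.frame_at(s)
        off = x - C
        th = np.arctan2(np.dot(off, e2), np.dot(off, e1)) % (2 * np.pi)
        f = s / parent.stations[-1] * K
        ia = int(np.clip(np.floor(f), 0, K - 1))
        xi = float(np.clip(f - ia, 0.0, 1.0))
        g = th / (2 * np.pi) * n_circ
        jc = int(np.floor(g)) % n_circ
        eta = float(g - np.floor(g))
        jn = (jc + 1) % n_circ
        masters[i] = [outer_ids[ia, jc], outer_ids[ia + 1, jc],
                      outer_ids[ia, jn], outer_ids[ia + 1, jn]]
        weights[i] = [(1 - xi) * (1 - eta), xi * (1 - eta),
                      (1 - xi) * eta, xi * eta]
    return slaves, masters, weights


# ---------------------------------------------------------------------------
# convenience fixtures
# ---------------------------------------------------------------------------

def single_tube_tree(length_mm: float, radius_mm: float, thickness_mm: float,
                     name: str = "ascending_aorta") -> CenterlineTree:
    """A one-branch straight tube along +z (test and oracle fixture)."""
    return CenterlineTree([Branch(
        name,
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length_mm]]),
        np.array([radius_mm, radius_mm]),
        thickness_mm)])
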