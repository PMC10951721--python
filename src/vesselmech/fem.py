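"""Small-strain isotropic linear elasticity on the hexahedral wall mesh.

Discretization: 8-node isoparametric hexahedra with 2×2×2 Gauss
quadrature.  The default integration scheme is *selective reduced*
(mean-dilatation B-bar): the volumetric part of the strain-displacement
operator is replaced by its element average, which prevents volumetric
locking at the nearly incompressible Poisson ratio (ν = 0.45) used for
arterial wall tissue.  Full integration is selectable for comparison.

Boundary conditions follow the structural model: a uniform pressure is
applied as consistent nodal forces on the inner (lumen) surface, all
three displacement components are fixed to zero at every vessel
opening, and lateral branch roots are bonded to their parent's outer
surface through the mesh's bilinear tie constraints (multi-point
constraints eliminated before the solve).

The linear system is solved by sparse direct factorization (SuperLU);
problem sizes here are a few 10^4 unknowns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import MaterialCase
from .meshing import WallMesh, _hex_shape_gradients

_GAUSS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                   [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                  dtype=float) / np.sqrt(3.0)

_M6 = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


class SolverError(RuntimeError):
    """Linear solve failure (singular system or residual above tolerance)."""


@dataclass
class TransientOptions:
    """Newmark-β time integration parameters."""

    time_step: float = 1.0e-3          # s
    total_cycles: float = 1.0          # number of waveform cycles
    cycle_period: float = 1.0          # s per cycle
    density: float = 1100.0            # kg/m3, arterial wall tissue
    newmark_beta: float = 0.25
    newmark_gamma: float = 0.5
    force: bool = False                # override the stability refusal
    output_every: int = 10             # store every n-th step

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")


@dataclass
class SolveOptions:
    backend: str = "fem"
    linear_solver_tolerance: float = 1.0e-9
    integration_scheme: str = "selective_reduced"   # or "full"
    transient: Optional[TransientOptions] = None

    def __post_init__(self) -> None:
        if self.linear_solver_tolerance <= 0:
            raise ValueError("linear_solver_tolerance must be > 0")
        if self.integration_scheme not in ("selective_reduced", "full"):
            raise ValueError(
                f"unknown integration_scheme {self.integration_scheme!r}")


@dataclass
class SolveResult:
    """Displacement and stress fields from one solve."""

    displacement: np.ndarray            # (n, 3) m
    stress: Optional[np.ndarray]        # (m, 3, 3) Pa, cell centroids
    applied_pressure: float             # Pa
    case_id: Optional[int] = None
    backend: str = "fem"
    residual: float = 0.0
    time: Optional[float] = None


@dataclass
class System:
    """Assembled (unconstrained) stiffness operator for one material case."""

    mesh: WallMesh
    case: MaterialCase
    options: SolveOptions
    K: sp.csr_matrix
    M: Optional[sp.csr_matrix] = None


@dataclass
class ConstrainedSystem:
    system: System
    f: np.ndarray                       # (3n,) consistent nodal forces
    fixed_dofs: np.ndarray              # int dof indices, u = 0
    pressure: float


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_moduli(mesh: WallMesh, case: MaterialCase) -> tuple[np.ndarray, np.ndarray]:
    E_by_code = np.array([case.modulus(name) for name in mesh.region_names])
    E = E_by_code[mesh.cell_region]
    nu = case.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return lam, mu


def _batch_B(points: np.ndarray, cells: np.ndarray, scheme: str
             ) -> tuple[list[np.ndarray], np.ndarray]:
    """B matrices (B-bar adjusted per ``scheme``) and detJ per Gauss point.

    Returns ``(B_gp, detJ)`` with ``B_gp`` a list of 8 arrays (ne, 6, 24)
    and ``detJ`` of shape (ne, 8).
    """
    X = points[cells]                                   # (ne, 8, 3)
    ne = len(cells)
    B_gp: list[np.ndarray] = []
    b_rows = np.empty((8, ne, 24))
    detJ = np.empty((ne, 8))
    for g, (xi, eta, zeta) in enumerate(_GAUSS):
        dN = _hex_shape_gradients(xi, eta, zeta)        # (8, 3)
        J = np.einsum("eai,aj->eij", X, dN)
        detJ[:, g] = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        grad = np.einsum("aj,eji->eai", dN, invJ)       # dN_a/dx_i
        B = np.zeros((ne, 6, 24))
        B[:, 0, 0::3] = grad[:, :, 0]
        B[:, 1, 1::3] = grad[:, :, 1]
        B[:, 2, 2::3] = grad[:, :, 2]
        B[:, 3, 0::3] = grad[:, :, 1]
        B[:, 3, 1::3] = grad[:, :, 0]
        B[:, 4, 1::3] = grad[:, :, 2]
        B[:, 4, 2::3] = grad[:, :, 1]
        B[:, 5, 0::3] = grad[:, :, 2]
        B[:, 5, 2::3] = grad[:, :, 0]
        b_rows[g] = B[:, 0] + B[:, 1] + B[:, 2]
        B_gp.append(B)
    if scheme == "selective_reduced":
        vol = detJ.sum(axis=1)                           # (ne,)
        b_bar = np.einsum("gea,eg->ea", b_rows, detJ) / vol[:, None]
        for g in range(8):
            corr = (b_bar - b_rows[g]) / 3.0             # (ne, 24)
            B_gp[g][:, 0] += corr
            B_gp[g][:, 1] += corr
            B_gp[g][:, 2] += corr
    return B_gp, detJ


def assemble_system(mesh: WallMesh, case: MaterialCase,
                    options: SolveOptions | None = None) -> System:
    """Assemble the global stiffness matrix (symmetric positive
    semi-definite before constraints).

    Raises ``KeyError`` naming any mesh region without a modulus in the
    material case.
    """
    options = options or SolveOptions()
    lam, mu = _element_moduli(mesh, case)
    B_gp, detJ = _batch_B(mesh.points, mesh.cells, options.integration_scheme)
    ne = mesh.n_cells
    D = np.zeros((ne, 6, 6))
    D[:, :3, :3] = lam[:, None, None]
    idx = np.arange(3)
    D[:, idx, idx] += 2 * mu[:, None]
    D[:, idx + 3, idx + 3] = mu[:, None]
    Ke = np.zeros((ne, 24, 24))
    for g in range(8):
        BD = np.einsum("eka,ekl->ela", B_gp[g], D)
        Ke += np.einsum("ela,elb->eab", BD, B_gp[g]) * detJ[:, g, None, None]
    edofs = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(edofs, 24, axis=1)
    cols = np.tile(edofs, (1, 24))
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())),
                      shape=(n, n)).tocsr()
    return System(mesh, case, options, K)


def assemble_mass(system: System, density: float) -> sp.csr_matrix:
    """Consistent mass matrix for transient analyses."""
    mesh = system.mesh
    X = mesh.points[mesh.cells]
    ne = mesh.n_cells
    Me = np.zeros((ne, 8, 8))
    for xi, eta, zeta in _GAUSS:
        dN = _hex_shape_gradients(xi, eta, zeta)
        N = _hex_shapes(xi, eta, zeta)
        J = np.einsum("eai,aj->eij", X, dN)
        detJ = np.linalg.det(J)
        Me += np.einsum("a,b->ab", N, N)[None] * detJ[:, None, None]
    Me *= density
    # expand to 3 dofs per node
    Me3 = np.zeros((ne, 24, 24))
    for c in range(3):
        Me3[:, c::3, c::3] = Me
    edofs = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(edofs, 24, axis=1)
    cols = np.tile(edofs, (1, 24))
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((Me3.ravel(), (rows.ravel(), cols.ravel())),
                         shape=(n, n)).tocsr()


def _hex_shapes(xi: float, eta: float, zeta: float) -> np.ndarray:
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                     dtype=float)
    return 0.125 * (1 + signs[:, 0] * xi) * (1 + signs[:, 1] * eta) \
        * (1 + signs[:, 2] * zeta)


# ---------------------------------------------------------------------------
# loads and boundary conditions
# ---------------------------------------------------------------------------

_QGAUSS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3.0)
_QSIGNS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def pressure_forces(points: np.ndarray, facets: np.ndarray, p: float) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure on oriented quads.

    The facet normal follows the node ordering (right-hand rule); the
    mesher orients lumen facets away from the centerline, so a positive
    pressure inflates the vessel.  Returns (n_points, 3).
    """
    f = np.zeros_like(points)
    if len(facets) == 0 or p == 0.0:
        return f
    X = points[facets]                                   # (k, 4, 3)
    for xi, eta in _QGAUSS:
        N = 0.25 * (1 + _QSIGNS[:, 0] * xi) * (1 + _QSIGNS[:, 1] * eta)
        dNdxi = 0.25 * _QSIGNS[:, 0] * (1 + _QSIGNS[:, 1] * eta)
        dNdeta = 0.25 * _QSIGNS[:, 1] * (1 + _QSIGNS[:, 0] * xi)
        x_xi = np.einsum("a,kai->ki", dNdxi, X)
        x_eta = np.einsum("a,kai->ki", dNdeta, X)
        normal = np.cross(x_xi, x_eta)                   # area-weighted
        contrib = p * np.einsum("a,ki->kai", N, normal)  # (k, 4, 3)
        np.add.at(f, facets.ravel(),
                  contrib.reshape(-1, 3))
    return f


def apply_loads_and_bcs(system: System, mesh: WallMesh, p: float
                        ) -> ConstrainedSystem:
    """Uniform pressure on the inner surface; zero displacement at all
    vessel openings."""
    inner = mesh.facet_sets.get("inner_surface")
    if inner is None or len(inner) == 0:
        raise ValueError("mesh has no inner_surface facet set to load")
    f = pressure_forces(mesh.points, inner, p).ravel()
    fixed_nodes = mesh.opening_nodes()
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    return ConstrainedSystem(system, f, fixed_dofs, p)


def _tie_transform(mesh: WallMesh, n_dofs: int) -> tuple[sp.csr_matrix, np.ndarray]:
    """Elimination map T with u_full = T @ u_retained.

    Retained dofs are all non-slave dofs; slave dofs are expressed as the
    bilinear combination of their master-face dofs.
    """
    ties = mesh.ties
    slave_dofs = (3 * ties.slave_nodes[:, None] + np.arange(3)).ravel()
    keep = np.setdiff1d(np.arange(n_dofs), slave_dofs)
    col_of = -np.ones(n_dofs, dtype=np.int64)
    col_of[keep] = np.arange(len(keep))
    rows = list(keep)
    cols = list(col_of[keep])
    vals = [1.0] * len(keep)
    for s, ms, ws in zip(ties.slave_nodes, ties.master_nodes, ties.weights):
        for c in range(3):
            for mnode, w in zip(ms, ws):
                rows.append(3 * s + c)
                cols.append(col_of[3 * mnode + c])
                vals.append(w)
    T = sp.coo_matrix((vals, (rows, cols)), shape=(n_dofs, len(keep))).tocsr()
    return T, keep


def solve_static(constrained: ConstrainedSystem,
                 options: SolveOptions | None = None,
                 prescribed: dict[int, float] | None = None) -> SolveResult:
    """Direct sparse solve of the constrained equilibrium system.

    ``prescribed`` optionally maps dof indices to nonzero boundary
    values (used by patch tests); spec'd openings stay at zero.
    """
    system = constrained.system
    options = options or system.options
    mesh = system.mesh
    n_dofs = 3 * mesh.n_nodes
    T, keep = _tie_transform(mesh, n_dofs)
    K2 = (T.T @ system.K @ T).tocsr()
    f2 = T.T @ constrained.f

    col_of = -np.ones(n_dofs, dtype=np.int64)
    col_of[keep] = np.arange(len(keep))
    bc: dict[int, float] = {int(d): 0.0 for d in constrained.fixed_dofs}
    if prescribed:
        bc.update({int(k): float(v) for k, v in prescribed.items()})
    bc_cols = np.array([col_of[d] for d in bc], dtype=np.int64)
    if np.any(bc_cols < 0):
        raise ValueError("cannot prescribe a tied (slave) dof")
    bc_vals = np.array(list(bc.values()))

    nred = K2.shape[0]
    free = np.setdiff1d(np.arange(nred), bc_cols)
    u_red = np.zeros(nred)
    u_red[bc_cols] = bc_vals
    rhs = f2[free] - K2[free][:, bc_cols] @ bc_vals
    K_ff = K2[free][:, free].tocsc()
    try:
        lu = splu(K_ff)
    except RuntimeError as exc:
        raise SolverError(f"factorization failed: {exc}") from exc
    u_f = lu.solve(rhs)
    u_red[free] = u_f

    res = np.linalg.norm(K_ff @ u_f - rhs)
    scale = max(np.linalg.norm(rhs), 1e-300)
    rel = res / scale if np.linalg.norm(rhs) > 0 else res
    if np.linalg.norm(rhs) > 0 and rel > max(options.linear_solver_tolerance, 1e-8):
        raise SolverError(f"linear solve residual {rel:.2e} above tolerance")

    u = (T @ u_red).reshape(-1, 3)
    stress = recover_stress(mesh, system.case, u,
                            scheme=options.integration_scheme)
    return SolveResult(u, stress, constrained.pressure,
                       backend="fem", residual=float(rel))


def recover_stress(mesh: WallMesh, case: MaterialCase, displacement: np.ndarray,
                   scheme: str = "selective_reduced") -> np.ndarray:
    """Cauchy stress at cell centroids from Hooke's law.

    Uses the centroid strain-displacement operator; under the
    selective-reduced scheme the volumetric strain is the element mean,
    consistent with the assembled stiffness.
    """
    lam, mu = _element_moduli(mesh, case)
    X = mesh.points[mesh.cells]
    ne = mesh.n_cells
    u_e = displacement.reshape(-1, 3)[mesh.cells].reshape(ne, 24)

    dN = _hex_shape_gradients(0.0, 0.0, 0.0)
    J = np.einsum("eai,aj->eij", X, dN)
    invJ = np.linalg.inv(J)
    grad = np.einsum("aj,eji->eai", dN, invJ)
    B = np.zeros((ne, 6, 24))
    B[:, 0, 0::3] = grad[:, :, 0]
    B[:, 1, 1::3] = grad[:, :, 1]
    B[:, 2, 2::3] = grad[:, :, 2]
    B[:, 3, 0::3] = grad[:, :, 1]
    B[:, 3, 1::3] = grad[:, :, 0]
    B[:, 4, 1::3] = grad[:, :, 2]
    B[:, 4, 2::3] = grad[:, :, 1]
    B[:, 5, 0::3] = grad[:, :, 2]
    B[:, 5, 2::3] = grad[:, :, 0]
    if scheme == "selective_reduced":
        B_gp, detJ = _batch_B(mesh.points, mesh.cells, "full")
        b_rows = np.stack([Bg[:, 0] + Bg[:, 1] + Bg[:, 2] for Bg in B_gp])
        b_bar = np.einsum("gea,eg->ea", b_rows, detJ) / detJ.sum(axis=1)[:, None]
        corr = (b_bar - (B[:, 0] + B[:, 1] + B[:, 2])) / 3.0
        B[:, 0] += corr
        B[:, 1] += corr
        B[:, 2] += corr
    eps = np.einsum("eka,ea->ek", B, u_e)               # (ne, 6) engineering
    tr = eps[:, 0] + eps[:, 1] + eps[:, 2]
    sig = np.empty((ne, 6))
    sig[:, :3] = lam[:, None] * tr[:, None] + 2 * mu[:, None] * eps[:, :3]
    sig[:, 3:] = mu[:, None] * eps[:, 3:]
    out = np.empty((ne, 3, 3))
    out[:, 0, 0], out[:, 1, 1], out[:, 2, 2] = sig[:, 0], sig[:, 1], sig[:, 2]
    out[:, 0, 1] = out[:, 1, 0] = sig[:, 3]
    out[:, 1, 2] = out[:, 2, 1] = sig[:, 4]
    out[:, 0, 2] = out[:, 2, 0] = sig[:, 5]
    return out


def solve_case(mesh: WallMesh, case: MaterialCase, p: float,
               options: SolveOptions | None = None) -> SolveResult:
    """Assemble, load, constrain and solve in one call."""
    options = options or SolveOptions()
    system = assemble_system(mesh, case, options)
    constrained = apply_loads_and_bcs(system, mesh, p)
    result = solve_static(constrained, options)
    result.case_id = case.case_id
    return result


# ---------------------------------------------------------------------------
# transient (Newmark-beta)
# ---------------------------------------------------------------------------

def solve_transient(constrained: ConstrainedSystem,
                    waveform: Callable[[float], float],
                    options: SolveOptions) -> list[SolveResult]:
    """Newmark-β integration of M ü + K u = f(t).

    ``waveform`` maps normalized cycle time to a pressure scale factor;
    the applied force is the static consistent load scaled by it.  With
    slow loading the peak response converges to the static solution at
    peak pressure (quasi-static limit, verified in tests).
    """
    tr = options.transient
    if tr is None:
        raise ValueError("transient options not set")
    beta, gamma = tr.newmark_beta, tr.newmark_gamma
    if not (gamma >= 0.5 and 2 * beta >= gamma):
        warnings.warn(
            f"Newmark parameters beta={beta}, gamma={gamma} are outside the "
            "unconditional-stability region (gamma >= 1/2, 2 beta >= gamma)",
            stacklevel=2)
        if not tr.force:
            raise ValueError(
                "refusing unstable Newmark parameters (set force=True to override)")

    system = constrained.system
    mesh = system.mesh
    n_dofs = 3 * mesh.n_nodes
    if system.M is None:
        system.M = assemble_mass(system, tr.density)
    T, keep = _tie_transform(mesh, n_dofs)
    K2 = (T.T @ system.K @ T).tocsr()
    M2 = (T.T @ system.M @ T).tocsr()
    f2 = T.T @ constrained.f

    col_of = -np.ones(n_dofs, dtype=np.int64)
    col_of[keep] = np.arange(len(keep))
    bc_cols = col_of[constrained.fixed_dofs]
    free = np.setdiff1d(np.arange(K2.shape[0]), bc_cols)
    Kf = K2[free][:, free].tocsc()
    Mf = M2[free][:, free].tocsc()
    ff = f2[free]

    dt = tr.time_step
    a0 = 1.0 / (beta * dt ** 2)
    a1 = 1.0 / (beta * dt)
    a2 = 1.0 / (2 * beta) - 1.0
    lu = splu((Kf + a0 * Mf).tocsc())

    n_steps = int(round(tr.total_cycles * tr.cycle_period / dt))
    u = np.zeros(len(free))
    v = np.zeros(len(free))
    a = np.zeros(len(free))
    results: list[SolveResult] = []
    for step in range(1, n_steps + 1):
        t = step * dt
        scale = float(waveform((t / tr.cycle_period) % 1.0))
        rhs = scale * ff + Mf @ (a0 * u + a1 * v + a2 * a)
        u_new = lu.solve(rhs)
        a_new = a0 * (u_new - u) - a1 * v - a2 * a
        v_new = v + dt * ((1 - gamma) * a + gamma * a_new)
        u, v, a = u_new, v_new, a_new
        if step % tr.output_every == 0 or step == n_steps:
            u_red = np.zeros(K2.shape[0])
            u_red[free] = u
            full = (T @ u_red).reshape(-1, 3)
            results.append(SolveResult(
                full, None, scale * constrained.pressure,
                backend="fem", time=t))
    return results
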