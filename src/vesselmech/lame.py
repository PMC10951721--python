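"""Thick-walled cylinder (Lamé) solution and the reduced per-branch backend.

For an isotropic linear-elastic tube of inner radius ``a``, outer radius
``b``, internally pressurized by ``p`` with zero external pressure, the
plane-strain radial displacement is

    u(r) = p a² (1+ν) / (E (b² − a²)) · [(1−2ν) r + b²/r]

with stresses

    σ_r(r) = p a²/(b²−a²) (1 − b²/r²)
    σ_θ(r) = p a²/(b²−a²) (1 + b²/r²)
    σ_z    = ν (σ_r + σ_θ)           (plane strain)

The plane-strain state is the interior limit of a long tube whose ends
are axially restrained — which is exactly the boundary condition the
structural model applies (fixed supports at every vessel opening), so
this closed form serves as the convergence oracle for the hexahedral
finite-element backend.

The *reduced* backend treats every branch of a centerline tree as an
independent Lamé tube of its mean radius: fast, exactly linear in p and
1/E, but blind to the geometric coupling between aorta and branches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import CenterlineTree
from .materials import MaterialCase

MM_TO_M = 1.0e-3


def _check_geometry(a: float, b: float, E: float, nu: float) -> None:
    if not 0 < a < b:
        raise ValueError(f"need 0 < a < b, got a={a}, b={b}")
    if E <= 0:
        raise ValueError(f"Young's modulus must be > 0, got {E}")
    if not 0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {nu}")


def lame_radial_displacement(r, a: float, b: float, E: float, nu: float,
                             p: float):
    """Radial displacement u(r) of the pressurized thick-walled cylinder."""
    _check_geometry(a, b, E, nu)
    r = np.asarray(r, dtype=float)
    coef = p * a ** 2 * (1 + nu) / (E * (b ** 2 - a ** 2))
    return coef * ((1 - 2 * nu) * r + b ** 2 / r)


def lame_inner_displacement(a: float, b: float, E: float, nu: float,
                            p: float) -> float:
    """u(a): inner-wall radial displacement, m (for SI inputs)."""
    return float(lame_radial_displacement(a, a, b, E, nu, p))


def lame_stresses(r, a: float, b: float, p: float, nu: float):
    """(σ_r, σ_θ, σ_z) at radius r, plane strain."""
    _check_geometry(a, b, 1.0, nu)
    r = np.asarray(r, dtype=float)
    k = p * a ** 2 / (b ** 2 - a ** 2)
    s_r = k * (1 - b ** 2 / r ** 2)
    s_t = k * (1 + b ** 2 / r ** 2)
    s_z = nu * (s_r + s_t)
    return s_r, s_t, s_z


def lame_von_mises(r, a: float, b: float, p: float, nu: float):
    s_r, s_t, s_z = lame_stresses(r, a, b, p, nu)
    return np.sqrt(0.5 * ((s_r - s_t) ** 2 + (s_t - s_z) ** 2
                          + (s_z - s_r) ** 2))


def lame_ode_displacement(a: float, b: float, E: float, nu: float, p: float,
                          n: int = 2001) -> np.ndarray:
    """Independent finite-difference solution of the axisymmetric
    plane-strain equilibrium ODE,

        d/dr [ (1/r) d(r u)/dr ] = 0,

    with traction boundary conditions σ_r(a) = −p, σ_r(b) = 0, where
    σ_r = (λ+2μ) u' + λ u/r.  Returns u on a uniform grid from a to b.
    Used in tests to cross-check the closed form.
    """
    _check_geometry(a, b, E, nu)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    r = np.linspace(a, b, n)
    h = r[1] - r[0]
    # interior: (λ+2μ)(u'' + u'/r − u/r²) = 0
    main = np.full(n, -2.0 / h ** 2)
    main -= 1.0 / r ** 2
    upper = 1.0 / h ** 2 + 1.0 / (2 * h * r)
    lower = 1.0 / h ** 2 - 1.0 / (2 * h * r)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(1, n - 1):
        A[i, i - 1] = lower[i]
        A[i, i] = main[i]
        A[i, i + 1] = upper[i]
    # boundary: (λ+2μ) u' + λ u/r = σ_r, one-sided 2nd-order differences
    A[0, 0] = (lam + 2 * mu) * (-3 / (2 * h)) + lam / r[0]
    A[0, 1] = (lam + 2 * mu) * (4 / (2 * h))
    A[0, 2] = (lam + 2 * mu) * (-1 / (2 * h))
    rhs[0] = -p
    A[-1, -1] = (lam + 2 * mu) * (3 / (2 * h)) + lam / r[-1]
    A[-1, -2] = (lam + 2 * mu) * (-4 / (2 * h))
    A[-1, -3] = (lam + 2 * mu) * (1 / (2 * h))
    rhs[-1] = 0.0
    return np.linalg.solve(A, rhs)


def reduced_solve(tree: CenterlineTree, case: MaterialCase,
                  p: float) -> pd.DataFrame:
    """Per-branch Lamé estimates: inner displacement, ΔV, compliance,
    mid-wall hoop and von Mises stress.

    Each branch is an independent tube of its mean lumen radius; the
    volume change of a uniformly inflated tube is ΔV = 2π a u(a) L.
    Exactly linear in p and in 1/E per branch.
    """
    rows = []
    for branch in tree.branches:
        a = float(np.mean(branch.lumen_radius_profile)) * MM_TO_M
        b = a + branch.wall_thickness * MM_TO_M
        L = branch.length * MM_TO_M
        E = case.modulus(branch.name)
        nu = case.poisson_ratio
        u = lame_inner_displacement(a, b, E, nu, p) if p != 0 else 0.0
        dV = 2 * np.pi * a * u * L
        r_mid = 0.5 * (a + b)
        s_r, s_t, s_z = lame_stresses(r_mid, a, b, p, nu)
        vm = float(lame_von_mises(r_mid, a, b, p, nu))
        rows.append({
            "region": branch.name,
            "inner_radius_m": a,
            "length_m": L,
            "E_pa": E,
            "inner_displacement_m": u,
            "delta_v_m3": dV,
            "compliance_m3_per_pa": dV / p if p != 0 else np.nan,
            "hoop_stress_pa": float(s_t),
            "von_mises_pa": vm,
        })
    return pd.DataFrame(rows).set_index("region")
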