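"""Shared fixtures: small oracle meshes and the two session-level
stiffness sweeps on the default anatomy (computed once)."""

from __future__ import annotations

import numpy as np
import pytest

from vesselmech.geometry import build_default_tree
from vesselmech.meshing import DEFAULT_RESOLUTION, mesh_tree, single_tube_tree
from vesselmech.sweep import SweepSpec, run_sweep

# oracle tube: long enough that the clamped-end boundary layers decay
# before mid-length (decay length ~ sqrt(a t) ≈ 6 mm here)
TUBE_A_MM = 12.5
TUBE_T_MM = 2.6
TUBE_L_MM = 160.0
TUBE_RESOLUTION = (32, 0.4, 2)


@pytest.fixture(scope="session")
def tube_mesh():
    tree = single_tube_tree(TUBE_L_MM, TUBE_A_MM, TUBE_T_MM)
    return mesh_tree(tree, TUBE_RESOLUTION)


@pytest.fixture(scope="session")
def small_tube_mesh():
    return mesh_tree(single_tube_tree(20.0, 3.0, 1.0), (12, 0.3, 2))


@pytest.fixture(scope="session")
def default_tree():
    return build_default_tree()


@pytest.fixture(scope="session")
def default_mesh(default_tree):
    return mesh_tree(default_tree, DEFAULT_RESOLUTION)


@pytest.fixture(scope="session")
def uniform_fem_bundle(default_tree, default_mesh):
    spec = SweepSpec(case_table="uniform", backend="fem",
                     tree=default_tree, mesh=default_mesh)
    return run_sweep(spec)


@pytest.fixture(scope="session")
def regional_fem_bundle(default_tree, default_mesh):
    spec = SweepSpec(case_table="regional", backend="fem",
                     tree=default_tree, mesh=default_mesh)
    return run_sweep(spec)


def mid_inner_radial_displacement(mesh, displacement, length_mm: float) -> float:
    """Mean radial displacement of inner-surface nodes at tube mid-length."""
    P = mesh.points
    inner = np.unique(mesh.facet_sets["inner_surface"].ravel())
    mid = length_mm / 2 * 1e-3
    sel = inner[np.abs(P[inner, 2] - mid) < 1.5e-3]
    r = np.linalg.norm(P[sel, :2], axis=1)
    return float((np.einsum("ij,ij->i", displacement[sel, :2], P[sel, :2]) / r).mean())
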