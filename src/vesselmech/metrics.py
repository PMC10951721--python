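"""Observables of the structural model: total deformation, enclosed
lumen volumes and compliance (C = ΔV/ΔP), von Mises stress, percent
changes and local compliance maps.

Regional volumes close each branch lumen with fan caps at its end rings
(generated on the fly, never stored as mesh facets).  Caps at welded
interfaces are shared by the two adjacent regions with opposite
orientation, so volume swept by interface motion moves between regions
and regional ΔV sums exactly to the whole-model ΔV.  The cap at a
lateral branch root lies on the parent's outer surface and moves with
the parent wall; its swept-volume contribution is attributed to the
upstream (parent) region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import SolveResult
from .meshing import WallMesh


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def deformation_magnitude(displacement: np.ndarray) -> np.ndarray:
    """Total deformation U = sqrt(Ux² + Uy² + Uz²) per node."""
    displacement = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(displacement)):
        raise ValueError("displacement field contains non-finite values")
    return np.linalg.norm(displacement, axis=-1)


@dataclass
class DeformationSummary:
    """Per-region maximum total deformation and its node."""

    max_by_region: dict[str, float]
    argmax_by_region: dict[str, int]

    @property
    def overall_max(self) -> float:
        return max(self.max_by_region.values())


def summarize_deformation(mesh: WallMesh, displacement: np.ndarray
                          ) -> DeformationSummary:
    U = deformation_magnitude(displacement)
    max_by, arg_by = {}, {}
    for code, name in enumerate(mesh.region_names):
        nodes = np.unique(mesh.cells[mesh.cell_region == code].ravel())
        i = nodes[np.argmax(U[nodes])]
        max_by[name] = float(U[i])
        arg_by[name] = int(i)
    return DeformationSummary(max_by, arg_by)


# ---------------------------------------------------------------------------
# enclosed volumes and compliance
# ---------------------------------------------------------------------------

def _tri_volume(verts: np.ndarray, tris: np.ndarray) -> float:
    """Signed volume enclosed by oriented triangles (divergence theorem)."""
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _cap_volume(verts: np.ndarray, ring: np.ndarray, orientation: int) -> float:
    """Signed volume contribution of a fan cap over an ordered node ring."""
    pts = verts[ring]
    centroid = pts.mean(axis=0)
    v1 = pts
    v2 = np.roll(pts, -1, axis=0)
    if orientation > 0:
        vol = np.einsum("ij,ij->i", np.broadcast_to(centroid, v1.shape),
                        np.cross(v1, v2)).sum() / 6.0
    else:
        vol = np.einsum("ij,ij->i", np.broadcast_to(centroid, v1.shape),
                        np.cross(v2, v1)).sum() / 6.0
    return float(vol)


def region_volumes(mesh: WallMesh, displacement: np.ndarray | None = None
                   ) -> dict[str, float]:
    """Enclosed lumen volume per region, m³ (deformed if a displacement
    field is given).

    Lateral-root cap contributions are *not* reassigned here — each
    region's closed-surface volume is reported; reassignment applies to
    volume differences (see :func:`region_volume_changes`).
    """
    verts = mesh.points if displacement is None else mesh.points + displacement
    vols: dict[str, float] = {}
    for name in mesh.region_names:
        quads = mesh.inner_facets_by_region[name]
        tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
        v = _tri_volume(verts, tris)
        for cap in mesh.caps:
            if cap.region == name:
                v += _cap_volume(verts, cap.ring, cap.orientation)
        if v <= 0 and displacement is None:
            raise ValueError(
                f"region {name!r}: non-positive enclosed volume; "
                "inner surface is not closed or mis-oriented")
        vols[name] = v
    return vols


def enclosed_volume(mesh: WallMesh, displacement: np.ndarray | None = None
                    ) -> float:
    """Whole-model lumen volume, m³ (sum over regions; shared interface
    caps cancel exactly)."""
    return float(sum(region_volumes(mesh, displacement).values()))


def _tri_volume_linearized(verts: np.ndarray, disp: np.ndarray,
                           tris: np.ndarray) -> float:
    """First-order (in displacement) change of the enclosed volume."""
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    ua, ub, uc = disp[tris[:, 0]], disp[tris[:, 1]], disp[tris[:, 2]]
    dv = (np.einsum("ij,ij->i", ua, np.cross(b, c))
          + np.einsum("ij,ij->i", a, np.cross(ub, c))
          + np.einsum("ij,ij->i", a, np.cross(b, uc)))
    return float(dv.sum() / 6.0)


def _cap_volume_linearized(verts: np.ndarray, disp: np.ndarray,
                           ring: np.ndarray, orientation: int) -> float:
    pts, du = verts[ring], disp[ring]
    cen, ducen = pts.mean(axis=0), du.mean(axis=0)
    v1, u1 = pts, du
    v2, u2 = np.roll(pts, -1, axis=0), np.roll(du, -1, axis=0)
    if orientation < 0:
        v1, v2, u1, u2 = v2, v1, u2, u1
    dv = (np.einsum("ij,ij->i", np.broadcast_to(ducen, v1.shape), np.cross(v1, v2))
          + np.einsum("ij,ij->i", np.broadcast_to(cen, v1.shape), np.cross(u1, v2))
          + np.einsum("ij,ij->i", np.broadcast_to(cen, v1.shape), np.cross(v1, u2)))
    return float(dv.sum() / 6.0)


def region_volume_changes(mesh: WallMesh, displacement: np.ndarray,
                          reference: np.ndarray | None = None
                          ) -> dict[str, float]:
    """ΔV per region between two states, first order in displacement.

    Consistent with the small-strain linear model: ΔV is exactly linear
    in the displacement field, so compliance is exactly independent of
    the pulse-pressure amplitude.  (The quadratic geometric correction
    the full displaced-surface volume would add is of order u/a ≈ a few
    percent here and belongs to large-deformation theory, which the
    solver does not model.)  Lateral-root cap motion is attributed to
    the upstream (parent) region.
    """
    du = displacement if reference is None else displacement - reference
    dv: dict[str, float] = {}
    for name in mesh.region_names:
        quads = mesh.inner_facets_by_region[name]
        tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
        d = _tri_volume_linearized(mesh.points, du, tris)
        for cap in mesh.caps:
            if cap.region == name:
                d += _cap_volume_linearized(mesh.points, du, cap.ring,
                                            cap.orientation)
        dv[name] = d
    for cap in mesh.caps:
        if cap.kind == "tie_root" and cap.upstream is not None:
            c = _cap_volume_linearized(mesh.points, du, cap.ring, cap.orientation)
            dv[cap.region] -= c
            dv[cap.upstream] += c
    return dv


@dataclass
class ComplianceReport:
    """Per-region ΔV, ΔP and compliance C = ΔV/ΔP for one solve pair."""

    table: pd.DataFrame                  # index region, columns delta_v_m3, compliance
    delta_p: float
    case_id: int | None = None
    pressure_label: str | None = None
    percent_change_vs_reference: pd.Series | None = field(default=None)

    def compliance_of(self, region: str) -> float:
        return float(self.table.loc[region, "compliance_m3_per_pa"])


def compliance(mesh: WallMesh, result_systole: SolveResult,
               result_diastole: SolveResult | None, delta_p: float,
               extra_groups: dict[str, list[str]] | None = None
               ) -> ComplianceReport:
    """Compliance C = (V_systole − V_diastole)/ΔP per region.

    ``result_diastole`` may be None for a zero diastolic baseline.
    ``extra_groups`` adds aggregate rows (e.g. whole aorta) whose ΔV is
    the sum of member regions.
    """
    if delta_p <= 0:
        raise ValueError(f"delta_p must be > 0, got {delta_p}")
    u_sys = result_systole.displacement
    u_dia = None if result_diastole is None else result_diastole.displacement
    dv = region_volume_changes(mesh, u_sys, u_dia)
    rows = {name: {"delta_v_m3": d, "compliance_m3_per_pa": d / delta_p}
            for name, d in dv.items()}
    for gname, members in (extra_groups or {}).items():
        d = sum(dv[m] for m in members)
        rows[gname] = {"delta_v_m3": d, "compliance_m3_per_pa": d / delta_p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "region"
    return ComplianceReport(table, delta_p, case_id=result_systole.case_id)


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------

def von_mises(stress: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Von Mises equivalent stress σ_vm = sqrt(3 J₂) per cell.

    ``stress`` is (m, 3, 3) Cauchy tensors; asymmetry beyond ``tol``
    (relative to the largest component) raises ValueError.
    """
    s = np.asarray(stress, dtype=float)
    if s.ndim == 2:
        s = s[None]
    asym = np.abs(s - np.swapaxes(s, -1, -2)).max()
    scale = max(np.abs(s).max(), 1.0)
    if asym > tol * scale:
        raise ValueError(
            f"stress tensors are asymmetric (max deviation {asym:.3e})")
    d11 = s[:, 0, 0] - s[:, 1, 1]
    d22 = s[:, 1, 1] - s[:, 2, 2]
    d33 = s[:, 2, 2] - s[:, 0, 0]
    shear = s[:, 0, 1] ** 2 + s[:, 1, 2] ** 2 + s[:, 0, 2] ** 2
    return np.sqrt(0.5 * (d11 ** 2 + d22 ** 2 + d33 ** 2) + 3.0 * shear)


def von_mises_by_region(mesh: WallMesh, stress: np.ndarray) -> dict[str, float]:
    """Per-region maximum von Mises stress."""
    vm = von_mises(stress)
    return {name: float(vm[mesh.cell_region == code].max())
            for code, name in enumerate(mesh.region_names)}


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def percent_change(reference_value: float, value: float) -> float:
    """100·(reference − value)/reference: positive for a decrease."""
    if reference_value <= 0:
        raise ValueError(
            f"reference value must be > 0, got {reference_value}")
    # divide first: exact ratios (e.g. a halved compliance) give exact
    # percentages
    return 100.0 * ((reference_value - value) / reference_value)


def local_compliance_map(mesh: WallMesh, result_systole: SolveResult,
                         result_diastole: SolveResult | None, delta_p: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Nodal local compliance on the inner surface: the outward-normal
    displacement difference between the two states divided by ΔP
    (a radial distensibility surrogate, m/Pa).

    Returns ``(node_ids, values)`` for inner-surface nodes.
    """
    if delta_p <= 0:
        raise ValueError(f"delta_p must be > 0, got {delta_p}")
    quads = mesh.facet_sets["inner_surface"]
    P = mesh.points
    a, b, c, d = P[quads[:, 0]], P[quads[:, 1]], P[quads[:, 2]], P[quads[:, 3]]
    fn = 0.5 * np.cross(c - a, d - b)          # area-weighted facet normals
    normals = np.zeros_like(P)
    for k in range(4):
        np.add.at(normals, quads[:, k], fn)
    node_ids = np.unique(quads.ravel())
    nrm = normals[node_ids]
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-300)
    du = result_systole.displacement[node_ids]
    if result_diastole is not None:
        du = du - result_diastole.displacement[node_ids]
    return node_ids, np.einsum("ij,ij->i", du, nrm) / delta_p
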