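"""Parametric centerline description of an aorta–carotid arterial tree.

The tree is an idealized stand-in for a patient-specific thoracic
vasculature: ascending aorta rising from the aortic root, arch curving
over to the descending aorta, with the three classic supra-aortic
branches (brachiocephalic trunk splitting into right common carotid and
right subclavian; left common carotid and left subclavian arising
directly from the arch) and both carotid bifurcations into internal and
external branches.  All dimensions are authored in millimetres; the
mesher converts to SI metres.

Wall thicknesses default to literature values for the adult arterial
wall: aorta 2.6 mm, brachiocephalic 1.5 mm, carotids 1.0 mm,
subclavians 1.0 mm.  Lumen radii and vessel lengths are implementation
defaults chosen to be anatomically representative; they are all
overridable (see :data:`DEFAULT_PARAMS` and :func:`build_default_tree`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

#: Controlled vocabulary of vascular region labels.
REGION_LABELS = (
    "ascending_aorta",
    "aortic_arch",
    "descending_aorta",
    "brachiocephalic",
    "right_common_carotid",
    "right_internal_carotid",
    "right_external_carotid",
    "left_common_carotid",
    "left_internal_carotid",
    "left_external_carotid",
    "right_subclavian",
    "left_subclavian",
)

#: Default geometric parameters, millimetres.  Radii are lumen (inner)
#: radii; "taper" entries give the radius at the distal end of the branch.
DEFAULT_PARAMS: dict[str, float] = {
    # wall thicknesses
    "aorta_wall_thickness": 2.6,
    "brachiocephalic_wall_thickness": 1.5,
    "carotid_wall_thickness": 1.0,
    "subclavian_wall_thickness": 1.0,
    # aorta
    "ascending_length": 65.0,
    "ascending_radius": 12.5,
    "ascending_radius_distal": 11.5,
    "arch_radius_of_curvature": 25.0,
    "arch_radius": 11.5,
    "arch_radius_distal": 10.5,
    "descending_length": 117.0,
    "descending_radius": 10.5,
    "descending_radius_distal": 9.0,
    # brachiocephalic trunk
    "brachiocephalic_length": 40.0,
    "brachiocephalic_radius": 6.0,
    "brachiocephalic_radius_distal": 4.5,
    "brachiocephalic_attach_fraction": 0.18,
    # common carotids
    "common_carotid_length": 70.0,
    "common_carotid_radius": 3.5,
    "left_carotid_attach_fraction": 0.42,
    # carotid bifurcation branches
    "internal_carotid_length": 25.0,
    "internal_carotid_radius": 2.8,
    "external_carotid_length": 20.0,
    "external_carotid_radius": 2.3,
    "external_carotid_attach_fraction": 0.85,
    # subclavians
    "subclavian_length": 40.0,
    "subclavian_radius": 3.6,
    "right_subclavian_attach_fraction": 0.60,
    "left_subclavian_attach_fraction": 0.72,
}


class GeometryError(ValueError):
    """Invalid geometric parameter or tree topology."""


@dataclass
class Branch:
    """One vessel segment: a centerline curve with a lumen radius profile.

    ``attach_arclength`` is the arclength fraction of the parent at which
    this branch attaches.  A fraction of exactly 1.0 denotes an
    end-to-end continuation (the mesher welds the rings node-to-node);
    fractions < 1 denote a lateral branch (the mesher mounts the root on
    the parent's outer surface with tie constraints).
    """

    name: str
    control_points: np.ndarray          # (k, 3) mm
    lumen_radius_profile: np.ndarray    # (k,) mm
    wall_thickness: float               # mm
    parent: Optional[str] = None
    attach_arclength: float = 0.0

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.lumen_radius_profile = np.asarray(self.lumen_radius_profile, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise GeometryError(f"branch {self.name!r}: control_points must be (k, 3)")
        if len(self.lumen_radius_profile) != len(self.control_points):
            raise GeometryError(
                f"branch {self.name!r}: radius profile length must match control points")
        if np.any(self.lumen_radius_profile <= 0):
            raise GeometryError(f"branch {self.name!r}: all lumen radii must be > 0")
        if self.wall_thickness <= 0:
            raise GeometryError(f"branch {self.name!r}: wall_thickness must be > 0")
        if not (0.0 <= self.attach_arclength <= 1.0):
            raise GeometryError(
                f"branch {self.name!r}: attach_arclength must lie in [0, 1]")

    @property
    def is_weld(self) -> bool:
        """True when this branch continues its parent end-to-end."""
        return self.parent is not None and self.attach_arclength == 1.0

    def polyline(self, n: int = 400) -> tuple[np.ndarray, np.ndarray]:
        """Densely resampled centerline: (positions (n,3), arclengths (n,))."""
        pts = self.control_points
        if len(pts) == 2:
            t = np.linspace(0.0, 1.0, n)
            pos = pts[0] + t[:, None] * (pts[1] - pts[0])
        else:
            chord = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            spl = CubicSpline(chord, pts, axis=0)
            dense = spl(np.linspace(0.0, chord[-1], 4 * n))
            s_dense = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(dense, axis=0), axis=1))])
            pos = np.empty((n, 3))
            targets = np.linspace(0.0, s_dense[-1], n)
            for c in range(3):
                pos[:, c] = np.interp(targets, s_dense, dense[:, c])
        s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pos, axis=0), axis=1))])
        return pos, s

    @property
    def length(self) -> float:
        """Arclength of the centerline, mm."""
        _, s = self.polyline()
        return float(s[-1])

    def radius_at(self, frac: np.ndarray | float) -> np.ndarray | float:
        """Lumen radius at arclength fraction(s) of the branch."""
        k = len(self.lumen_radius_profile)
        knots = np.linspace(0.0, 1.0, k)
        return np.interp(frac, knots, self.lumen_radius_profile)


@dataclass
class CenterlineTree:
    """A rooted tree of :class:`Branch` segments with unique region labels."""

    branches: list[Branch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise GeometryError("region labels must be unique")
        unknown = set(names) - set(REGION_LABELS)
        if unknown:
            raise GeometryError(
                f"unknown region labels {sorted(unknown)}; allowed: {REGION_LABELS}")
        roots = [b for b in self.branches if b.parent is None]
        if len(self.branches) and len(roots) != 1:
            raise GeometryError("tree must have exactly one root branch")
        for b in self.branches:
            if b.parent is not None and b.parent not in names:
                raise GeometryError(
                    f"branch {b.name!r} attaches to unknown parent {b.parent!r}")

    def branch(self, name: str) -> Branch:
        for b in self.branches:
            if b.name == name:
                return b
        raise KeyError(name)

    def children(self, name: str) -> list[Branch]:
        return [b for b in self.branches if b.parent == name]

    @property
    def root(self) -> Branch:
        return next(b for b in self.branches if b.parent is None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CenterlineTree):
            return NotImplemented
        if len(self.branches) != len(other.branches):
            return False
        for a, b in zip(self.branches, other.branches):
            if (a.name != b.name or a.parent != b.parent
                    or a.attach_arclength != b.attach_arclength
                    or a.wall_thickness != b.wall_thickness
                    or not np.array_equal(a.control_points, b.control_points)
                    or not np.array_equal(a.lumen_radius_profile,
                                          b.lumen_radius_profile)):
                return False
        return True


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


def _arch_point(p: dict, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and outward (away from arch center) normal on the arch
    centerline at arclength fraction ``frac``."""
    R = p["arch_radius_of_curvature"]
    z0 = p["ascending_length"]
    center = np.array([-R, 0.0, z0])
    phi = frac * math.pi
    radial = np.array([math.cos(phi), 0.0, math.sin(phi)])
    return center + R * radial, radial


def jitter_tree(tree: CenterlineTree, amplitude_mm: float,
                rng: np.random.Generator) -> CenterlineTree:
    """Gaussian perturbation of interior control points (robustness
    studies).  Attachment/end points stay fixed so the topology and
    junction mounts survive; amplitude 0 returns an identical tree."""
    if amplitude_mm < 0:
        raise GeometryError("jitter amplitude must be >= 0")
    branches = []
    for b in tree.branches:
        cp = b.control_points.copy()
        if amplitude_mm > 0 and len(cp) > 2:
            cp[1:-1] = cp[1:-1] + rng.normal(0.0, amplitude_mm,
                                             size=cp[1:-1].shape)
        branches.append(Branch(b.name, cp, b.lumen_radius_profile.copy(),
                               b.wall_thickness, b.parent, b.attach_arclength))
    return CenterlineTree(branches)


def build_default_tree(**overrides: float) -> CenterlineTree:
    """Build the default 12-branch aorta–carotid tree.

    Parameters are named scalar overrides of :data:`DEFAULT_PARAMS`
    (all in mm).  The construction is fully deterministic: identical
    overrides give bitwise-identical trees.

    Raises
    ------
    GeometryError
        If an override is unknown or non-positive, naming the parameter.
    """
    p = dict(DEFAULT_PARAMS)
    for key, val in overrides.items():
        if key not in p:
            raise GeometryError(
                f"unknown geometry parameter {key!r}; known parameters: "
                f"{sorted(p)}")
        if not np.isfinite(val) or val <= 0:
            raise GeometryError(
                f"geometry parameter {key!r} must be a positive number, got {val!r}")
        if key.endswith("_fraction") and val > 1.0:
            raise GeometryError(
                f"geometry parameter {key!r} must lie in (0, 1], got {val!r}")
        p[key] = float(val)

    t_ao = p["aorta_wall_thickness"]
    branches: list[Branch] = []

    # --- aorta: ascending | arch | descending, welded end to end -------
    z0 = p["ascending_length"]
    branches.append(Branch(
        "ascending_aorta",
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, z0]]),
        np.array([p["ascending_radius"], p["ascending_radius_distal"]]),
        t_ao))
    R = p["arch_radius_of_curvature"]
    phis = np.linspace(0.0, math.pi, 9)
    arch_pts = np.stack([
        -R + R * np.cos(phis), np.zeros_like(phis), z0 + R * np.sin(phis)], axis=1)
    branches.append(Branch(
        "aortic_arch", arch_pts,
        np.linspace(p["arch_radius"], p["arch_radius_distal"], 9),
        t_ao, parent="ascending_aorta", attach_arclength=1.0))
    branches.append(Branch(
        "descending_aorta",
        np.array([[-2 * R, 0.0, z0], [-2 * R, 0.0, z0 - p["descending_length"]]]),
        np.array([p["descending_radius"], p["descending_radius_distal"]]),
        t_ao, parent="aortic_arch", attach_arclength=1.0))

    def straight(origin: np.ndarray, direction: np.ndarray, length: float,
                 bow: float = 0.0, bow_dir: np.ndarray | None = None) -> np.ndarray:
        """Control points for a straight or gently bowed segment."""
        d = _normalize(direction)
        if bow == 0.0:
            return np.array([origin, origin + length * d])
        mid = origin + 0.5 * length * d + bow * _normalize(bow_dir)
        return np.array([origin, mid, origin + length * d])

    def bent(origin: np.ndarray, normal: np.ndarray, target: np.ndarray,
             length: float, n: int = 9) -> np.ndarray:
        """Control points leaving along the parent surface ``normal`` and
        curving toward ``target`` over the branch length.  Lateral branches
        must leave close to normally so their root annulus projects cleanly
        onto the parent surface."""
        nh, th = _normalize(normal), _normalize(target)
        pts = [np.asarray(origin, dtype=float)]
        step = length / (n - 1)
        for i in range(1, n):
            u = (i - 0.5) / (n - 1)
            d = _normalize((1 - u) * nh + u * th)
            pts.append(pts[-1] + step * d)
        return np.array(pts)

    # --- brachiocephalic trunk off the arch (lateral tie) --------------
    c_bc, n_bc = _arch_point(p, p["brachiocephalic_attach_fraction"])
    d_bc = _normalize(np.array([0.35, 0.55, 0.85]))
    o_bc = c_bc + (p["arch_radius"] + t_ao) * n_bc
    bc_pts = bent(o_bc, n_bc, d_bc, p["brachiocephalic_length"])
    branches.append(Branch(
        "brachiocephalic",
        bc_pts,
        np.linspace(p["brachiocephalic_radius"],
                    p["brachiocephalic_radius_distal"], len(bc_pts)),
        p["brachiocephalic_wall_thickness"],
        parent="aortic_arch",
        attach_arclength=p["brachiocephalic_attach_fraction"]))
    bc_end = bc_pts[-1]

    # --- right common carotid continues the trunk (weld) ----------------
    d_rcc = _normalize(np.array([0.08, 0.22, 0.97]))
    branches.append(Branch(
        "right_common_carotid",
        straight(bc_end, d_rcc, p["common_carotid_length"],
                 bow=3.0, bow_dir=np.array([0.0, 1.0, 0.0])),
        np.full(3, p["common_carotid_radius"]),
        p["carotid_wall_thickness"],
        parent="brachiocephalic", attach_arclength=1.0))

    # --- left common carotid off the arch (lateral tie) -----------------
    c_lcc, n_lcc = _arch_point(p, p["left_carotid_attach_fraction"])
    d_lcc = _normalize(np.array([0.05, -0.30, 0.95]))
    frac_lcc = p["left_carotid_attach_fraction"]
    r_arch_lcc = float(np.interp(frac_lcc, [0, 1],
                                 [p["arch_radius"], p["arch_radius_distal"]]))
    o_lcc = c_lcc + (r_arch_lcc + t_ao) * n_lcc
    lcc_pts = bent(o_lcc, n_lcc, d_lcc, p["common_carotid_length"] + 5.0)
    branches.append(Branch(
        "left_common_carotid",
        lcc_pts,
        np.full(len(lcc_pts), p["common_carotid_radius"]),
        p["carotid_wall_thickness"],
        parent="aortic_arch",
        attach_arclength=frac_lcc))

    # --- carotid bifurcations -------------------------------------------
    def carotid_bifurcation(side: str, common_name: str,
                            d_common: np.ndarray) -> None:
        common = next(b for b in branches if b.name == common_name)
        pos, _ = common.polyline()
        end = pos[-1]
        tilt = 1.0 if side == "right" else -1.0
        d_int = _normalize(d_common + np.array([-0.10, 0.15 * tilt, 0.0]))
        branches.append(Branch(
            f"{side}_internal_carotid",
            straight(end, d_int, p["internal_carotid_length"]),
            np.full(2, p["internal_carotid_radius"]),
            p["carotid_wall_thickness"],
            parent=common_name, attach_arclength=1.0))
        frac = p["external_carotid_attach_fraction"]
        attach = pos[int(round(frac * (len(pos) - 1)))]
        d_ext = _normalize(d_common + np.array([0.45, -0.35 * tilt, 0.0]))
        # start on the parent's outer surface, leaving normally
        t_vec = _normalize(pos[-1] - pos[-2])
        side_dir = _normalize(d_ext - np.dot(d_ext, t_vec) * t_vec)
        o_ext = attach + (p["common_carotid_radius"]
                          + p["carotid_wall_thickness"]) * side_dir
        ext_pts = bent(o_ext, side_dir, d_ext, p["external_carotid_length"])
        branches.append(Branch(
            f"{side}_external_carotid",
            ext_pts,
            np.full(len(ext_pts), p["external_carotid_radius"]),
            p["carotid_wall_thickness"],
            parent=common_name, attach_arclength=frac))

    carotid_bifurcation("right", "right_common_carotid", d_rcc)
    carotid_bifurcation("left", "left_common_carotid", d_lcc)

    # --- subclavians ------------------------------------------------------
    bc = next(b for b in branches if b.name == "brachiocephalic")
    frac_rs = p["right_subclavian_attach_fraction"]
    bc_pos, bc_s = bc.polyline()
    i_rs = int(round(frac_rs * (len(bc_pos) - 1)))
    c_rs = bc_pos[i_rs]
    t_rs = _normalize(bc_pos[i_rs + 1] - bc_pos[i_rs - 1])
    d_rs = _normalize(np.array([0.05, 0.97, 0.15]))
    side_rs = _normalize(d_rs - np.dot(d_rs, t_rs) * t_rs)
    r_bc_here = float(bc.radius_at(frac_rs)) + p["brachiocephalic_wall_thickness"]
    rs_pts = bent(c_rs + r_bc_here * side_rs, side_rs, d_rs, p["subclavian_length"])
    branches.append(Branch(
        "right_subclavian",
        rs_pts,
        np.full(len(rs_pts), p["subclavian_radius"]),
        p["subclavian_wall_thickness"],
        parent="brachiocephalic", attach_arclength=frac_rs))

    frac_ls = p["left_subclavian_attach_fraction"]
    c_ls, n_ls = _arch_point(p, frac_ls)
    d_ls = _normalize(np.array([-0.10, -0.90, 0.42]))
    # arch tangent at the attachment: dP/dphi, then the start point sits on the
    # outer surface along the component of the branch direction off the tangent
    phi_ls = frac_ls * math.pi
    t_ls = np.array([-math.sin(phi_ls), 0.0, math.cos(phi_ls)])
    side_ls = _normalize(0.4 * d_ls + 0.6 * n_ls
                         - np.dot(0.4 * d_ls + 0.6 * n_ls, t_ls) * t_ls)
    r_arch_ls = float(np.interp(frac_ls, [0, 1],
                                [p["arch_radius"], p["arch_radius_distal"]])) + t_ao
    ls_pts = bent(c_ls + r_arch_ls * side_ls, side_ls, d_ls, p["subclavian_length"])
    branches.append(Branch(
        "left_subclavian",
        ls_pts,
        np.full(len(ls_pts), p["subclavian_radius"]),
        p["subclavian_wall_thickness"],
        parent="aortic_arch",
        attach_arclength=frac_ls))

    return CenterlineTree(branches)
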