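"""Stiffness-sweep experiments over the aorta–carotid model.

Two sweep families (uniform aortic modulus; regional ascending/arch/
descending moduli) are run across both pulse-pressure levels.  Every
(case, pressure) pair is solved, postprocessed into regional compliance,
peak deformation and peak von Mises stress, and accumulated into tidy
tables with percent changes against a reference case (default case 1,
the most compliant aorta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .fem import SolveOptions, apply_loads_and_bcs, assemble_system, solve_static
from .geometry import CenterlineTree, REGION_LABELS, build_default_tree
from .lame import reduced_solve
from .materials import PressureSpec, case_table, pressure_levels
from .meshing import DEFAULT_RESOLUTION, WallMesh, mesh_tree
from .metrics import (compliance, percent_change, summarize_deformation,
                      von_mises_by_region)

#: Aggregate region groups reported alongside the individual regions.
AGGREGATES: dict[str, list[str]] = {
    "aorta": ["ascending_aorta", "aortic_arch", "descending_aorta"],
    "left_carotid": ["left_common_carotid", "left_internal_carotid",
                     "left_external_carotid"],
    "right_carotid": ["right_common_carotid", "right_internal_carotid",
                      "right_external_carotid"],
    "aorta_carotid": ["ascending_aorta", "aortic_arch", "descending_aorta",
                      "left_common_carotid", "left_internal_carotid",
                      "left_external_carotid", "right_common_carotid",
                      "right_internal_carotid", "right_external_carotid"],
    "whole_model": list(REGION_LABELS),
}


@dataclass
class SweepSpec:
    """Definition of one sweep experiment."""

    case_table: str = "uniform"                  # uniform | regional
    pressures: list[PressureSpec] = field(default_factory=lambda: list(pressure_levels()))
    tree: Optional[CenterlineTree] = None        # default anatomy when None
    mesh: Optional[WallMesh] = None              # overrides tree when given
    resolution: tuple[int, float, int] = DEFAULT_RESOLUTION
    backend: str = "fem"                         # fem | reduced
    reference_case: int = 1
    options: SolveOptions = field(default_factory=SolveOptions)

    def __post_init__(self) -> None:
        if self.backend not in ("fem", "reduced"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if not self.pressures:
            raise ValueError("at least one pressure level required")
        cases = case_table(self.case_table)
        if self.reference_case not in [c.case_id for c in cases]:
            raise ValueError(
                f"reference case {self.reference_case} not in table "
                f"{self.case_table!r}")


@dataclass
class ReportBundle:
    """Tables accumulated by :func:`run_sweep`."""

    compliance_table: pd.DataFrame       # case, pressure, region rows
    percent_change_table: pd.DataFrame
    deformation_table: pd.DataFrame
    von_mises_table: pd.DataFrame
    manifest: dict

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("compliance", self.compliance_table),
                         ("percent_change", self.percent_change_table),
                         ("deformation", self.deformation_table),
                         ("von_mises", self.von_mises_table)):
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format="%.10e")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return out

    def compliance_of(self, case_id: int, pressure: str, region: str) -> float:
        t = self.compliance_table
        row = t[(t.case_id == case_id) & (t.pressure == pressure)
                & (t.region == region)]
        if len(row) != 1:
            raise KeyError(f"({case_id}, {pressure}, {region}) not unique in table")
        return float(row.compliance_m3_per_pa.iloc[0])

    def percent_change_of(self, case_id: int, pressure: str, region: str) -> float:
        t = self.percent_change_table
        row = t[(t.case_id == case_id) & (t.pressure == pressure)
                & (t.region == region)]
        if len(row) != 1:
            raise KeyError(f"({case_id}, {pressure}, {region}) not unique in table")
        return float(row.compliance_percent_decrease.iloc[0])


def run_sweep(spec: SweepSpec) -> ReportBundle:
    """Solve every (material case × pressure level) of the sweep.

    Deterministic for a fixed spec.  Solve failures abort with the
    offending (case, pressure) identity attached.
    """
    cases = case_table(spec.case_table)
    tree = spec.tree if spec.tree is not None else build_default_tree()

    comp_rows, def_rows, vm_rows = [], [], []
    if spec.backend == "fem":
        mesh = spec.mesh if spec.mesh is not None else mesh_tree(tree, spec.resolution)
        for case in cases:
            system = assemble_system(mesh, case, spec.options)
            for ps in spec.pressures:
                try:
                    constrained = apply_loads_and_bcs(system, mesh, ps.systolic)
                    res_sys = solve_static(constrained, spec.options)
                    res_sys.case_id = case.case_id
                    res_dia = None
                    if ps.diastolic > 0:
                        c_dia = apply_loads_and_bcs(system, mesh, ps.diastolic)
                        res_dia = solve_static(c_dia, spec.options)
                except Exception as exc:
                    raise RuntimeError(
                        f"solve failed for case {case.case_id}, "
                        f"pressure {ps.label}: {exc}") from exc
                rep = compliance(mesh, res_sys, res_dia, ps.pulse_pressure,
                                 extra_groups=AGGREGATES)
                for region, row in rep.table.iterrows():
                    comp_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region,
                        "delta_v_m3": row.delta_v_m3,
                        "compliance_m3_per_pa": row.compliance_m3_per_pa})
                dsum = summarize_deformation(mesh, res_sys.displacement)
                for region, val in dsum.max_by_region.items():
                    def_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region, "max_deformation_m": val})
                def_rows.append({
                    "case_id": case.case_id, "pressure": ps.label,
                    "region": "whole_model", "max_deformation_m": dsum.overall_max})
                vm = von_mises_by_region(mesh, res_sys.stress)
                for region, val in vm.items():
                    vm_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region, "max_von_mises_pa": val})
                vm_rows.append({
                    "case_id": case.case_id, "pressure": ps.label,
                    "region": "whole_model", "max_von_mises_pa": max(vm.values())})
    else:
        for case in cases:
            for ps in spec.pressures:
                table = reduced_solve(tree, case, ps.pulse_pressure)
                dv = table.delta_v_m3.to_dict()
                for region, d in dv.items():
                    comp_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region, "delta_v_m3": d,
                        "compliance_m3_per_pa": d / ps.pulse_pressure})
                for gname, members in AGGREGATES.items():
                    d = sum(dv[m] for m in members)
                    comp_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": gname, "delta_v_m3": d,
                        "compliance_m3_per_pa": d / ps.pulse_pressure})
                for region, row in table.iterrows():
                    def_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region,
                        "max_deformation_m": row.inner_displacement_m})
                    vm_rows.append({
                        "case_id": case.case_id, "pressure": ps.label,
                        "region": region, "max_von_mises_pa": row.von_mises_pa})
                def_rows.append({
                    "case_id": case.case_id, "pressure": ps.label,
                    "region": "whole_model",
                    "max_deformation_m": table.inner_displacement_m.max()})
                vm_rows.append({
                    "case_id": case.case_id, "pressure": ps.label,
                    "region": "whole_model",
                    "max_von_mises_pa": table.von_mises_pa.max()})

    comp = pd.DataFrame(comp_rows)
    pct_rows = []
    for ps in spec.pressures:
        for region in comp.region.unique():
            sel = comp[(comp.pressure == ps.label) & (comp.region == region)]
            ref = float(sel[sel.case_id == spec.reference_case]
                        .compliance_m3_per_pa.iloc[0])
            for _, row in sel.iterrows():
                pct_rows.append({
                    "case_id": int(row.case_id), "pressure": ps.label,
                    "region": region,
                    "compliance_percent_decrease":
                        percent_change(ref, row.compliance_m3_per_pa)
                        if ref > 0 else np.nan})
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "case_table": spec.case_table,
        "backend": spec.backend,
        "resolution": list(spec.resolution),
        "reference_case": spec.reference_case,
        "integration_scheme": spec.options.integration_scheme,
        "pressures": [{"label": ps.label, "pulse_pressure_pa": ps.pulse_pressure,
                       "diastolic_baseline_pa": ps.diastolic_baseline}
                      for ps in spec.pressures],
    }
    return ReportBundle(comp, pd.DataFrame(pct_rows), pd.DataFrame(def_rows),
                        pd.DataFrame(vm_rows), manifest)


def _trend(values: list[float], increasing: bool) -> str:
    arr = np.asarray(values)
    if len(arr) <= 1:
        return "decreasing" if not increasing else "increasing"
    d = np.diff(arr)
    if np.all(d < 0):
        return "decreasing"
    if np.all(d > 0):
        return "increasing"
    if np.all(d == 0):
        return "flat"
    return "non-monotone"


def max_deformation_trend(bundle: ReportBundle, pressure: str | None = None,
                          region: str = "whole_model"
                          ) -> tuple[pd.DataFrame, str]:
    """Peak total deformation per case with a monotonicity verdict."""
    t = bundle.deformation_table
    if pressure is None:
        pressure = t.pressure.iloc[0]
    sel = t[(t.pressure == pressure) & (t.region == region)].sort_values("case_id")
    verdict = _trend(list(sel.max_deformation_m), increasing=False)
    return sel.reset_index(drop=True), verdict


def von_mises_trend(bundle: ReportBundle, pressure: str | None = None,
                    region: str = "whole_model") -> tuple[pd.DataFrame, str]:
    """Peak von Mises stress per case with a monotonicity verdict.

    Under the study sweeps the FEM peak stress rises with aortic
    stiffness.  The reduced (independent-tube Lamé) backend cannot show
    this: its hoop stress at fixed pressure is independent of E, so its
    verdict is 'flat' — a documented limitation, not a defect.
    """
    t = bundle.von_mises_table
    if pressure is None:
        pressure = t.pressure.iloc[0]
    sel = t[(t.pressure == pressure) & (t.region == region)].sort_values("case_id")
    verdict = _trend(list(sel.max_von_mises_pa), increasing=True)
    return sel.reset_index(drop=True), verdict
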