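#!/usr/bin/env python
"""Combine the saved sweep tables into the final comparison report.

Reads results/uniform_sweep/ and results/regional_sweep/ (run scripts
02 and 03 first), writes results/summary.csv with the headline
case 1 -> 5 percent compliance decreases, and, when matplotlib is
available, bar charts of the percent changes under results/figures/.
"""

from pathlib import Path

import pandas as pd

HEADLINE = [
    ("uniform", "aorta_carotid", "PP1"),
    ("uniform", "aorta_carotid", "PP2"),
    ("uniform", "aorta", "PP2"),
    ("uniform", "left_common_carotid", "PP1"),
    ("uniform", "right_common_carotid", "PP1"),
    ("regional", "ascending_aorta", "PP1"),
    ("regional", "aortic_arch", "PP1"),
    ("regional", "left_common_carotid", "PP1"),
    ("regional", "right_common_carotid", "PP1"),
]


def main() -> None:
    tables = {name: pd.read_csv(f"results/{name}_sweep/percent_change.csv")
              for name in ("uniform", "regional")}
    rows = []
    for sweep_name, region, pressure in HEADLINE:
        t = tables[sweep_name]
        sel = t[(t.case_id == 5) & (t.pressure == pressure)
                & (t.region == region)]
        rows.append({
            "sweep": sweep_name, "region": region, "pressure": pressure,
            "compliance_percent_decrease_case1_to_5":
                round(float(sel.compliance_percent_decrease.iloc[0]), 2)})
    summary = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    summary.to_csv("results/summary.csv", index=False)
    print(summary.to_string(index=False))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("\nmatplotlib not installed; skipping figures")
        return
    figdir = Path("results/figures")
    figdir.mkdir(parents=True, exist_ok=True)
    for name, t in tables.items():
        sel = t[(t.pressure == "PP1") & t.region.isin(
            ["aorta", "left_carotid", "right_carotid", "whole_model"])]
        pivot = sel.pivot(index="case_id", columns="region",
                          values="compliance_percent_decrease")
        ax = pivot.plot.bar(figsize=(7, 4))
        ax.set_xlabel("material case")
        ax.set_ylabel("compliance decrease vs case 1 (%)")
        ax.set_title(f"{name} aortic stiffness sweep")
        ax.figure.tight_layout()
        ax.figure.savefig(figdir / f"{name}_percent_change.png", dpi=120)
        plt.close(ax.figure)
    print(f"\nwrote {figdir}/uniform_percent_change.png and "
          f"{figdir}/regional_percent_change.png")


if __name__ == "__main__":
    main()
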