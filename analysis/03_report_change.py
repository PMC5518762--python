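#!/usr/bin/env python
"""Report the headline results from the tables written by the previous
step: overlap per scenario, range size per group, and the mixed-model
tests of the log change ratios. Optionally renders the three figure
analogues (overlap by scenario, range size by group, per-species log
ratios) as PNGs under scratch/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plots", action="store_true", help="also render PNGs")
    args = parser.parse_args()

    results = ROOT / "results"
    overlap = pd.read_csv(results / "overlap_by_scenario.csv")
    ranges = pd.read_csv(results / "range_by_group.csv")
    lmm = pd.read_csv(results / "lmm_tests.csv")
    ratios = pd.read_csv(results / "pair_log_ratios.csv")

    print("== mean overlap of garden plants with their congeners ==")
    print(overlap.to_string(index=False))
    print("\n== mean consensus range size per group ==")
    print(ranges.to_string(index=False))
    print("\n== mixed-model intercept tests of log change ratios ==")
    cols = ["scenario_id", "metric", "group", "intercept", "se", "p_value", "n_obs", "method"]
    print(lmm[cols].to_string(index=False))

    sev = lmm.query("scenario_id == 'SEVERE'")
    garden_range = sev.query("metric == 'range_size' and group == 'garden'")
    cong_range = sev.query("metric == 'range_size' and group == 'congener'")
    ov = sev.query("metric == 'mean_overlap_cells'")
    print("\nUnder the severe scenario:")
    if len(garden_range):
        print(f"  garden-plant range change (log ratio): {garden_range.intercept.iloc[0]:+.3f}")
    if len(cong_range):
        print(f"  congener range change (log ratio):     {cong_range.intercept.iloc[0]:+.3f}")
    if len(ov):
        r = ov.iloc[0]
        print(f"  overlap-cells change (log ratio):      {r.intercept:+.3f} (p = {r.p_value:.2g})")

    if args.plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = ROOT / "scratch" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        order = ["BASE", "MILD", "MEDIUM", "SEVERE"]
        ov_s = overlap.set_index("scenario_id").loc[order]
        axes[0].errorbar(order, ov_s["mean_tss_overlap"], yerr=ov_s["sd_tss_overlap"], fmt="o-")
        axes[0].set_ylabel("mean TSS overlap")
        axes[1].errorbar(order, ov_s["mean_overlap_cells"], yerr=ov_s["sd_overlap_cells"], fmt="o-")
        axes[1].set_ylabel("mean overlapping cells")
        fig.tight_layout()
        fig.savefig(figdir / "overlap_by_scenario.png", dpi=150)

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for group, marker in (("garden", "o"), ("congener", "^")):
            sub = ranges[ranges.group == group].set_index("scenario_id").loc[order]
            ax.errorbar(order, sub["mean_range_cells"], yerr=sub["sd_range_cells"],
                        fmt=marker + "-", label=group, capsize=3)
        ax.set_ylabel("mean range size (cells)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "range_size_by_group.png", dpi=150)

        fig, axes = plt.subplots(1, 3, figsize=(10, 3.5), sharey=True)
        for ax, scen in zip(axes, ["MILD", "MEDIUM", "SEVERE"]):
            sub = ratios[ratios.scenario_id == scen]
            ax.axhline(0, color="grey", lw=0.8)
            ax.plot([0] * len(sub), sub["log_ratio"], "o", alpha=0.6)
            ax.axhline(sub["log_ratio"].mean(), color="red")
            ax.set_title(scen)
            ax.set_xticks([])
        axes[0].set_ylabel("log overlap-cells ratio")
        fig.tight_layout()
        fig.savefig(figdir / "log_ratios.png", dpi=150)
        print(f"\nfigures written to {figdir}")


if __name__ == "__main__":
    main()
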