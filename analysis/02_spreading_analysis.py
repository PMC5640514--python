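#!/usr/bin/env python
"""Spreading-factor analysis of the simulated conditions.

Reads results/positions.csv (from 01_simulate_conditions.py), computes the
per-myotube nuclear spreading factor, summarizes each condition by mean and
interquartile range, and tests all condition pairs with the two-sided
Mann-Whitney test.  Writes results/sf_per_myotube.csv, results/sf_summary.csv,
results/sf_pairwise.csv, and a strip plot results/sf_comparison.png.
"""

import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from myonuc.spreading import compare_conditions, format_report, sf_table

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
ORDER = ("control", "no_ne_nucleation", "no_ne_nucleation_no_kif5b")
LABELS = ("+NE nucl\n+NE Kif5b", "−NE nucl\n+NE Kif5b",
          "−NE nucl\n−NE Kif5b")


def main():
    positions = pd.read_csv(RESULTS / "positions.csv")
    sf = sf_table(positions.rename(columns={"replicate_id": "myotube_id"}),
                  group="condition")
    sf.to_csv(RESULTS / "sf_per_myotube.csv", index=False)

    report = compare_conditions(sf)
    report["summary"].to_csv(RESULTS / "sf_summary.csv", index=False)
    report["pairwise"].to_csv(RESULTS / "sf_pairwise.csv", index=False)
    print(format_report(report))

    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, cond in enumerate(ORDER):
        vals = sf.loc[sf["condition"] == cond, "sf"].to_numpy()
        ax.plot(i + rng.uniform(-0.12, 0.12, vals.size), vals, "o",
                color="0.55", ms=4, alpha=0.8)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        ax.plot([i - 0.2, i + 0.2], [vals.mean()] * 2, color="tab:blue",
                lw=2.5, zorder=3)
        ax.vlines(i, q1, q3, color="k", lw=1.5)
    ax.set_xticks(range(len(ORDER)), LABELS)
    ax.set_ylabel("nuclear spreading factor")
    ax.set_ylim(0, 1.1)
    fig.tight_layout()
    fig.savefig(RESULTS / "sf_comparison.png", dpi=150)
    print(f"figure -> {RESULTS / 'sf_comparison.png'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
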