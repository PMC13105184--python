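"""Figures: observed-vs-predicted MST scatter and per-sample envelope bars.

Recreates the two standard views of the analysis from the tables written
by 02: (a) observed MST length against the scaling-law prediction at the
study-mean beta, with the 1:1 line; (b) for the 40 lowest-count samples,
the three benchmark envelopes as vertical bars with the observed length
overplotted. PNGs under results/figures/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "figures"

SCENARIO_COLORS = {"clustered": "tab:blue", "random": "tab:green", "over_dispersed": "black"}


def main() -> int:
    per_sample_path = STUDY / "per_sample.csv"
    summary_path = STUDY / "study_summary.csv"
    if not per_sample_path.exists():
        print("run analysis/02_run_pipeline.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(per_sample_path)
    summary = pd.read_csv(summary_path).iloc[0]

    mean_beta = summary["mean_beta"]
    predicted = mean_beta * np.sqrt(table["n_stomata"] * table["area_mm2"])
    fig, ax = plt.subplots(figsize=(5, 5))
    for site, marker_color in (("Antumapu", "tab:blue"), ("Frutillar", "tab:red")):
        mask = table["site"] == site
        ax.scatter(predicted[mask], table.loc[mask, "mst_length_mm"], s=14,
                   color=marker_color, alpha=0.7, label=site)
    lim = [0, 1.05 * max(predicted.max(), table["mst_length_mm"].max())]
    ax.plot(lim, lim, "k--", lw=1, label="1:1")
    ax.set_xlabel(f"predicted MST length (mm), beta = {mean_beta:.3f}")
    ax.set_ylabel("observed MST length (mm)")
    ax.set_title(f"Observed vs predicted (R$^2$ = {summary['r_squared']:.3f})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(OUT / "observed_vs_predicted.png", dpi=150)

    sub = table.nsmallest(40, "n_stomata").sort_values("n_stomata").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(10, 4))
    for kind, color in SCENARIO_COLORS.items():
        ax.vlines(
            sub.index + {"clustered": -0.22, "random": 0.0, "over_dispersed": 0.22}[kind],
            sub[f"{kind}_ci_low_mm"], sub[f"{kind}_ci_high_mm"],
            color=color, lw=2.2, label=kind.replace("_", "-"),
        )
    ax.scatter(sub.index, sub["mst_length_mm"], color="red", s=12, zorder=3, label="observed")
    ax.set_xticks(sub.index)
    ax.set_xticklabels(sub["sample_id"], rotation=90, fontsize=6)
    for i, n in enumerate(sub["n_stomata"]):
        ax.annotate(str(n), (i, ax.get_ylim()[0]), fontsize=5, ha="center")
    ax.set_ylabel("MST length (mm)")
    ax.set_title("Benchmark envelopes (95% bands) vs observed, 40 sparsest samples")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "envelopes.png", dpi=150)
    print(f"wrote {OUT / 'observed_vs_predicted.png'}")
    print(f"wrote {OUT / 'envelopes.png'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
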