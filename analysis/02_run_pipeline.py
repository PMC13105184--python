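"""Run the full pattern-analysis pipeline on the synthetic study.

Reads the centroid tables and metadata written by 01, computes each
sample's Euclidean MST and normalised scaling statistic, simulates the
three matched benchmark envelopes (200 replicates each here; a
publication-scale run would use 1,000 — the manifest flags this), and
classifies every sample by envelope membership. Tables go to
results/study/.
"""

import sys
from pathlib import Path

from stomanet.pipeline import RunConfig, run_analysis

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic_study"
OUT = ROOT / "results" / "study"


def main() -> int:
    if not DATA.exists():
        print("run analysis/01_simulate_study.py first", file=sys.stderr)
        return 1
    config = RunConfig(
        centroid_dir=str(DATA / "centroids"),
        metadata_path=str(DATA / "metadata.csv"),
        out_dir=str(OUT),
        reps=200,
        seed=7,
    )
    res = run_analysis(config)
    s = res.summary
    print(f"analyzed {s['n_samples']} samples ({s['n_failed']} failed) -> {OUT}")
    print(
        f"  mean beta_hat = {s['mean_beta']:.4f} "
        f"(95% {s['beta_ci_method']}-CI [{s['beta_ci_low']:.4f}, {s['beta_ci_high']:.4f}]); "
        f"origin-slope beta = {s['beta_origin_slope']:.4f}"
    )
    print(
        f"  observed vs predicted: R^2 = {s['r_squared']:.3f}; "
        f"Pearson r(N, L) = {s['pearson_r_n_vs_length']:.3f} "
        f"[{s['pearson_n_length_ci_low']:.3f}, {s['pearson_n_length_ci_high']:.3f}]"
    )
    print(
        f"  Pearson r(N, diameter) = {s['pearson_r_n_vs_diameter']:.3f} "
        f"[{s['pearson_n_diameter_ci_low']:.3f}, {s['pearson_n_diameter_ci_high']:.3f}]"
    )
    print(
        "  classification shares: "
        f"clustered {s['pct_exclusive_clustered']:.1f}%, "
        f"random {s['pct_exclusive_random']:.1f}%, "
        f"over-dispersed {s['pct_exclusive_over_dispersed']:.1f}%, "
        f"non-exclusive {s['pct_non_exclusive']:.1f}%"
    )
    print(
        f"  above over-dispersed band: {s['pct_above_overdispersed']:.1f}%; "
        f"within-or-above over-dispersed: {s['pct_within_or_above_overdispersed']:.1f}%"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
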