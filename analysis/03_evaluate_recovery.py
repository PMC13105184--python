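"""Evaluate how well classification recovers the known generating process.

Joins the per-sample classification table from 02 with the ground-truth
labels from 01 and reports, per truth scenario, the fraction of samples
whose envelope membership includes (or whose position sits on the correct
side of) their true scenario. Writes results/truth_recovery.csv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PER_SAMPLE = ROOT / "results" / "study" / "per_sample.csv"
TRUTH = ROOT / "scratch" / "synthetic_study" / "truth.csv"
OUT = ROOT / "results" / "truth_recovery.csv"


def main() -> int:
    if not (PER_SAMPLE.exists() and TRUTH.exists()):
        print("run analysis/01 and 02 first", file=sys.stderr)
        return 1
    table = pd.read_csv(PER_SAMPLE).merge(pd.read_csv(TRUTH), on="sample_id")
    rows = []
    for truth, group in table.groupby("truth_scenario"):
        member = group[f"member_{truth}"].mean()
        exclusive_hit = (group["exclusive"] & group[f"member_{truth}"]).mean()
        rows.append(
            {
                "truth_scenario": truth,
                "n": len(group),
                "membership_recovery": member,
                "exclusive_recovery": exclusive_hit,
                "median_beta_hat": group["beta_hat"].median(),
            }
        )
    recovery = pd.DataFrame(rows).sort_values("truth_scenario")
    recovery.to_csv(OUT, index=False, float_format="%.4f")
    print(recovery.to_string(index=False))
    ordered = (
        recovery.set_index("truth_scenario")
        .loc[["clustered", "random", "over_dispersed"], "median_beta_hat"]
        .tolist()
    )
    print(
        "median beta_hat ordered clustered < random < over-dispersed: "
        f"{ordered[0]:.3f} < {ordered[1]:.3f} < {ordered[2]:.3f} -> "
        f"{'yes' if ordered[0] < ordered[1] < ordered[2] else 'NO'}"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
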