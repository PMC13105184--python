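"""End-to-end study runs: read → MST → beta → envelopes → classify → summarise.

One :func:`run_analysis` call takes a directory of centroid tables plus a
metadata CSV, computes each sample's MST summary and normalised scaling
statistic, simulates the three matched benchmark envelopes, classifies
every sample, and writes the per-sample table, study summary, and a JSON
run manifest. Per-sample failures are isolated (flagged rows) unless
``strict`` is set. Results are deterministic in the master seed, with
per-(sample, scenario) substreams so sample order does not matter.
"""

from __future__ import annotations

import math
import time
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from stomanet import io
from stomanet.network import compute_emst, mst_summary
from stomanet.patterns import StomatalSample
from stomanet.scaling import (
    BetaEstimate,
    UndefinedStatisticError,
    aggregate_beta,
    beta_hat,
    fit_predicted_vs_observed,
    origin_slope,
    pearson_with_ci,
)
from stomanet.simulate import (
    SCENARIO_ORDER,
    ScenarioSpec,
    classify_sample,
    simulate_envelope,
    summarize_classifications,
)

SCENARIO_CODE = {kind: i + 1 for i, kind in enumerate(SCENARIO_ORDER)}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run (echoed verbatim into the manifest)."""

    centroid_dir: str
    metadata_path: str
    out_dir: str
    unit_scale: float = 1.0
    window_policy: str = "auto"  # "auto" (declared-area expansion) or "tight"
    reps: int = 1000
    n_clusters: int = 4
    cluster_sd_factor: float = 0.08  # cluster spread as a fraction of sqrt(area)
    ci_method: str = "t"  # "t" or "bootstrap" for the study-level beta CI
    seed: int = 0
    jitter: bool = False
    strict: bool = False
    allow_partial: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class StudyResults:
    per_sample: pd.DataFrame
    summary: dict
    manifest: dict
    classifications: list
    paths: dict = field(default_factory=dict)


def _scenario_rng(seed: int, sample_id: str, kind: str) -> np.random.Generator:
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, key, SCENARIO_CODE[kind]))
    )


def load_study(config: RunConfig) -> tuple[list[StomatalSample], io.ReconciliationReport, dict]:
    """Read and join all centroid tables and metadata for a run."""
    metadata = io.read_metadata_table(config.metadata_path)
    meta_by_id = {m.sample_id: m for m in metadata}
    centroid_dir = Path(config.centroid_dir)
    patterns = {}
    window_fallbacks = []
    for path in sorted(centroid_dir.glob("*.csv")) + sorted(centroid_dir.glob("*.tsv")):
        sid = path.stem
        meta = meta_by_id.get(sid)
        declared = meta.area_mm2 if (meta and config.window_policy == "auto") else None
        jitter_um = (
            0.01 * meta.diameter_um if (config.jitter and meta is not None) else None
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            patterns[sid] = io.read_centroid_table(
                path,
                unit_scale=config.unit_scale,
                declared_area_mm2=declared,
                jitter_um=jitter_um,
                rng=np.random.default_rng(
                    np.random.SeedSequence(entropy=(config.seed, zlib.crc32(sid.encode()), 0))
                ),
            )
        if any("bounding box" in str(w.message) for w in caught):
            window_fallbacks.append(sid)
    samples, report = io.assemble_samples(patterns, metadata)
    diagnostics = {"window_fallbacks": window_fallbacks}
    return samples, report, diagnostics


def analyze_sample(
    sample: StomatalSample, config: RunConfig
) -> tuple[dict, object | None, list[str]]:
    """All per-sample computation: MST, beta_hat, envelopes, classification.

    Returns the per-sample result row, the classification (None when the
    sample is degenerate), and accumulated warnings.
    """
    notes: list[str] = []
    mst = compute_emst(sample.pattern)
    summ = mst_summary(mst)
    n = sample.pattern.n
    area = sample.area_mm2
    row = {
        "sample_id": sample.sample_id,
        "species": sample.species,
        "site": sample.site,
        "n_stomata": n,
        "area_mm2": area,
        "diameter_um": sample.stomatal_diameter_um,
        "mst_length_um": summ.total_length * 1000.0,
        "mst_mean_edge_um": summ.mean_edge * 1000.0,
        "mst_sd_edge_um": summ.sd_edge * 1000.0,
    }
    try:
        row["beta_hat"] = beta_hat(summ.total_length, n, area)
    except UndefinedStatisticError:
        row["beta_hat"] = float("nan")
        row["flag"] = "undefined_beta"
        notes.append(f"{sample.sample_id}: n={n} < 2, beta_hat undefined")
    if n < 2:
        return row, None, notes

    cluster_sd = config.cluster_sd_factor * math.sqrt(area)
    specs = {
        "clustered": ScenarioSpec(
            "clustered", n_clusters=config.n_clusters, cluster_sd=cluster_sd, reps=config.reps
        ),
        "random": ScenarioSpec("random", reps=config.reps),
        "over_dispersed": ScenarioSpec(
            "over_dispersed", inhibition_distance=sample.diameter_mm, reps=config.reps
        ),
    }
    envelopes = {}
    for kind, spec in specs.items():
        rng = _scenario_rng(config.seed, sample.sample_id, kind)
        envelopes[kind] = simulate_envelope(spec, n, sample.pattern.window, rng)
        row[f"{kind}_median_mm"] = envelopes[kind].median
        row[f"{kind}_ci_low_mm"] = envelopes[kind].ci_low
        row[f"{kind}_ci_high_mm"] = envelopes[kind].ci_high
        if envelopes[kind].infeasible_count:
            notes.append(
                f"{sample.sample_id}: {envelopes[kind].infeasible_count} infeasible "
                f"{kind} replicate(s)"
            )
    result, order_warnings = classify_sample(
        summ.total_length, envelopes, sample_id=sample.sample_id
    )
    notes.extend(f"{sample.sample_id}: {w}" for w in order_warnings)
    for kind in SCENARIO_ORDER:
        row[f"member_{kind}"] = kind in result.membership
    row["position"] = result.position
    row["exclusive"] = result.exclusive
    return row, result, notes


def run_analysis(config: RunConfig) -> StudyResults:
    """Run the full pipeline and write all results tables.

    Study-level outputs: the mean normalised MST statistic with its 95% CI
    (t or bootstrap), the regression-through-origin alternative estimate,
    observed-vs-predicted fit statistics at the study mean, the Pearson
    correlations of stomata count with MST length and with stomatal
    diameter, and the classification share table.
    """
    t0 = time.time()
    samples, report, diagnostics = load_study(config)
    if not report.is_clean() and not config.allow_partial:
        if report.unmatched_metadata or report.orphan_patterns:
            raise ValueError(
                f"pattern/metadata mismatch (use allow_partial to proceed): {report}"
            )
    rows = []
    classifications = []
    notes: list[str] = []
    failed: list[str] = []
    for sample in samples:
        try:
            row, result, sample_notes = analyze_sample(sample, config)
        except Exception as exc:  # per-sample isolation
            if config.strict:
                raise
            failed.append(sample.sample_id)
            rows.append({"sample_id": sample.sample_id, "flag": f"failed: {exc}"})
            continue
        rows.append(row)
        notes.extend(sample_notes)
        if result is not None:
            classifications.append(result)
    per_sample = pd.DataFrame(rows)

    summary: dict = {"n_samples": len(samples), "n_failed": len(failed)}
    if "beta_hat" in per_sample.columns:
        valid = per_sample[per_sample["beta_hat"].notna()]
    else:
        valid = per_sample.iloc[0:0]
    if len(valid) >= 2:
        estimates = [
            BetaEstimate(r.beta_hat, int(r.n_stomata), float(r.area_mm2), r.mst_length_um / 1000.0)
            for r in valid.itertuples()
        ]
        study_beta = aggregate_beta(
            estimates, method=config.ci_method, seed=np.random.default_rng(config.seed)
        )
        summary.update(
            mean_beta=study_beta.mean_beta,
            beta_ci_low=study_beta.ci_low,
            beta_ci_high=study_beta.ci_high,
            beta_ci_method=study_beta.method,
            beta_origin_slope=origin_slope(
                [e.mst_length for e in estimates],
                [e.n for e in estimates],
                [e.area for e in estimates],
            ),
        )
        if len(valid) >= 4:
            fit = fit_predicted_vs_observed(
                [(e.mst_length, e.n, e.area) for e in estimates], study_beta.mean_beta
            )
            summary.update(
                r_squared=fit.r_squared,
                pearson_r_pred_vs_obs=fit.pearson_r,
            )
            r, lo, hi = pearson_with_ci(
                valid["n_stomata"].to_numpy(float), valid["mst_length_um"].to_numpy(float)
            )
            summary.update(pearson_r_n_vs_length=r, pearson_n_length_ci_low=lo, pearson_n_length_ci_high=hi)
            r, lo, hi = pearson_with_ci(
                valid["n_stomata"].to_numpy(float), valid["diameter_um"].to_numpy(float)
            )
            summary.update(
                pearson_r_n_vs_diameter=r,
                pearson_n_diameter_ci_low=lo,
                pearson_n_diameter_ci_high=hi,
            )
    if classifications:
        summary.update(summarize_classifications(classifications))

    manifest = {
        "config": asdict(config),
        "n_samples": len(samples),
        "n_failed": len(failed),
        "failed_samples": failed,
        "reconciliation": {
            "orphan_patterns": list(report.orphan_patterns),
            "unmatched_metadata": list(report.unmatched_metadata),
        },
        "window_fallbacks": diagnostics["window_fallbacks"],
        "warnings": notes,
        "reduced_replicates": config.reps < 1000,
        "runtime_s": round(time.time() - t0, 3),
    }
    paths = io.write_results(per_sample, summary, manifest, config.out_dir)
    return StudyResults(per_sample, summary, manifest, classifications, paths)
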