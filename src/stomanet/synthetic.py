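"""Synthetic study generator: a full two-site stomatal dataset with known truth.

Emulates the shape of a ~180-sample, two-site leaf survey: stomatal
densities spanning three orders of magnitude (3–777 per mm^2, drawn
log-uniformly), a negative density–diameter association (bigger stomata
where they are sparse), one site shifted toward higher densities, and a
mixture of clustered / random / hard-core generating processes. Every file
it writes uses exactly the dialects the readers in :mod:`stomanet.io`
consume, plus a ground-truth CSV for recovery tests.

What it deliberately does not emulate: species identities are placeholder
labels with no phylogenetic structure, observation areas are uniform
squares, and densities/diameters are drawn independently across samples.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stomanet.patterns import ObservationWindow, StomatalSample
from stomanet.simulate import (
    PackingInfeasibleError,
    simulate_clustered,
    simulate_csr,
    simulate_inhibited,
)

TRUTH_KINDS = ("clustered", "random", "over_dispersed")


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic study.

    ``truth_mix`` gives the proportions of clustered / random /
    over-dispersed generating processes (must sum to 1); ``sites`` maps
    site labels to sample shares; ``site_density_shift`` moves each site's
    log-density draw toward the high (positive) or low (negative) end of
    ``density_range`` by that fraction of the log-range. Diameters follow
    ``diameter_a - diameter_b * ln(density) + N(0, diameter_noise_um)``,
    floored at 5 µm, giving the negative density–diameter association.
    """

    n_samples: int = 180
    sites: dict = field(
        default_factory=lambda: {"Antumapu": 0.5, "Frutillar": 0.5}
    )
    site_density_shift: dict = field(
        default_factory=lambda: {"Antumapu": 0.35, "Frutillar": -0.35}
    )
    density_range: tuple[float, float] = (3.0, 777.0)
    area_mm2: float = 1.0
    truth_mix: tuple[float, float, float] = (0.10, 0.30, 0.60)
    cluster_sd_factor: float = 0.08  # offspring sd as a fraction of sqrt(area)
    n_clusters: int = 4
    diameter_a: float = 40.0
    diameter_b: float = 4.0
    diameter_noise_um: float = 2.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.density_range[0] < 1 or self.density_range[1] <= self.density_range[0]:
            raise ValueError(f"bad density_range {self.density_range}")
        if abs(sum(self.truth_mix) - 1.0) > 1e-9:
            raise ValueError(f"truth_mix must sum to 1, got {self.truth_mix}")
        if abs(sum(self.sites.values()) - 1.0) > 1e-9:
            raise ValueError(f"site shares must sum to 1, got {self.sites}")
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")


def _sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Independent, order-free stream for one sample, keyed by its id."""
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=(master_seed, key)))


def generate_sample(
    density: float,
    area: float,
    diameter_um: float,
    truth: str,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
    species: str = "Synthetica exemplaris",
    site: str = "S",
    cluster_sd: float | None = None,
    n_clusters: int = 4,
) -> tuple[StomatalSample, dict]:
    """One synthetic sample with its ground-truth record.

    ``n = max(1, round(density * area))`` points are drawn from the
    generator matching ``truth`` in a square window of the given area.
    An infeasible hard-core request is retried with the diameter shrunk by
    20% up to five times (each shrink logged in the truth record); if still
    infeasible the error propagates.
    """
    if truth not in TRUTH_KINDS:
        raise ValueError(f"unknown truth scenario {truth!r}")
    n = max(1, round(density * area))
    window = ObservationWindow.square(area)
    if cluster_sd is None:
        cluster_sd = 0.08 * math.sqrt(area)
    eff_diameter = diameter_um
    shrinks = 0
    while True:
        try:
            if truth == "random":
                pattern = simulate_csr(n, window, rng)
            elif truth == "clustered":
                pattern = simulate_clustered(n, window, cluster_sd, rng, n_clusters)
            else:
                # tighter attempt budget than the simulator default so that
                # over-packed requests fail fast and trigger a shrink retry
                pattern = simulate_inhibited(
                    n, window, eff_diameter / 1000.0, rng, max_attempts=200 * n
                )
            break
        except PackingInfeasibleError:
            shrinks += 1
            if shrinks > 5:
                raise
            eff_diameter *= 0.8
    sample = StomatalSample(
        sample_id=sample_id,
        species=species,
        site=site,
        pattern=pattern,
        stomatal_diameter_um=diameter_um,
    )
    truth_record = {
        "sample_id": sample_id,
        "truth_scenario": truth,
        "n": n,
        "density_per_mm2": density,
        "generator_params": json.dumps(
            {
                "cluster_sd_mm": cluster_sd if truth == "clustered" else None,
                "n_clusters": n_clusters if truth == "clustered" else None,
                "inhibition_distance_mm": eff_diameter / 1000.0
                if truth == "over_dispersed"
                else None,
                "diameter_shrinks": shrinks,
            }
        ),
    }
    return sample, truth_record


def generate_study(design: StudyDesign, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study to disk.

    Produces ``centroids/<sample_id>.csv`` (X,Y in µm), ``metadata.csv``
    and ``truth.csv``. Densities are log-uniform over the design range with
    the per-site shift applied in log space (clipped to the range);
    allocation of samples to sites and truth scenarios is deterministic in
    the design (largest-remainder rounding), and each sample draws from an
    independent stream keyed by its id, so the same master seed yields a
    byte-identical file tree. Samples still infeasible after diameter
    shrinks are recorded as failed in truth.csv and skipped.
    """
    out = Path(out_dir)
    centroid_dir = out / "centroids"
    centroid_dir.mkdir(parents=True, exist_ok=True)

    site_labels = _allocate(design.n_samples, design.sites)
    truth_labels = _allocate(
        design.n_samples, dict(zip(TRUTH_KINDS, design.truth_mix))
    )
    # interleave truth across sites deterministically
    order_rng = np.random.default_rng(np.random.SeedSequence(entropy=(design.master_seed, 0xA110C)))
    order_rng.shuffle(truth_labels)

    lo, hi = (math.log(d) for d in design.density_range)
    meta_rows = []
    truth_rows = []
    for i in range(design.n_samples):
        site = site_labels[i]
        truth = truth_labels[i]
        sid = f"{site[0]}{i + 1:03d}"
        rng = _sample_rng(design.master_seed, sid)
        shift = design.site_density_shift.get(site, 0.0) * (hi - lo)
        logd = np.clip(rng.uniform(lo, hi) + shift, lo, hi)
        density = math.exp(logd)
        diameter = max(
            5.0,
            design.diameter_a
            - design.diameter_b * logd
            + rng.normal(0.0, design.diameter_noise_um),
        )
        try:
            sample, record = generate_sample(
                density,
                design.area_mm2,
                diameter,
                truth,
                rng,
                sample_id=sid,
                species=f"Synthetica sp{(i % 40) + 1:02d}",
                site=site,
                cluster_sd=design.cluster_sd_factor * math.sqrt(design.area_mm2),
                n_clusters=design.n_clusters,
            )
        except PackingInfeasibleError as exc:
            truth_rows.append(
                {
                    "sample_id": sid,
                    "truth_scenario": truth,
                    "n": max(1, round(density * design.area_mm2)),
                    "density_per_mm2": density,
                    "generator_params": json.dumps({"failed": str(exc)}),
                }
            )
            continue
        pts_um = sample.pattern.points * 1000.0
        pd.DataFrame({"X": pts_um[:, 0], "Y": pts_um[:, 1]}).to_csv(
            centroid_dir / f"{sid}.csv", index=False, float_format="%.6f"
        )
        meta_rows.append(
            {
                "sample_id": sid,
                "species": sample.species,
                "site": site,
                "area_mm2": design.area_mm2,
                "diameter_um": round(diameter, 3),
            }
        )
        truth_rows.append(record)

    meta_path = out / "metadata.csv"
    truth_path = out / "truth.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False, float_format="%.6f")
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, float_format="%.6f")
    return {"centroids": centroid_dir, "metadata": meta_path, "truth": truth_path}


def _allocate(n: int, shares: dict) -> list:
    """Deterministic largest-remainder allocation of n slots to labels."""
    labels = sorted(shares)
    exact = {lab: n * shares[lab] for lab in labels}
    counts = {lab: int(math.floor(exact[lab])) for lab in labels}
    short = n - sum(counts.values())
    by_remainder = sorted(labels, key=lambda lab: (-(exact[lab] - counts[lab]), lab))
    for lab in by_remainder[:short]:
        counts[lab] += 1
    out: list = []
    for lab in labels:
        out.extend([lab] * counts[lab])
    return out
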