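"""Benchmark point processes, Monte-Carlo envelopes, and CI classification.

Each empirical sample is compared against three simulated benchmarks with
the same point count and observation window:

* clustered — offspring scattered around four parent centres (Gaussian
  displacements, rejection-resampled into the window);
* random — complete spatial randomness, i.e. the binomial process (a
  homogeneous Poisson process conditioned on the observed count);
* over-dispersed — hard-core inhibition by random sequential placement
  with a minimum inter-point distance equal to the sample's mean stomatal
  diameter.

The MST total length of many replicates per scenario forms a Monte-Carlo
envelope (median and 2.5–97.5 percentile band); a sample is a member of
every scenario whose band contains its observed MST length, which can be
none (e.g. more over-dispersed than the hard-core benchmark) or several
(overlapping bands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Sequence

import numpy as np

from stomanet.network import mst_total_length
from stomanet.patterns import ObservationWindow, PointPattern

ScenarioKind = Literal["clustered", "random", "over_dispersed"]

#: canonical scenario order from shortest to longest expected MST
SCENARIO_ORDER: tuple[ScenarioKind, ...] = ("clustered", "random", "over_dispersed")

#: densest possible packing of equal discs in the plane (hexagonal)
HEX_PACKING_FRACTION = math.pi / (2 * math.sqrt(3))  # ~0.9069


class PackingInfeasibleError(RuntimeError):
    """Hard-core placement cannot fit the requested number of points."""

    def __init__(self, message: str, placed: int, requested: int):
        super().__init__(message)
        self.placed = placed
        self.requested = requested


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one benchmark scenario.

    ``cluster_sd`` (mm) is the Gaussian offspring spread of the clustered
    process; ``inhibition_distance`` (mm) the hard-core distance of the
    over-dispersed process. Each scenario uses only its own parameter.
    """

    kind: ScenarioKind
    n_clusters: int = 4
    cluster_sd: float | None = None
    inhibition_distance: float | None = None
    reps: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_ORDER:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.kind == "clustered":
            if self.n_clusters < 1:
                raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
            if self.cluster_sd is None or self.cluster_sd <= 0:
                raise ValueError(f"clustered scenario needs cluster_sd > 0, got {self.cluster_sd}")
        if self.kind == "over_dispersed":
            if self.inhibition_distance is None or self.inhibition_distance <= 0:
                raise ValueError(
                    f"over-dispersed scenario needs inhibition_distance > 0, "
                    f"got {self.inhibition_distance}"
                )


@dataclass(frozen=True)
class ScenarioEnvelope:
    """Monte-Carlo distribution of MST lengths under one scenario.

    ``ci_low``/``ci_high`` are the 2.5th/97.5th percentiles of the replicate
    lengths; with a single replicate the band degenerates onto that value.
    """

    spec: ScenarioSpec
    lengths: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    infeasible_count: int = 0

    def contains(self, length: float) -> bool:
        return self.ci_low <= length <= self.ci_high


@dataclass(frozen=True)
class ClassificationResult:
    """CI-membership set and relational position of one sample."""

    sample_id: str
    membership: frozenset
    position: str
    exclusive: bool
    observed_length: float = field(default=float("nan"), compare=False)


def _uniform_in(window: ObservationWindow, size: int, rng: np.random.Generator) -> np.ndarray:
    pts = rng.random((size, 2))
    pts[:, 0] = window.x_min + pts[:, 0] * window.width
    pts[:, 1] = window.y_min + pts[:, 1] * window.height
    return pts


def simulate_csr(n: int, window: ObservationWindow, rng: np.random.Generator) -> PointPattern:
    """Complete spatial randomness: n i.i.d. uniform points in the window."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return PointPattern(_uniform_in(window, n, rng), window, allow_duplicates=True)


def simulate_clustered(
    n: int,
    window: ObservationWindow,
    cluster_sd: float,
    rng: np.random.Generator,
    n_clusters: int = 4,
    max_tries_per_point: int = 1000,
) -> PointPattern:
    """Clustered pattern: Gaussian offspring around uniform parent centres.

    Parents are drawn uniformly on the window shrunk inward by one
    ``cluster_sd`` per side (so clusters are not half-outside); points are
    split across parents as evenly as possible with the remainder assigned
    at random; each offspring is parent + isotropic N(0, cluster_sd^2)
    displacement, redrawn until it lands inside the window.
    """
    if cluster_sd <= 0:
        raise ValueError(f"cluster_sd must be positive, got {cluster_sd}")
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    inset = min(cluster_sd, window.width / 4, window.height / 4)
    core = ObservationWindow(
        window.x_min + inset, window.y_min + inset, window.x_max - inset, window.y_max - inset
    )
    parents = _uniform_in(core, n_clusters, rng)
    counts = np.full(n_clusters, n // n_clusters)
    remainder = n % n_clusters
    if remainder:
        counts[rng.choice(n_clusters, size=remainder, replace=False)] += 1
    pts = np.empty((n, 2))
    k = 0
    for parent, cnt in zip(parents, counts):
        for _ in range(cnt):
            for attempt in range(max_tries_per_point):
                p = parent + rng.normal(0.0, cluster_sd, size=2)
                if (
                    window.x_min <= p[0] <= window.x_max
                    and window.y_min <= p[1] <= window.y_max
                ):
                    pts[k] = p
                    k += 1
                    break
            else:
                raise PackingInfeasibleError(
                    f"clustered placement: {max_tries_per_point} rejected draws for one "
                    f"offspring (cluster_sd={cluster_sd} vs window {window.width}x{window.height})",
                    placed=k,
                    requested=n,
                )
    return PointPattern(pts, window, allow_duplicates=True)


def simulate_inhibited(
    n: int,
    window: ObservationWindow,
    d_min: float,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> PointPattern:
    """Hard-core pattern by random sequential placement (dart throwing).

    Uniform candidates are accepted iff at least ``d_min`` from every
    accepted point, so all pairwise distances of the result are >= d_min.
    A request whose disc packing fraction n*pi*(d_min/2)^2/A exceeds the
    hexagonal bound (~0.9069) is rejected immediately; otherwise placement
    that exhausts ``max_attempts`` (default 10,000*n) raises with the count
    of points placed so far.
    """
    if d_min <= 0:
        raise ValueError(f"d_min must be positive, got {d_min}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return PointPattern(np.empty((0, 2)), window, allow_duplicates=True)
    packing = n * math.pi * (d_min / 2) ** 2 / window.area()
    if packing > HEX_PACKING_FRACTION:
        raise PackingInfeasibleError(
            f"packing fraction {packing:.3f} exceeds the hexagonal bound "
            f"{HEX_PACKING_FRACTION:.4f}: {n} discs of diameter {d_min} cannot fit "
            f"in area {window.area():.4g}",
            placed=0,
            requested=n,
        )
    if max_attempts is None:
        max_attempts = 10_000 * n
    d2 = d_min * d_min
    inv = 1.0 / d_min
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        batch = min(max(4 * n, 64), max_attempts - attempts)
        if batch <= 0:
            raise PackingInfeasibleError(
                f"hard-core placement stalled after {attempts} attempts: "
                f"{placed}/{n} points placed (d_min={d_min})",
                placed=placed,
                requested=n,
            )
        cand = _uniform_in(window, batch, rng)
        for cx, cy in cand:
            attempts += 1
            gx = math.floor(cx * inv)
            gy = math.floor(cy * inv)
            ok = True
            for ix in (gx - 1, gx, gx + 1):
                for iy in (gy - 1, gy, gy + 1):
                    for k in grid.get((ix, iy), ()):
                        dx = pts[k, 0] - cx
                        dy = pts[k, 1] - cy
                        if dx * dx + dy * dy < d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[placed] = (cx, cy)
                grid.setdefault((gx, gy), []).append(placed)
                placed += 1
                if placed == n:
                    break
    return PointPattern(pts, window, allow_duplicates=True)


def simulate_pattern(
    spec: ScenarioSpec, n: int, window: ObservationWindow, rng: np.random.Generator
) -> PointPattern:
    """Dispatch one pattern draw for the scenario in ``spec``."""
    if spec.kind == "random":
        return simulate_csr(n, window, rng)
    if spec.kind == "clustered":
        return simulate_clustered(n, window, spec.cluster_sd, rng, spec.n_clusters)
    return simulate_inhibited(n, window, spec.inhibition_distance, rng)


def simulate_envelope(
    spec: ScenarioSpec,
    n: int,
    window: ObservationWindow,
    rng: np.random.Generator,
    max_infeasible_fraction: float = 0.01,
) -> ScenarioEnvelope:
    """Monte-Carlo envelope of MST total lengths under one scenario.

    Each of ``spec.reps`` replicates gets an independent child stream of
    ``rng``, so envelopes are reproducible and replicate-order independent.
    Infeasible hard-core replicates are skipped up to
    ``max_infeasible_fraction`` of reps, beyond which the envelope aborts
    with packing diagnostics.
    """
    if n < 2:
        raise ValueError(f"envelope needs n >= 2, got {n}")
    streams = rng.spawn(spec.reps)
    lengths = np.empty(spec.reps)
    kept = 0
    infeasible = 0
    last_error: PackingInfeasibleError | None = None
    for sub in streams:
        try:
            pattern = simulate_pattern(spec, n, window, sub)
        except PackingInfeasibleError as exc:
            infeasible += 1
            last_error = exc
            if infeasible > max_infeasible_fraction * spec.reps:
                raise PackingInfeasibleError(
                    f"envelope aborted: {infeasible}/{spec.reps} infeasible replicates "
                    f"for scenario {spec.kind} (last: {exc})",
                    placed=exc.placed,
                    requested=n,
                ) from exc
            continue
        lengths[kept] = mst_total_length(pattern.points)
        kept += 1
    lengths = lengths[:kept]
    if kept == 0:
        raise PackingInfeasibleError(
            f"envelope for scenario {spec.kind}: all replicates infeasible ({last_error})",
            placed=0,
            requested=n,
        )
    lo, med, hi = np.percentile(lengths, [2.5, 50.0, 97.5])
    return ScenarioEnvelope(spec, lengths, float(med), float(lo), float(hi), infeasible)


# position labels, ordered from shortest to longest observed MST
POSITIONS = (
    "below_clustered",
    "within_or_overlapping",
    "between_clustered_random",
    "between_random_overdispersed",
    "above_overdispersed",
)


def classify_sample(
    observed_length: float,
    envelopes: Dict[str, ScenarioEnvelope],
    sample_id: str = "",
) -> tuple[ClassificationResult, list[str]]:
    """Classify one sample by envelope membership and relational position.

    Membership is the set of scenarios whose 95% band contains the observed
    MST length; ``exclusive`` is true iff exactly one. The position label
    locates the observation relative to the ordered bands: below every band,
    inside/overlapping them, in one of the two gaps, or above the
    over-dispersed band. Returns the result plus any ordering warnings
    (classification proceeds on the raw bounds regardless).
    """
    missing = [k for k in SCENARIO_ORDER if k not in envelopes]
    if missing:
        raise ValueError(f"missing envelopes for scenarios: {missing}")
    warnings: list[str] = []
    medians = [envelopes[k].median for k in SCENARIO_ORDER]
    if not (medians[0] <= medians[1] <= medians[2]):
        warnings.append(
            f"scenario medians not ordered clustered <= random <= over_dispersed: "
            f"{dict(zip(SCENARIO_ORDER, medians))}"
        )
    membership = frozenset(k for k in SCENARIO_ORDER if envelopes[k].contains(observed_length))
    clu, ran, over = (envelopes[k] for k in SCENARIO_ORDER)
    if observed_length > over.ci_high:
        position = "above_overdispersed"
    elif observed_length < clu.ci_low:
        position = "below_clustered"
    elif membership:
        position = "within_or_overlapping"
    elif ran.ci_high < observed_length < over.ci_low:
        position = "between_random_overdispersed"
    elif clu.ci_high < observed_length < ran.ci_low:
        position = "between_clustered_random"
    else:
        # only reachable when the bands are not in canonical order
        position = "within_or_overlapping"
    result = ClassificationResult(
        sample_id=sample_id,
        membership=membership,
        position=position,
        exclusive=len(membership) == 1,
        observed_length=observed_length,
    )
    return result, warnings


def summarize_classifications(results: Sequence[ClassificationResult]) -> dict:
    """Study-level counts and percentages of the classification outcomes.

    Mirrors how such studies are reported: exclusive shares per scenario,
    the non-exclusive share (membership of zero or >= 2 scenarios), the two
    notable subsets of the non-exclusive group (the random/over-dispersed
    gap and observations above the over-dispersed band), and the composite
    shares "within or above the over-dispersed band" and "above the random
    band".
    """
    if not results:
        raise ValueError("no classification results to summarise")
    n = len(results)

    def share(count: int) -> float:
        return 100.0 * count / n

    counts = {
        "n_classified": n,
        "exclusive_clustered": sum(
            1 for r in results if r.exclusive and "clustered" in r.membership
        ),
        "exclusive_random": sum(1 for r in results if r.exclusive and "random" in r.membership),
        "exclusive_over_dispersed": sum(
            1 for r in results if r.exclusive and "over_dispersed" in r.membership
        ),
        "non_exclusive": sum(1 for r in results if not r.exclusive),
        "between_random_overdispersed": sum(
            1 for r in results if r.position == "between_random_overdispersed"
        ),
        "above_overdispersed": sum(1 for r in results if r.position == "above_overdispersed"),
        "within_or_above_overdispersed": sum(
            1
            for r in results
            if "over_dispersed" in r.membership or r.position == "above_overdispersed"
        ),
        "above_random": sum(1 for r in results if _above_random(r)),
    }
    summary = dict(counts)
    for key in list(counts):
        if key == "n_classified":
            continue
        summary[f"pct_{key}"] = share(counts[key])
    return summary


def _above_random(r: ClassificationResult) -> bool:
    """Sample sits above the random band: over-dispersed membership without
    random membership, a gap position above random, or above everything."""
    if "random" in r.membership:
        return False
    return "over_dispersed" in r.membership or r.position in (
        "between_random_overdispersed",
        "above_overdispersed",
    )
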