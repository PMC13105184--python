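# Methods

## The model

Stomatal-complex centroids in a rectangular crop of the leaf epidermis are
treated as a planar point pattern of `N` points in a window of area `A`
(mm²). The analysis graph is the Delaunay triangulation — each stoma linked
to its natural neighbours, mean vertex degree ≈ 6 for homogeneous patterns
— and the statistic of record is the total length `L` of its Euclidean
minimum spanning tree (EMST), the loop-free subgraph connecting all points
with minimal total edge length. For a stationary random (Poisson) pattern,

    L = β · √(N · A)

with a dimensionless constant whose asymptotic value under complete spatial
randomness (CSR) is empirically placed in 0.63–0.64. Clustering shortens
the tree (β̂ = L/√(N·A) below the random range); spatial inhibition —
over-dispersion, as produced biologically by the one-cell-spacing rule and
the finite size of stomata — lengthens it.

**Finite-size behaviour.** The 0.63–0.64 range is a large-`N` limit.
`L/√(N·A)` converges to it from above, with a boundary-dominated excess
that decays roughly like `N^(-1/2)`: our own CSR simulations give a mean
β̂ ≈ 0.658 at `N = 1000` and ≈ 0.708 at `N = 100` in a unit window. For
this reason per-sample inference never compares β̂ to the asymptotic band
directly; every sample is judged against Monte-Carlo envelopes simulated
at its own `N` and window, which carry the same finite-size and edge
effects (no edge correction is applied on either side, so the bias
cancels in the comparison).

## Benchmark processes and envelopes

Each sample is compared to three processes with matched `N` and window:

* **clustered** — `N` points split as evenly as possible across 4 parent
  centres (remainder assigned at random), parents uniform on the window
  inset by one offspring standard deviation per side; offspring are
  parent + isotropic Gaussian displacement, rejection-resampled into the
  window (the crop is physical, not periodic, so no torus wrapping). The
  offspring SD defaults to `0.08·√A` — visibly aggregated across the
  density range of the study — and is configurable, since envelope widths
  depend on it.
* **random** — `N` i.i.d. uniform points (the binomial process, i.e. CSR
  conditioned on the observed count).
* **over-dispersed** — hard-core inhibition at distance `d_min` equal to
  the sample's mean stomatal diameter (metadata `diameter_um`/1000),
  realised by random sequential adsorption (dart throwing): uniform
  candidates accepted iff ≥ `d_min` from all accepted points. This is the
  simplest process satisfying a minimum inhibition distance and is exactly
  reproducible given a seed; a Gibbs/Strauss sampler would allow denser
  packings but adds an MCMC convergence question. Requests beyond the
  hexagonal disc-packing bound (`N·π(d_min/2)²/A > 0.9069`) are rejected
  up front; feasible-but-jammed requests (RSA saturates near packing
  fraction ≈ 0.55) exhaust an attempt budget (default `10,000·N`) and
  raise with the number of points placed.

Per scenario, the MST lengths of `reps` replicates (default 1,000; the run
manifest flags smaller runs) form the envelope; "95% interval" means the
2.5th–97.5th percentile band of replicate lengths, the standard
Monte-Carlo envelope reading. A sample is a *member* of every scenario
whose band contains its observed length — possibly several (overlapping
bands) or none. Its *position* label locates it against the ordered bands:
below all, within/overlapping, in one of the two gaps, or above the
over-dispersed band (the strongest over-dispersion signal the comparison
can give).

## Study-level estimates

* **Mean β** — arithmetic mean of per-sample β̂ with a Student-t 95% CI by
  default; a seeded percentile bootstrap (10,000 resamples) is available
  behind a flag, since either convention is defensible and the choice is
  recorded in the manifest. The regression-through-origin slope of `L` on
  `√(N·A)` is exported alongside as the fitted-line alternative.
* **R²** — computed against the theoretical prediction line
  `p_i = β_ref·√(N_i·A_i)` (the 1:1-line convention of an
  observed-vs-predicted plot), not a refitted regression; it can therefore
  go negative for a bad model, which is intended. `β_ref` is the study
  mean β̂.
* **Correlations** — Pearson r with Fisher-z 95% CIs, for stomata count vs
  MST length and stomata count vs stomatal diameter.
* Samples with `N < 2` have no defined β̂; they are flagged in the
  per-sample table and excluded from aggregation, never silently dropped.

## Input handling

Centroid tables are ImageJ-style delimited exports (comma or tab sniffed
from the header) with `X`/`Y` columns, extra columns ignored; coordinates
default to µm, with `unit_scale` (µm per unit) for pixel exports. The
internal canonical unit is mm. Real exports carry no window bounds, so by
default the tight bounding box is expanded by an equal margin on all four
sides until its area equals the metadata-declared observation area — the
smallest symmetric window of that area containing every point. If the
bounding box already exceeds the declared area the tight box is used and
the sample is flagged in the manifest, because the window choice sets `A`
and hence β̂. Exactly coincident centroid rows are an error by default
(they create zero-length MST edges and break inhibition logic); an opt-in
jitter of ±1% of the stomatal diameter resolves them, recorded in the
manifest.

## Degenerate geometry and determinism

The EMST is extracted from Delaunay edges (the EMST is always a Delaunay
subgraph); for `N < 3` or collinear/degenerate geometry the extraction
falls back to the complete graph rather than failing — real data include
extremely sparse samples. Total MST length is unaffected by equal-length
edge ties; edge identity under ties follows the extraction's deterministic
scan order, so repeated runs are byte-identical. All randomness flows from
one master seed through named substreams keyed by (sample id, scenario),
with per-replicate child streams, so per-sample results are independent of
sample order and stable under parallelisation.

## The synthetic study

The generator emulates the *shape* of a ~180-sample, two-site leaf survey
so the whole pipeline is testable without data: densities log-uniform over
3–777 per mm² (three orders of magnitude), one site shifted denser by 0.35
of the log-range, diameters `40 − 4·ln(density) + N(0, 2)` µm floored at
5 µm (a clearly negative density–diameter association; the coefficients
are fixture choices, not estimates), 1 mm² square windows, and a
10/30/60% clustered/random/over-dispersed truth mixture reflecting the
predominance of over-dispersed arrangements in real leaves. Ground truth
is stored beside — not inside — the samples. It does **not** emulate
species identities, phylogenetic structure, inhomogeneous intensity,
venation-scale constraints, or measurement noise in centroid digitisation;
passing recovery tests on it demonstrates the machinery is correct and
calibrated, not that real leaves behave this way.

## Problem sizes used in the checked runs

The bundled analysis runs the 180-sample study at 200 envelope replicates;
the test suite exercises the CSR reference at 1,000 replicates of
`N = 1000`, envelope ordering at `N = 200` with 200 replicates × 20
repeats, and scenario recovery at `N = 200` with 500 replicates × 100
trials per scenario (checking the observed length against its own
scenario's band, which is the membership predicate for that scenario).
Recovery uses a hard-core distance of 0.04 mm: an inhibition distance of
twice the CSR mean nearest-neighbour spacing at `N = 200` (≈ 0.071 mm,
packing fraction ≈ 0.78) is not realisable by random sequential
adsorption, which jams near 0.55.

## Known limitations

* β is a scalar per sample; no spatially explicit or inhomogeneous
  variant, and no mixed-effects structure over sites/species.
* Only one clustered and one inhibited configuration are simulated per
  sample; the classification is relative to those specific benchmarks.
* RSA cannot represent packings between its jamming density and the
  hexagonal bound; such over-dispersed benchmarks would need a Gibbs
  sampler.
* No edge-effect correction: absolute β̂ values carry boundary bias (they
  cancel only in the envelope comparison and only because simulations use
  the sample's own window).
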