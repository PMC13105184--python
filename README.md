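# stomanet

Network-based analysis of stomatal spatial patterns on the leaf epidermis.

Stomata — the pores regulating gas exchange — are laid out on a leaf
surface under developmental constraints (the one-cell-spacing rule, their
own finite size) that push their arrangement away from randomness. This
package asks, for each microscopy sample of stomatal-complex centroids:
*is this arrangement clustered, random, or over-dispersed, and does it
follow the scaling law a spatial network predicts?* It is written for
plant anatomists and spatial ecologists working with ImageJ centroid
exports, one delimited table of `X,Y` coordinates per sample plus a
metadata table (species, site, observation area in mm², mean stomatal
diameter in µm).

## The statistic

Each sample's centroids form a point pattern of `N` points in a window of
area `A`. The package builds the Delaunay neighbour network, extracts its
Euclidean minimum spanning tree (EMST), and measures the total tree length
`L`. Under complete spatial randomness,

    L = β · √(N · A),   β ≈ 0.63–0.64 (asymptotically)

so the normalised statistic `β̂ = L/√(N·A)` indexes spatial structure:
smaller for clustered patterns, larger for over-dispersed (regularly
spaced) ones. Because `β̂` at realistic `N` carries finite-size and
boundary effects, each sample is classified not against the asymptotic
band but against Monte-Carlo envelopes of `L` simulated at the sample's
own `N` and window under three benchmark processes: a four-cluster
aggregated process, CSR, and hard-core inhibition at the sample's mean
stomatal diameter. A sample is a *member* of every scenario whose 2.5–97.5
percentile band contains its observed `L`; samples above the
over-dispersed band are more regular than the hard-core benchmark itself.
Study-level outputs are the mean `β̂` with a 95% CI, observed-vs-predicted
fit statistics (R² against the 1:1 line, Pearson r with Fisher-z CIs), and
the classification share table. See `docs/methods.md` for assumptions,
parameter defaults, and limitations.

## Worked example

No real centroid data ship with the package; `stomanet synth` (or
`analysis/01_simulate_study.py`) generates a full synthetic two-site study
with known ground truth — 180 samples, densities log-uniform over 3–777
stomata/mm², diameters negatively tied to density, a 10/30/60%
clustered/random/over-dispersed truth mixture:

```
$ python analysis/01_simulate_study.py
wrote 180 samples under .../scratch/synthetic_study
  density range: 3.0 to 777.0 per mm^2
  sites: {'Antumapu': 90, 'Frutillar': 90}
  truth mix: {'over_dispersed': 108, 'random': 54, 'clustered': 18}
  diameter range: 9.9 to 40.6 um

$ python analysis/02_run_pipeline.py
analyzed 180 samples (0 failed) -> .../results/study
  mean beta_hat = 0.6248 (95% t-CI [0.6038, 0.6458]); origin-slope beta = 0.6752
  observed vs predicted: R^2 = 0.953; Pearson r(N, L) = 0.966 [0.955, 0.975]
  Pearson r(N, diameter) = -0.818 [-0.862, -0.764]
  classification shares: clustered 7.2%, random 11.1%, over-dispersed 21.7%, non-exclusive 60.0%
  above over-dispersed band: 2.2%; within-or-above over-dispersed: 78.9%
```

Reading this: the scaling law explains 95% of the variance in MST length
across three orders of magnitude of density (R² is measured against the
prediction line itself, not a refit); the mean `β̂` of 0.62 sits below the
clean-CSR value because 10% of the synthetic samples are strongly
clustered, which drags the mean down; and 79% of samples fall within or
above the over-dispersed band, recovering the truth mixture in which
over-dispersion dominates. `analysis/03_evaluate_recovery.py` joins the
classifications with the ground truth — membership recovery is 94%, 91%,
and 94% for clustered, random, and over-dispersed truths — and
`analysis/04_figures.py` draws the observed-vs-predicted scatter and the
per-sample envelope bars.

The same pipeline runs on real data from a shell:

```
stomanet analyze --centroids DIR --metadata metadata.csv \
    --reps 1000 --seed 1 --out results/run1
```

writing `per_sample.csv` (MST length in µm and mm, `β̂`, the three
envelope bands, membership flags, position label), `study_summary.csv`,
and a JSON run manifest (seed, replicate count, config echo, warnings).
`stomanet simulate` prints a single scenario envelope; `stomanet synth`
writes a synthetic study.

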