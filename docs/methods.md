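# Methods

This document records the model assumptions, parameter choices, numerical
decisions and known limitations of `velozones`. The README gives the
high-level picture; this is the reference for anyone auditing the
implementation.

## 1. Synthetic locomotion generator

`LocomotionModel` is a semi-Markov process over a small set of velocity
regimes ("states"), sampled at `sample_hz` (default 10 Hz):

- **Dwells.** Time in a state is geometric at the sample level with leave
  probability `p = 1 / (dwell_mean_s · hz)`, capped at 1, so the expected
  dwell is `dwell_mean_s` seconds.
- **Jump chain.** On leaving, the next state is drawn from the row of
  `transition_weights` (non-negative, zero diagonal, positive row sums),
  normalised to probabilities. The initial state is drawn from the
  stationary distribution of the embedded jump chain
  (`expected_state_occupancy` solves for it with a least-squares linear
  solve and weights it by the dwell means).
- **Velocity dynamics.** Velocity starts at 0 and each step moves toward a
  per-step target `state_mean + N(0, state_sd)`, with the step clipped to
  `±a_max / hz` (default a_max = 6 m/s²) and the result clamped to
  `[0, v_cap]` (default v_cap = 10 m/s).
- **Artefacts.** With probability `spike_rate` a sample is replaced by a
  uniform draw on `(v_cap, v_cap + 3]`, emulating GPS velocity spikes.

Scope: the generator produces occupancy structure (distinct velocity modes
with noise, acceleration-limited transitions between them, and out-of-range
spikes), which is what the clustering pipeline consumes. It does **not**
attempt to emulate positional error, satellite-geometry effects,
autocorrelated dropout, fatigue drift within a match, or sport-specific
tactical sequencing. Conclusions drawn from synthetic cohorts are about the
pipeline's ability to recover a known regime structure, not about rugby.

Default cohort parameterisations (in `defaults.yaml`) use four states with
means (1.2, 3.2, 5.8, 7.8) m/s for the male cohort and (1.0, 3.0, 5.0, 7.0)
for the female cohort, SD 0.3 m/s, mean dwell 4 s, symmetric transitions,
and 17 minutes of effective play per simulated match.

## 2. Cleaning

- Samples with velocity **strictly above** 10 m/s are removed (10.0 is
  kept — it is the upper edge of the top bin).
- A file in which removed samples exceed **3 %** of the original count is
  excluded from the cohort.
- No interpolation: removal leaves gaps in the time grid, and the traversal
  counting below never bridges a gap.
- Cleaning is idempotent: re-cleaning a cleaned trace removes nothing.

Timestamps must lie on the `1/hz` lattice (tolerance 1e-9 s); gaps are
allowed, irregular sampling is not.

## 3. Traversal graph and affinity

Velocity is discretised into **100 bins of 0.1 m/s** on [0, 10]; the last
bin is closed (`[9.9, 10.0]`). For each pair of *temporally adjacent*
retained samples, one traversal count is added from the first sample's bin
to the second's (self-transitions included; pairs spanning a cleaning gap
excluded). Per-match matrices are summed to pool a cohort.

The affinity is

```
S = (T + Tᵀ) / 2            # symmetrise counts
A = S / max(S) + β · C      # max-normalise, add chain adjacency
```

with β = 0.1 and `C` the path-graph adjacency of the 100 bins. The chain
term guarantees a connected graph (so the normalised Laplacian has a single
zero eigenvalue) and encodes that neighbouring velocity bins are a priori
similar; β is small enough that data-driven structure dominates wherever
counts exist.

## 4. Spectral clustering

Normalised spectral clustering on `A`:

1. `L = I − D^(−1/2) A D^(−1/2)` with `D = diag(row sums of A)`.
2. The k eigenvectors of the smallest eigenvalues (via
   `scipy.linalg.eigh(subset_by_index=...)` — the matrix is a dense
   symmetric 100×100, so a direct solver is the right tool).
3. Rows of the eigenvector matrix are normalised to unit length
   (Ng–Jordan–Weiss) and clustered with seeded `sklearn` KMeans
   (`n_init=10`).

**Degree-weighted k-means.** The k-means step uses
`sample_weight = degree(A)`. With row-normalised spectral embeddings,
weighting points by degree makes the k-means objective the
weighted-kernel-k-means form of the normalised cut, so bins that are barely
visited (e.g. empty tail bins connected only through the β chain) cannot
claim a centroid of their own. Unweighted k-means demonstrably does exactly
that on realistic traces — it dedicates a cluster to the empty top bins and
merges two genuine regimes.

**Contiguity.** Velocity regimes must be intervals of bins. Labels are
repaired in two passes: an occupancy-weighted mode filter (window 3), then
any label occupying more than one run keeps its heaviest run while the
remaining fragments are absorbed, lightest first, into whichever neighbour
shares the larger boundary affinity. If repair collapses the solution below
k clusters, a `ClusteringError` is raised rather than silently returning
fewer zones. Clusters are relabelled in order of occupancy-weighted mean
velocity.

**WCSS.** Model selection uses the within-cluster sum of squares of
**bin-centre velocities**, weighted by bin occupancy (traversal row sums
including the diagonal) — i.e. dispersion in physical velocity space, not in
the embedding. This makes WCSS comparable across k and across matches.

Because k-means optimises the embedding while WCSS is measured in velocity
space, WCSS is not guaranteed monotone in k; in practice inversions are
rare and tiny. The code warns when the curve is non-monotone, and tests
tolerate rises up to 1 % of WCSS(2).

## 5. Elbow selection

For k = 2…10 on the pooled cohort affinity, the selected k maximises the
**second difference of log WCSS** over interior k, with ties broken toward
smaller k. Using log WCSS measures *relative* flattening: the raw second
difference is scale-dependent and, for any steeply decaying curve, is
dominated by the first drop regardless of where the curve actually bends.
Endpoints of the scanned range are never selected.

## 6. Boundaries and cohort thresholds

For a contiguous solution, each boundary is the **lower edge of the first
bin of the upper cluster** (`grid.lower_edges[first index of the new
label]`). Stage 2 re-clusters every match at the cohort k, extracts its
k − 1 boundaries, and averages them by rank across matches; reported values
are rounded to 0.01 m/s and the rank-wise standard error of the mean is
attached. Matches whose repaired solution is not contiguous at k are
errors, not silently dropped.

## 7. Zone metrics

`ZoneScheme` zones are **half-open** `[bᵢ, bᵢ₊₁)` with the first zone
starting at 0 and the last unbounded above (assignment via
`searchsorted(..., side="right")`). Per sample, distance is `v / hz`;
per-match distance-per-zone therefore sums exactly to total distance, which
the tests assert to 1e-6 m. Relative distance is total distance divided by
`n / (hz · 60)` minutes of retained samples.

## 8. Statistics

Two-group comparisons are gated: Shapiro–Wilk on each group at α = 0.05;
both normal → Welch's t (unequal variances, two-sided); otherwise
Mann–Whitney U, exact when the combined sample is ≤ 20 and tie-free,
asymptotic (tie-corrected) otherwise. Constant samples make normality
undefined and fall through to Mann–Whitney. A `test=` argument overrides
the gate when a specific test is required. `welch_from_summary` reproduces
Welch p-values from published mean/SD/n rows via
`scipy.stats.ttest_ind_from_stats`. Per-metric reporting without multiplicity
correction is the default, matching field convention; `compare_table`
optionally adds Holm-adjusted p-values.

## 9. Seeding and determinism

All randomness flows from `numpy.random.SeedSequence`: cohort simulation
spawns one child per trace, and multi-cohort scripts spawn one child per
cohort, converting each to an integer seed with
`generate_state(1)[0] % 2**31`. The k-means seed defaults to a fixed
package constant; every public entry point takes an explicit `seed`.
Identical seeds give bit-identical labels, boundaries and WCSS.

## 10. Problem sizes and tolerances

- Validation cohorts: 10 replicate cohorts × 20 traces × 20 min at 10 Hz
  (240 000 samples per cohort); the full pipeline on one cohort runs in a
  few seconds on one CPU.
- Spectral oracle: exhaustive minimum normalised 2-way cut over all 99
  contiguous splits, matched exactly on 20 randomised two-block graphs.
- Boundary recovery: cohort-mean boundaries within 0.3 m/s of the
  generative occupancy-density minima; across-seed spread below 0.1 m/s.
- WCSS monotonicity slack: 1 % of WCSS(2) (see §4).
- Zone conservation: 1e-6 m absolute.
- Statistical calibration: empirical type-I error of the gated procedure on
  2000 normal nulls within [0.03, 0.07] at nominal 0.05.

## 11. Limitations

- The 10 m/s cap and the 0.1 m/s bin width are fixed by the default grid;
  other sports or sampling rates may need a different `BinGrid`.
- Boundary resolution is limited to the bin width (0.1 m/s) per match;
  sub-bin precision comes only from averaging across matches.
- The elbow rule assumes the WCSS curve has a single dominant bend; cohorts
  with genuinely ambiguous regime counts will give unstable k across seeds,
  which the replicate machinery makes visible but does not resolve.
- Per-metric, uncorrected p-values are reported by default; with many zones
  the family-wise error rate exceeds 0.05 unless `holm=True` is used.
- The simulator validates the pipeline, not the sport: agreement on
  synthetic cohorts does not by itself establish the physiological meaning
  of derived thresholds on real GPS data.
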