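# Methods

This note documents the models, numerical conventions and design choices
behind `bryoclim`, and what the synthetic test-bed does and does not show
about real data.

## Grid and coordinate conventions

All layers live on one regular lon/lat grid addressed as `(row, col)`
with row 0 at the northern edge; the default cell size of 0.0083° is the
~1-km² convention of global bioclim products. Cells are half-open
intervals `[west, west + cell) × (north − cell, north]`; a point on a
shared edge therefore belongs to exactly one cell, and the mapping is
fixed in `geo.lonlat_to_cell` so no other module re-derives geography.
Missing data in any layer invalidates the cell for modelling, projection
and every count. Rasters are ESRI ASCII grids (text, one band per file);
no reprojection is supported — inputs must already share one grid.

## Synthetic landscapes

The generator is a pure function of a spec plus a seed.

* **Elevation/islands** — the maximum over Gaussian bumps (peak heights
  drawn uniformly from 500–1500 m, plausible volcanic-island summits) at
  random centres kept ≥ 5.6 bump-widths apart so the patches thresholded
  at `sea_level` (default 50 m) are exactly `n_islands` connected
  components; a mismatch is a hard error, not a silent degradation.
  Centre placement restarts when sequential rejection deadlocks and
  falls back to a seeded jittered lattice, so generation succeeds for
  any feasible spec and seed. Archipelago labels come from
  single-linkage clustering of island centroids, renumbered west to
  east. An optional eastern strip with an inland elevation ramp plays
  the role of a continental margin.
* **Climate** — each variable is `base + lapse × elevation + noise`,
  the noise being white Gaussian smoothed with an isotropic kernel whose
  scale is the autocorrelation range (in cells) and rescaled to the
  requested marginal SD. The five default variables are the retained
  bioclim predictors with a −6.5 °C/km thermal lapse and orographic
  precipitation increases; their independent noise components (1.2 °C
  for the temperatures, 2.5–12 mm for the precipitation variables) stand
  in for aspect, rain-shadow and cloud-incidence heterogeneity and are
  deliberately large enough that the set is not mutually redundant —
  this is the *retained* predictor set, so it should normally survive
  its own collinearity screen, as it does on most seeds.
* **Virtual species** — true suitability is a product of Gaussian
  responses (breadth = SD), rescaled so its maximum over land is 1.
  The three default species are narrow cloud-belt specialists (thermal
  breadths ≈ 1.1–1.2 °C, humid preferences) because the motivating
  endemics are laurel-forest specialists; climatic generalists would be
  weakly identifiable from presence-only data at realistic sample
  sizes, and their frequent elimination by the AUC/TSS filter would
  leave little pipeline to test.
* **Occurrences** — presence-only draws without replacement,
  probability proportional to true suitability; no detection model.
  Default 60 records per species (tens of records, as for real endemic
  bryophyte databases). Optional per-archipelago effort multipliers
  exist but default to uniform, since nothing is known about how real
  effort varied.
* **Scenarios** — cellwise `new = old × factor + offset`, optionally
  with per-archipelago extra offsets. The default deltas follow the
  published archipelago-mean magnitudes: +2.0 / +3.2 °C on the
  warmest-month maximum and ×0.83 / ×0.78 on wettest-month
  precipitation for the mitigated and high-emission 2070 pathways.
* **Protected areas** — random squares (2–6 cells on a side) centred on
  island cells, added until the polygon union covers the requested
  fraction of island land (measured exactly by polygon intersection);
  a requested fraction ≥ 0.95 saturates to one rectangle per island.
  Real reserve geometry (elevation bias, nestedness) is not imitated,
  so the *trend* of protected-area coverage under warming is not a
  prediction of the generator — only the coverage arithmetic is.

What the generator does **not** emulate: real topography or coastline
shape, the covariance structure of real bioclim layers, spatial sampling
bias beyond grid thinning, dispersal, and biotic interactions. Passing
tests therefore demonstrate that the *pipeline* recovers known truths
under its own assumptions, not that those assumptions hold in any real
archipelago.

## Input preparation

* Thinning snaps records to cells and keeps one per cell — the natural
  reading of a minimum-separation rule equal to the grid resolution; it
  is idempotent by construction. Records on invalid cells are dropped
  with a logged count.
* The minimum-records rule defaults to ≥ 11 thinned cells ("more than
  ten" read strictly); it is configurable because published guidance on
  minimum SDM sample sizes spans ~3–13. Thinned cells are counted (not
  raw records); the order of thinning vs counting is not documented for
  the motivating study, so the stricter option was fixed and logged.
* Collinearity screening estimates Pearson correlations on 10,000
  random valid cells (with replacement when fewer exist) and greedily
  keeps variables in priority order, dropping any candidate whose |r|
  with an already-kept variable exceeds 0.8. The screening sample
  correlation matrix is returned with the result so the decision is
  auditable.
* Pseudo-absences: 1,000 distinct background cells per species by
  default (a conventional presence–background calibration size; the
  motivating study does not state its count), drawn once per species
  and shared by all three techniques.

## Models

* **Envelope** — per-variable mid-rank empirical CDF of the presences;
  score `1 − 2|F(v) − 0.5|`, 0 outside the presence min–max, minimum
  over variables. A variable constant across presences degenerates to a
  spike (1 at the constant, 0 elsewhere) and is logged.
* **Penalized presence–background model** — logistic discrimination of
  presences vs background on standardized linear + quadratic features
  with an L1 penalty (`regularization` scales the penalty; default 1).
  The objective is convex and the solver deterministic; sparsity makes
  the regularization path monotone in the number of active features.
  Hinge/threshold/product features are out of scope. Coefficients are
  exposed on the original variable scale for interpretability.
* **Random forest** — scikit-learn forest (default 100 trees), seeded,
  class-probability output.
* All three weight records to neutral prevalence: unit presence weight,
  absence weight `n_presence/n_absence`, so total class weights are
  exactly equal.

## Evaluation and consensus

Ten stratified 70/30 splits (seeded; the split RNG derives from the run
seed, species and technique); AUC is the Mann–Whitney rank statistic,
TSS the maximum over observed thresholds of sensitivity + specificity
− 1 with "predicted present" meaning score ≥ threshold. The pass rule —
mean AUC ≥ 0.8 **and** mean TSS ≥ 0.7 — applies to the means across
splits (per-split application was the plausible alternative; the mean
was chosen and is logged). Consensus weights are raw mean AUCs
normalized to sum 1 (not AUC − 0.5 rescaling, which some ensemble
platforms use; configurable by post-processing the evaluation results).
Each surviving technique enters the consensus once, refitted on the full
calibration data; the ten splits serve evaluation only.

## Projection, MESS, binarization

MESS follows the standard percentile construction: per variable, with
`f` the percentage of reference values strictly below the cell value,
the similarity is `2f` (f ≤ 50), `2(100 − f)` (50 < f < 100), and the
linear extrapolation forms `100(v − min)/(max − min)` / `100(max − v)/
(max − min)` at f = 0 / f = 100; the surface is the minimum over
variables. A degenerate reference (max = min) scores 100 at the value
and a −10⁶ sentinel elsewhere (logged). The default reference set is the
species' calibration presence cells.

The binarization threshold is the lower empirical 5% quantile of
calibration-presence suitability — the largest observed score with at
most 5% of presences strictly below it — so achieved omission is ≤ 5% +
1/n. The motivating description calls this a "commission error
adjustment"; with presence-only calibration no direct commission
quantity exists, so the standard sensitivity-based reading was
implemented and the error rate left configurable. Future projections
reuse the present-day threshold (one consensus index, one threshold); a
cell is in the binary range iff it is valid, suitability ≥ threshold,
and MESS > 0.

## Change statistics

* `pct_remaining = 100 · n_future / n_present`, displayed half-up to one
  decimal; undefined (reported not-applicable) when nothing is suitable
  at present; values > 100 mean expansion.
* Threat classes: 0 → extinct; (0,1) → near-extinct; [1,5) → below 5%;
  [5,50] → endangered (≥ 50% reduction); (50,70] → vulnerable (≥ 30%
  reduction); (70,100] → below the Vulnerable cutoff; > 100 →
  expanding. Boundary values go to the more severe class (the class
  definitions state thresholds but not boundary handling).
* Elevation shift: per-island mean elevation of suitable cells in each
  period; islands with no suitable cell in either period are dropped
  from the pairing (disappearance removes the pair and with it power —
  with fewer than two usable pairs the test is reported as not
  computable). Two-sided paired t across islands; an all-zero
  difference vector returns t = 0, p = 1 rather than 0/0.
* Archipelago comparison: tie-corrected Kruskal–Wallis H with a
  chi-square p-value, then Nemenyi-style pairwise comparisons using the
  chi-square rank-sum approximation
  `(R̄ᵢ − R̄ⱼ)² / (C·N(N+1)/12·(1/nᵢ + 1/nⱼ))` against χ²(k−1), with C
  the tie-correction factor — the approximation recommended for
  Kruskal-type data with ties.
* Protected-area coverage: a pixel is protected iff the reserve union
  covers ≥ 5% of its area (computed exactly with polygon intersection,
  restricted to suitable cells for efficiency); coverage is
  100 × protected-and-suitable / suitable, not-applicable for an empty
  range. Percentages for the synthetic pipeline are computed after MESS
  masking.

## Orchestration and reproducibility

A YAML `RunConfig` drives simulate → prepare → fit → project → report;
every per-species seed derives from the master seed plus stage and
species name via SHA-256 (kept below 2³¹), so a rerun of the same config
reproduces all artifacts bit-identically (verified by the test suite).
Stage subcommands recompute earlier stages deterministically rather than
deserializing fitted forests; envelope and penalized-model parameters
are serialized to JSON, the forest by its configuration and seed. Exit
codes: 0 success, 2 validation error, 3 stage failure. The bundled demo
configuration uses a 200×200 grid, six islands in three archipelagos, a
30-column continental strip, three virtual species, 60 presences and
1,000 pseudo-absences per species — sizes at which the full run takes
well under a minute on one CPU while leaving every stage non-trivial.

## Known limitations

* The penalized presence–background model is a discriminative stand-in
  for the maximum-entropy family: it shares the convex smooth-response
  contract but not the exact feature set or normalization of the
  reference implementation.
* Random splits only; no spatial cross-validation (the evaluated
  protocol is random splitting).
* No clamping or extrapolation control beyond MESS masking; no
  fractional-pixel area weighting.
* The bundled published range-size table enables the worked-example
  arithmetic and headline counts; the map-level published statistics
  (e.g. archipelago-specific mean losses) require the original rasters
  and occurrence databases and are represented here only by the
  synthetic pipeline's analogous outputs.
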