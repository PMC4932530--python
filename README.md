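# bryoclim

Ensemble species-distribution modelling of climate-driven range loss for
island endemic floras — the full pipeline from occurrence thinning and
predictor screening, through three-technique ensemble fitting with
AUC/TSS quality control, to analog-climate-masked binary range
projections and the downstream conservation statistics (percent suitable
area remaining, IUCN-style threat classes, elevational shifts,
archipelago comparisons, protected-area coverage).

The package is aimed at macroecologists and conservation modellers who
want a tested, reproducible implementation of this workflow. Because the
motivating study system — narrow endemic bryophytes of subtropical
Atlantic archipelagos — has no deposited rasters or occurrence data, the
package ships a first-class synthetic-landscape generator: seeded island
landscapes with lapse-rate climate gradients and autocorrelated noise,
virtual species with bell-shaped niches, presence-only samples, scenario
deltas with realistic 2070 magnitudes, and random protected-area
polygons. Every stage of the pipeline is exercised and tested against
these virtual truths.

## The method

For each species with more than ten grid-thinned records (one record per
0.0083° ≈ 1 km² cell):

1. **Predictor screening** — of each predictor pair with |Pearson r| > 0.8
   on a 10,000-point background sample, the lower-priority variable is
   dropped. The canonical retained set is BIO5, BIO6, BIO13, BIO14, BIO18
   (max temperature of the warmest month, min temperature of the coldest
   month, precipitation of the wettest/driest month and warmest quarter).
2. **Three techniques**, calibrated on presences and pseudo-absences
   weighted to neutral (0.5) prevalence:
   a climatic envelope (per-variable percentile score
   s(v) = 1 − 2·|F(v) − 0.5| with F the presence empirical CDF, minimum
   over variables); a penalized presence–background discriminative model
   on linear + quadratic features (L1, convex, deterministic); and a
   seeded random forest.
3. **Evaluation** by ten random 70/30 splits, scoring AUC (rank
   statistic) and TSS (max over thresholds of sensitivity + specificity
   − 1). Techniques with mean AUC < 0.8 or mean TSS < 0.7 are eliminated.
4. **Consensus** — surviving techniques are combined with weights
   proportional to mean AUC; the consensus suitability is their weighted
   mean.
5. **Projection and binarization** — the consensus is projected onto
   present and scenario climates; a multivariate environmental similarity
   surface (MESS) flags non-analog cells (negative where any variable
   leaves the reference range); the continuous index is thresholded at
   the 5%-omission quantile of calibration-presence scores, and
   non-analog cells are masked out.
6. **Change statistics** — suitable-pixel counts and percent remaining
   per region and scenario; threat classes (≥ 30% loss → Vulnerable,
   ≥ 50% → Endangered, with < 5%, < 1% and total-loss classes);
   per-island mean suitable elevation with a paired t-test;
   Kruskal–Wallis + Nemenyi comparison of per-species losses among
   archipelagos; and protected-area coverage, counting a pixel as
   protected when reserves cover ≥ 5% of its area.

## Worked example

The repository is organised as an analysis: numbered drivers under
`analysis/` run the bundled demo configuration (`configs/demo.yaml`: a
200×200 landscape, six islands in three archipelagos plus a continental
strip, three virtual cloud-belt endemics, two scenarios) and write their
tables under `results/`. The same can be run from the CLI:

```
bryoclim run --config configs/demo.yaml --out scratch/run
```

`python analysis/03_fit_ensembles.py` prints, for example:

```
virtula montana
  envelope      mean AUC 0.904  mean TSS 0.794  pass
  maxent_like   mean AUC 0.946  mean TSS 0.891  pass
  random_forest mean AUC 0.941  mean TSS 0.873  pass
  consensus weights: envelope=0.324, maxent_like=0.339, random_forest=0.337
...
excluded virtula sylvatica: no technique passed the quality filter (...)
```

— two of the three virtual species pass quality control here; the third
is excluded exactly as weakly-modelled species are dropped in practice.
`python analysis/05_range_change_stats.py` then reports, per species and
scenario, the suitable-cell counts and the headline statistics:

```
         species  region scenario  n_present  n_future  pct_remaining     status  ...
 virtula montana islands    rcp45        160       102           63.8 vulnerable
 virtula montana islands    rcp85        160        28           17.5 endangered
virtula nebulosa islands    rcp45        131        86           65.6 vulnerable
virtula nebulosa islands    rcp85        131        51           38.9 endangered

mean percent of island suitable area remaining per scenario:
          mean   std
rcp45     64.7   1.3
rcp85     28.2  15.1
```

Under the mitigated scenario the virtual endemics keep roughly two
thirds of their suitable area (Vulnerable); under the high-emission
scenario they keep a fifth to a third (Endangered), their mean suitable
elevation rises by several hundred metres, and the elevation increase is
significant by the paired t-test wherever enough islands retain suitable
area in both periods.

`python analysis/06_reference_table_arithmetic.py` recomputes, from the
bundled published range-size table for 35 real Macaronesian endemic
bryophytes, the percent-remaining columns and the headline counts (six
species with no suitable island pixel left under the high-emission
pathway, five more below 5% remaining, 32 of 35 with continental
suitability at present, six of those losing it entirely under the
mitigated pathway).

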