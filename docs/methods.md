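# Methods

## Efficiency estimation

**Standard curve.** For a serial dilution with known relative concentrations
`c_k`, ordinary least squares of Cq on log10 `c_k` gives slope `M` and
`E = 10^(-1/M)`. Only the log10 spacing of the concentrations matters, so
concentrations are arbitrary units. At least three distinct levels are
required; a non-negative slope is an error (efficiency undefined).

**Log-linear reconstruction.** Each reaction's curve is first baseline
corrected by subtracting the mean fluorescence of its first `n_baseline_cycles`
(default 5) cycles; the baseline SD is kept as the reaction's noise scale.
More elaborate iterative baseline refinement exists in dedicated tools; the
simple estimator is used here with the cycle count configurable. Within a
common fluorescence band per amplicon group — the *window of linearity* — the
regression of log10 fluorescence on cycle gives `E = 10^slope` per reaction.

**Window search.** Candidate bounds are 50 log-spaced fluorescence values
spanning the group's usable range; all bound pairs are scored. A band is
feasible for a reaction when it contains at least `min_points` (default 4)
positive fluorescence readings, sits above the reaction's noise floor (3 x
baseline SD) and below its plateau (90% of its maximum). The selected band
maximises the mean in-band regression r² taken over *all* reactions of the
group, infeasible reactions contributing zero — so the search prefers bands
usable by as many reactions as possible over marginally straighter, narrower
ones (with a feasible-only denominator the optimum often spanned fewer than
five cycles and silently excluded ~10% of reactions). Ties break toward more
contributing reactions, then wider bands. If no band is feasible for at least
80% of the group, the search fails loudly, listing the offending reactions.
The implementation is vectorised over bands; tests check it against a naive
brute-force enumeration.

**Cq determination.** The pipeline determines the reconstructed Cq (threshold
0.4260; the instrument-style threshold is 0.4996) by log-linear interpolation
of the observed curve between the two cycles bracketing the first threshold
crossing. `compute_cq` also offers a regression mode — the crossing of the
fitted in-window exponential, `Cq = (log10 thr − intercept)/slope` — but it is
*not* the pipeline default for a structural reason: combining a
regression-derived Cq with the same regression's efficiency collapses
algebraically, `E^Cq = thr / 10^intercept`, so the slope (and with it all
per-reaction efficiency variation) cancels from replicate-level estimates.
That would make the replicate-level approach trivially the least noisy of the
seven, which is neither how reaction-by-reaction tools behave (they read the
Cq off the observed curve) nor what is observed on real data.

**Aggregation.** Replicate-level efficiencies average arithmetically to
sample level (triplicates within a plate), plate level (analytical samples
and positive controls only — never standards or the water blank) and batch
level (all such reactions across plates of one amplicon, weighting reactions,
not plates). Reactions flagged `no_amplification` (too few in-window points)
or `invalid_slope` are excluded from every average but reported in QC output.

## The seven T/S approaches

Replicate estimates are `E^Cq` evaluated in log space; T and S replicates are
aggregated independently (raw-scale arithmetic means, never log means) before
the ratio `T/S = s_estimate / t_estimate`. The approaches differ only in the
Cq source and the efficiency level:

| name | Cq | efficiency |
|---|---|---|
| RotorGeneCurve | instrument | per-plate standard curve (instrument Cq) |
| RotorGeneBatch | instrument | mean of those standard-curve E's per amplicon |
| LinRegRep | reconstructed | the reaction's own log-linear E |
| LinRegSamp | reconstructed | triplicate mean within plate |
| LinRegPlate | reconstructed | plate mean (samples + controls) |
| LinRegBatch | reconstructed | amplicon mean across plates |
| LinRegCurve | reconstructed | per-plate standard curve refit on reconstructed Cqs |

Replicate QC drops a replicate whose Cq deviates from the triplicate median by
more than `max_dcq` (default 0.5 cycles, configurable — the rule is a
reasonable default, not a published constant); a sample fails when fewer than
two replicates survive on either side. Positive controls enter plate/batch
efficiency averages but never receive T/S ratios; no inter-plate
normalisation by positive controls is applied.

## Precision and validity statistics

Replicate CVs are computed on natural-log transformed estimates (SD/mean),
which approximates normality better than the raw scale. Equality of CVs
across groups uses the Feltz–Miller asymptotic statistic
`D = Σ m_i (c_i − c̄)² / (c̄² (0.5 + c̄²))`, `m_i = n_i − 1`, chi-square with
k−1 df; its type-I error calibration is asserted by Monte Carlo. Scale
comparisons between approaches use two-sided paired t-tests with Bonferroni
control (sidedness is a convention; two-sided throughout).

Partial correlations residualise both variables on an intercept plus numeric
covariates (binary covariates coded 0/1, age in years as-is; correlations are
invariant to standardisation), then take the Pearson correlation of
residuals; constant covariate columns in homogeneous subsets (e.g. all-female
adults) are dropped rather than allowed to make the design singular. Fisher-z
intervals use `tanh(atanh(r) ± z/\sqrt{n−3})` with n replaced by n−k under k
covariates. Two estimates are declared different when their 83.4% intervals
are disjoint — intervals touching at exactly one point count as overlapping —
which approximates a 5% two-sample test (calibration asserted by simulation).

`required_n` reproduces the `pwr.r.test` computation: critical r from the
two-sided t quantile at df = n−2 via `r_c = sqrt(t²/(t²+n−2))`, power from the
Fisher approximation `Φ((atanh(r) + r/(2(n−1)) − atanh(r_c))·sqrt(n−3))`,
solved by bisection on n ∈ (3+1e−6, 1e7). The lower bracket sits just below 4
because for very large effects (r ≈ 0.99) the 80%-power root lies below n = 4
and a bracket starting at 4 would not straddle it.

## Attenuation simulation

`(TL, age, tissue)` are drawn from a zero-mean multivariate normal with
population correlations (0.15 TL–age, 0.70 TL–tissue, 0 age–tissue; the
implied 4x4 matrix including the noisy copy is PSD-checked at construction).
"Tissue" is simulated as a continuous correlate — a correlation of 0.70 with
a binary variable is barely attainable, and only the correlation structure
matters. The noisy copy is `noisyTL = ρ·TL + sqrt(1−ρ²)·ε` with ρ = 0.87, an
attenuation construction whose *population* correlation with TL is exactly ρ
(the alternative of fixing the *sample* correlation was checked and changes
none of the summary statistics materially; population semantics are simpler
and are the documented choice). Each replication computes

    f(x) = (r(TL,tissue) − r(noisyTL,tissue)) − (r(TL,age) − r(noisyTL,age)),

the difference between the correlation *recoveries* of the strong and the
weak correlate when noise is removed. Its expectation is approximately
`(1−ρ)(0.70 − 0.15) ≈ 0.07`, positive because attenuation is proportional:
the strong correlate loses (and regains) more correlation in absolute terms.
A ratio-based variant of this statistic, `r(TL,tissue)/r(noisyTL,tissue) −
r(TL,age)/r(noisyTL,age)`, was evaluated and rejected: both ratios have the
same expectation, the age ratio's sampling distribution is heavy-tailed (its
denominator is a noisy correlation near 0.13), and the resulting statistic is
positive in only ~52% of replications with an SD above 1 — incompatible with
the concentrated, overwhelmingly positive behaviour this analysis is designed
to exhibit. Per-replication seeds derive from the master seed and the
replication counter (`default_rng([seed, rep])`), so results are
bit-reproducible and independent of execution order.

## Synthetic data generator

**Curve model.** `F(c) = b0 + b1·c + f_max·u/(u + f_max)` with
`u = f_scale·x0·E^c`, times multiplicative log-normal noise. The saturating
fraction tends to `u` when `u ≪ f_max`, so the early phase is *exactly*
log-linear with slope log10 E — which is what makes closed-form ground truth
(stored true Cq, true E) and hence oracle tests possible. A logistic curve
lacks that property. Defaults: baseline 0.02, plateau `f_max = 10` so the
quantification thresholds (≈0.43–0.50) sit at ~4–5% of plateau, in the early
exponential phase as thresholds are conventionally placed; 40 cycles;
relative noise 1% (a well-running SYBR assay; the estimator-recovery
properties are stated for 0.5–1%).

**Plates.** Each 100-well run hosts 22 triplicate samples, five triplicate
ten-fold dilution standards, six triplicate positive controls (a fixed pooled
pseudo-sample, identical across plates) and one water blank. T and S plates
are paired; the same per-sample genome-copies factor (ln-scale SD 0.2) feeds
both (same DNA aliquot), so it cancels from T/S. Per-well pipetting noise is
2% (ln scale). True efficiencies are drawn per reaction around amplicon means
of 1.86 (T) and 1.92 (S) — telomeric repeats amplify less efficiently — with
a within-plate SD of 0.003 and a between-plate SD of 0.002, and dilution
errors of 0.3% per standard level. These spreads encode a tightly validated
assay: error propagation through `E^Cq` multiplies any efficiency error by
~Cq/E ≈ 11, so percent-level heterogeneity would dominate every approach
alike, while the chosen values keep true within-plate heterogeneity *below*
the per-reaction estimation error — the regime real assays operate in (on
real data, replicate-level T/S ratios show far larger replicate CVs than
aggregated ones) and the regime in which aggregating efficiencies pays off.

**Cohort.** Families of one grandmother (ages 52.6–72.2), two daughters
(29.1–43.6) and two children each (0.5–24.9); children are male with
probability 0.464. True ln-TL decomposes as `L = a·z_age + b·G + c·u` at the
person level with a family component `G` transmitted mother→child with
loading φ, and `TL_tissue = sqrt(ρ_t)·L + sqrt(1−ρ_t)·v` per tissue. Setting
`a = age_r/sqrt(ρ_t)`, `b² = 0.8` and `φ = parent_offspring_r/(b²·ρ_t)` makes
the population cross-tissue (default 0.70), parent–offspring (0.45) and age
(−0.15) correlations of tissue-level true TL equal the targets; infeasible
combinations raise a configuration error. An age *slope* (ln-TL per year) may
be given instead of the age correlation — they parameterise the same effect,
so supplying both is an error. ln-TL spread is 0.3 (≈30% between-sample CV on
the raw scale, matching the plate-level T/S CVs the pipeline produces).
Buccal samples exist for everyone; leukocyte samples for half the adults and
2% of children, emulating cohorts in which blood draws are optional and rarely
collected from minors.

**What the generator does not emulate.** PCR inhibitors varying with dilution
(a known cause of standard-curve efficiencies above 2), melt-curve artefacts,
multi-dye channels, instrument-specific background subtraction, and plate
position effects. Passing tests therefore demonstrate the pipeline's internal
correctness and the direction of approach differences under clean conditions,
not the absolute biases of any particular instrument.

## Problem sizes and numerics

The end-to-end property study uses 200 samples (10 paired plate pairs, 2,000
reactions), enough to separate approach correlations with true TL while
keeping the whole test suite under half a minute; the attenuation simulation
uses the study-scale 1,000 replications of n = 200. Estimator-recovery sweeps
use 100 seeds. OLS fits guard against zero x-spread; r² is clipped to [0, 1];
replicate estimates `E^Cq` are evaluated in log space and exponentiated once
(no overflow up to E = 2.2, Cq = 40); report frames are sorted
deterministically and CSVs written with fixed float formats so reruns are
byte-identical; CSV floats are read back with round-trip precision.

## Known limitations

* The window search is a grid search; the selected band can shift between
  datasets, and the log-linear slope retains a small downward bias (~1%) from
  residual saturation inside the window. The bias is common to T and S and
  largely cancels in T/S correlations, but it is visible in absolute
  efficiency summaries.
* Instrument Cq values are accepted as input (or emulated by threshold
  interpolation), never recomputed from proprietary run files; vendor
  dynamic-tube normalisation is out of scope.
* The cohort generator targets population correlations; realised values in
  small cohorts scatter around them.
* The CV-equality test implements the asymptotic Feltz–Miller variant only;
  the modified signed-likelihood-ratio variant is out of scope.
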