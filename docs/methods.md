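# Methods

This note documents the statistical models implemented in `ionqtl`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Genotypes and maps

RILs are modeled as fully homozygous at every marker, coded +1/2 (allele A)
and −1/2 (allele B) so that a regression coefficient on the genotype equals
the A-vs-B trait mean difference, i.e. the additive effect *a*. Map
positions are in centimorgans; the simulator treats them as *realized*
recombination distances for the population (an intermated RIL map already
incorporates the map expansion from intermating, so no further
selfing-expansion transform is applied). Genotypes are simulated as an
independent Markov chain per line and chromosome: the first marker is A or
B with probability 1/2, and adjacent markers switch with the Haldane
probability `r = (1 − exp(−2d/100))/2` for a gap of `d` cM (no
interference). Missing genotype calls can be injected at a configurable
rate (default 0).

## Single-seed normalization

**Outlier flagging.** Within each (line, environment) group and element,
`score = |x − median| / MAD` with `MAD = median(|x − median|)`; values with
score strictly greater than 6.2 are flagged and treated as missing
downstream. The score is the raw MAD ratio by default — the threshold was
defined without a stated scale, and the raw ratio is the more conservative
reading — with the 1.4826 normal-consistency constant available as a
switch (`consistency=True`; with it, the same threshold flags fewer seeds).
Groups with MAD = 0 or fewer than three seeds are exempt. Flagging is
defined as a single pass over the input values: scores are not recomputed
on the retained seeds, so it is deterministic but not a fixed-point
iteration.

**ECDM.** Per element, ordinary least squares of the raw (non
weight-normalized) concentration on an intercept, seed weight, and the
analytical run as a categorical factor; the residual is the estimated
concentration difference from the mean (ECDM). Flagging precedes the fit;
flagged seeds are excluded from the regression and get a missing ECDM.
The fit block is one environment by default (runs nest within shipping
batches, which nest within environments), switchable to a pooled fit. A
single run level drops the run factor, a constant weight drops the weight
term; both are logged with stable `[dropped-term]` prefixes. Missing
values are never imputed: a line whose seeds are all flagged is missing,
not zero, in the line × trait matrix.

Rationale: dividing by weight assumes concentration scales linearly
through the origin; an additive weight-independent contamination term then
inflates apparent concentrations in small seeds. The regression estimates
that relationship from the data and the residual is free of it, which is
what the weight-bias test (`|corr(ECDM, weight)| < |corr(raw/weight,
weight)|` under simulated contamination) verifies.

## Heritability

Across environments the data are one observation per (line, environment)
pair with unbalanced line sets. Two sequential least-squares fits are
made, `y ~ line + env` and `y ~ env + line`, and each factor's adjusted
(type-II) sum of squares is taken from the fit where it enters second.
With `MS = SS/df`, variance components are recovered by method of moments
using the standard unbalanced group-size coefficients
`c = (N − Σnᵢ²/N)/(k − 1)`:

    V_G = (MS_line − MS_resid) / c_line
    V_E = (MS_env  − MS_resid) / c_env
    H²  = V_G / (V_G + V_E + V_resid)

Negative component estimates are clipped to zero (logged with
`[clipped-variance]`), so H² ∈ [0, 1]. The raw SS-ratio and MS-ratio
variants are also carried on the result object (`h2_ss`, `h2_ms`) because
"the genetic variance from the ANOVA" is ambiguous between these readings;
the component-based definition is the default because it is the one that
is consistent in expectation — with a simulated variance ratio
V_G : V_E : V_res = 1 : 1 : 2 it recovers H² ≈ 0.25, whereas the raw MS
ratio is dominated by the factor with more levels. The estimator requires
≥ 2 environments, ≥ 2 lines observed in ≥ 2 environments, and a connected
line × environment incidence graph; otherwise genetic and environmental
variance are not separable and an error is raised rather than a number.

Within a replicated environment, lines with fewer than two replicates are
removed, then a one-way ANOVA gives `V_G = (MS_line − MS_resid)/c` and
`H² = V_G / (V_G + V_resid)`. All-identical values leave H² undefined
(reported missing). With zero residual noise H² is exactly 1.

## LOD scans and permutation thresholds

At each marker, lines with missing genotype or trait are dropped and

    LOD = (n/2) · log10(RSS_null / RSS_marker)

with both RSS on the same subset, so the statistic is a valid likelihood
ratio; it equals `(n/2)·log10(1/(1−R²))` of the marker regression, an
identity verified against an independent regression routine at 1e−10.
Scans are at markers only — no pseudomarker imputation — because the
emulated map is dense (≈ 4200 markers) and positions are reported at
marker resolution; positions may differ slightly from an
imputation-based scan. A perfect fit is capped by an RSS floor of
1e−12 × trait variance (logged `[capped-lod]`). Zero-variance traits give
an all-zero profile with a warning; markers with < 3 informative lines are
skipped with NaN.

Genome-wide thresholds: trait values are shuffled across lines (genotypes
fixed, per-trait independent shuffles), the scan is re-run, and the
genome-wide maximum recorded; the threshold is the empirical (1 − α)
quantile (numpy's default interpolation) of 1000 permutations by default,
configurable down for desk-scale work. Permutation scans are vectorized
across permutations (one matrix product per statistic), which is what
keeps the calibration experiments cheap.

## Stepwise multi-QTL selection

Forward selection scans for the marker that maximizes the additive
multi-locus model LOD given the current loci as covariates (via
Frisch–Waugh residualization; ties break to the lowest chromosome, then
lowest position) and accepts it while the penalized LOD
`model LOD − penalty·k` increases and `k ≤ 10`; backward elimination then
drops any locus whose removal raises the penalized LOD. The
penalized-LOD-maximal model visited is returned; a non-empty model always
has penalized LOD > 0. The penalty is the per-trait permutation threshold.
Interaction terms never enter (interaction penalties are fixed at zero and
the model is purely additive). Per-locus LOD drops are
`LOD(full) − LOD(without locus)`.

Position refinement visits loci in seeded-random order, rescans each
locus's chromosome holding the others fixed, and relocates it to the
maximum-LOD marker; the model LOD never decreases, and iteration stops at
a fixed point or after 10 passes.

QTL from different environments are merged per trait and chromosome by
single-linkage clustering with a 5 cM linkage distance: peaks 4.9 cM apart
are one locus, 5.1 cM apart are two, and a 0/4/8 cM chain is one locus.

## QEI

**Location-covariate test.** Growouts are stacked with one observation per
(line, year); years of the same location share a location label, and lines
present in both years contribute one observation per year with identical
genotype rows (fixed-effects formulation; no within-line correlation is
modeled). At each marker where every location carries both genotype
classes, the full model `y ~ g + loc + g:loc` and the additive model
`y ~ g + loc` are fit; each is scored against the shared genotype-free
null `y ~ loc`, and `ΔLOD = LOD_full − LOD_add ≥ 0` up to rounding since
the models nest. Uninformative or incomplete markers are skipped and
logged.

The permutation null repeats the full three-step procedure. Shuffling is
*within location strata*: an unstratified shuffle would destroy location
main effects and inflate the null. The implementation permutes trait
values within each stratum, which for every statistic involved is
equivalent to permuting the line-to-genotype assignment within the stratum
and vectorizes across permutations; `stratified=False` switches to an
unstratified shuffle. The threshold is the (1 − α) quantile of the
genome-wide max ΔLOD. Type-I calibration under a constant-effect null and
power under a ±1 SD effect reversal are checked end to end in the
acceptance suite.

**Difference mapping.** For two years at one location, the per-line
difference `y_yearA − y_yearB` over common lines (≥ 3 required) becomes a
trait mapped with the standard permutation-threshold stepwise procedure.
Only line means enter, never seed-level data. Year-stable effects cancel
(detection at ≈ α), year-specific effects double up relative to their
average and are detected.

## Synthetic-data generator

Default scenario: a 302-line RIL pool (the full population from which the
study growouts were subset) on a 10-chromosome map with 422 markers per
chromosome at 700 cM per chromosome; ten growouts FL05 (220 lines), FL06
(118), IN09 (193), IN10 (168), NC06 (197, 3 reps), NY05 (256, 3 reps),
NY06 (82), NY12 (168), MO06 (97, 2 reps), SA10 (87); 20 elemental traits;
seed weights ~ Normal(250 mg, 50 mg) truncated positive; four analytical
runs assigned in contiguous blocks; measurement noise SD 0.05 on the raw
scale; 1% heavy outliers. Trait values follow
`y = μ + Σₖ a_{k,e}·g_k + E_e + ε` with independent ε per replicate row,
and raw seed measurements follow
`raw = weight·trait + contamination + run_offset + noise`. Outliers are
injected at ≥ 12 group-MADs (one per group at most, amplified until the
post-injection MAD score clears the flagging threshold) and only into
groups of ≥ 3 seeds, since smaller groups are exempt from flagging — so
injected outliers are recoverable by construction. All randomness flows
from one scenario seed through fixed per-environment sub-streams, making
every output bit-reproducible.

What the generator does *not* emulate: pedigree-accurate intermating (the
Markov chain has no interference or segregation distortion), linkage
disequilibrium beyond the map, multi-allelic markers, within-run ICP-MS
drift (runs are a pure batch offset), correlated elements, or soil/weather
structure behind environment effects. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
model, not that real-data artifacts beyond that model are handled.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use reduced but
statistically meaningful designs chosen to make the checks sharp: 200
pure-noise scans at 100 lines × 300 markers with 200-permutation
thresholds for false-positive calibration; 100 datasets of 2 locations ×
200 lines for QEI type-I error; 20–25 replicates for power, recovery and
selectivity rates; 20 replicates of 200 lines × 4 environments for
heritability recovery. Because permutation scans are vectorized, the full
suite runs in well under a minute on one core.

## Known limitations

- With covariates, markers that have missing genotypes beyond the
  covariate-complete rows are scored by a Frisch–Waugh approximation
  rather than an exact per-marker refit (exact for complete markers, which
  is the default simulation setting).
- The across-environment ANOVA uses one-way-style method-of-moments
  coefficients for the unbalanced variance components; for severely
  unbalanced two-way layouts these are approximate (the exact Henderson
  coefficients were judged not worth the complexity at the observed
  imbalance).
- The QEI stacked model treats repeated lines as independent observations,
  matching the fixed-effects formulation; a mixed model with random line
  effects is out of scope.
- Heritability is broad-sense only; no REML/mixed-model estimation.
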