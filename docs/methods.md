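# Methods

## The isolation index

Every barrier is expressed on a common scale by comparing the rate of
heterospecific events H with the matching conspecific rate C for the same
recipient species and life stage:

    RI = 1 - 2·H / (H + C),     RI ∈ [-1, 1].

RI = 1 iff H = 0 (complete isolation), RI = 0 iff H = C (random gene
flow), RI = -1 iff C = 0 (purely heterospecific success). The index is
invariant to common rescaling of H and C, so percentages, fractions and
raw means are interchangeable, and it is antisymmetric under swapping H
and C. H + C = 0 is treated as *undefined* and raised as an error: "no
data" must never be silently promoted to "complete isolation".

All indices are directional: the recipient (seed parent) comes first.

## Temporal isolation (RI_F)

Inputs are flowering censuses: at each census date, the number of
monitored plants with open flowers out of a per-species sample. Working
with proportions p(t) = n_flowering/n_sampled normalises the very
different sample sizes per species (70–385 plants in the reference
study). Two same-season series are aligned on the union of their census
dates with implicit zeros (censuses are near-synchronous and biweekly;
interpolation would manufacture co-flowering that was not observed).
Each date with p_f + p_o > 0 contributes

    H += p_f·p_o / (p_f + p_o)        C += p_f² / (p_f + p_o)

to the focal species' heterospecific and conspecific exposure. The
weights make a date's contribution proportional to the focal species'
flowering there, split by the composition of the joint flowering pool:
disjoint schedules give H = 0 hence RI_F = 1; identical proportion
schedules give H = C hence RI_F = 0; scaling either species' counts and
sample sizes together changes nothing. A published spreadsheet variant
of this co-flowering index exists whose exact algebra differs in the
weighting; the kernel is isolated in a single function
(`coflowering_exposure`) so it can be swapped, and reproduction of
published per-pair RI_F values is treated as out of reach without the
original raw censuses.

Multi-season designs average the per-season index arithmetically.
A season in which the focal species never flowered has no mating
opportunities, so its index is undefined; such seasons are dropped from
the mean with a logged warning rather than counted as 0 or 1.

Seasons may span the calendar-year boundary (October–July in the
reference system); dates are kept as real calendar dates throughout.

## Mechanical isolation (RI_MS, RI_MP)

Four floral traits are measured per flower (mm): corolla length, corolla
aperture diameter, stamen length, pistil length.

*Testing.* Species differentiation is tested with a distance-based
permutation multivariate ANOVA on the Euclidean distance matrix of the
raw traits: with a species, N flowers, SS_total partitioned into
among/within components,

    pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)),   r² = SS_A/SS_total,
    p = (1 + #{F* ≥ F_obs}) / (1 + n_perm).

The permutation unit is the flower; labels are shuffled with a seeded
generator (default n_perm = 999). Pairwise tests follow a significant
global test and are Bonferroni-corrected by the number of pairs actually
tested. The implementation is validated against exhaustive enumeration
on 6-flower problems and against scikit-bio's PERMANOVA pseudo-F.

*Assignment.* The published criterion for the size barrier is visual —
"clearly separated in the multidimensional space" of a standardized PCA
biplot. That judgment is operationalized as: RI_MS = 1 iff the pairwise
test is significant after correction (α = 0.05) AND the two species'
PC1 score intervals (mean ± 2 sd) are disjoint; otherwise RI_MS = 0.
PC1 separation stands in for the biplot because the first component
carries the bulk of size variation in guild-structured morphometrics,
and ±2 sd approximates the extent of a 95% ellipse. Significance alone
is deliberately insufficient: with 30 flowers per species, tiny mean
differences are significant without implying different pollen placement,
and 0 is the conservative call. RI_MP = 1 iff the two species' anther/
stigma arrangement categories differ (dorsal hood vs lateral triplets).
Both indices are symmetric.

## Postpollination isolation (RI_I, RI_S, RI_V)

Raw inputs are one row per pollinated plant (flowers pollinated, fruits
set), one row per harvested fruit (seed count), and one row per
germination replicate (sown, germinated). Summaries per directed pair:

* fruit rate = 100·Σfruits/Σflowers (pooled over plants) → H or C of RI_I;
* mean seeds per *successful* fruit with sample sd (n−1) → RI_S — per
  fruit, not per pollinated flower, because fruit failure is already
  charged to RI_I;
* germination = unweighted mean over replicate percentages (the
  replicate, default 12 × 40 seeds, is the experimental unit) → RI_V.

A cross that sets no fruit gives RI_I = 1 and leaves RI_S and RI_V *not
measured* (NaN + flag), mirroring how such chains compress in the
sequential calculus. Published index values are reproduced from the
bundled summary table to within ±0.002: the published inputs are
themselves rounded (whole seeds, 0.1%), which moves three recomputed
values (0.496/0.497, 0.317/0.316, 0.150/0.149) by ~0.001.

## Sequential contributions

With measured strengths ordered RI_F → RI_MS → RI_MP → RI_I → RI_S →
RI_V (the life-cycle order), AC_1 = s_1 and AC_k = s_k·(1 − ΣAC_{<k});
TI = ΣAC; RC_k = AC_k/TI (NaN when TI = 0, flagged not raised). For
strengths in [0,1], TI = 1 − Π(1−s_i), AC ≥ 0, and TI is order-invariant
and monotone in each strength; a strength of 1 zeroes every later AC.
Not-measured barriers are skipped so the chain compresses; their rows
are kept in the output with NaN sentinels. Negative strengths propagate
through the same recurrence with a warning, since they break the
"share of total" reading of AC.

Category means (pre- vs postpollination) are unweighted means over all
measured directional cells, *including* assigned zeros of the binary
mechanical indices. On the bundled strengths this gives 0.614 for the
36 prepollination cells and 0.459 for the 12 measured postpollination
cells. The reference study's narrative quotes 0.225 for the
postpollination category; no simple mean of the published cells yields
that number (candidate schemes give 0.459, 0.306 or 0.153), so the
package reports the internally consistent measured-cell mean and notes
the divergence here rather than special-casing it.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, plus closed-form truth for recovery testing:

* *Phenology*: flowering probability is a mixture of Gaussian bumps
  π(t) = min(1, Σ a·exp(−(t−μ)²/2w²)) — one wide low bump for a
  steady-state bloomer, one narrow tall bump for a cornucopia burst, two
  bumps for a bimodal species — sampled every 14 days over a 280-day
  season as Binomial(n_sampled, π(t)).
* *Crossing*: fruits ~ Binomial(flowers, p); seeds per fruit ~ negative
  binomial with mean m and size k (var = m + m²/k — field seed counts
  are strongly overdispersed, e.g. a published 636 ± 234); germination ~
  Binomial(40, p) per replicate, 12 replicates.
* *Morphometrics*: multivariate normal per species (4 traits), truncated
  below at 0.01 mm; flowers are exchangeable within species (the
  reference study reports no within-plant variance decomposition).

One global seed fans out to one independent substream per table via
`SeedSequence` spawning, so every table is individually reproducible.

The bundled study-like preset copies the reference design: four
species with the observed schedule shapes and monitoring sample sizes,
crossing probabilities/means/dispersions matched to the published
summary table (dispersion k = m²/(var − m)), and a large-flowered vs
small-flowered morphometric structure with 2–3× trait separation between
groups but overlapping morphology within them.

What the simulations do *not* emulate: weather-driven interannual
phenology shifts (seasons are i.i.d. given the schedule), pollinator
behaviour, spatial or microhabitat structure, plant-level random
effects, and germination contamination losses. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to those field realities.

## Verification choices and problem sizes

* The total-isolation identity ΣAC = 1 − Π(1−s) is property-tested over
  10⁴ random chains of length 1–6.
* The permutation test is checked against exhaustive enumeration of all
  C(6,3) = 20 label partitions at n = 6 (the sampled p must match the
  exact p within 3 binomial standard errors at 999 permutations).
* Parameter recovery runs the full crossing experiment at the study's
  sample sizes for 1000 Monte-Carlo replicates and requires each
  estimator's mean to sit within two standard errors of a 200-replicate
  recovery experiment (2·sd/√200 ≈ 0.007 for the noisiest stage) of the
  closed-form truth. The 1000-replicate average pins the estimator's
  expectation precisely (residual noise ≈ 0.0017) so the check verifies
  the bias itself — measured at ≈ −0.002 for the worst stage, the
  seeds-per-fruit index with 6–11 fruits per cell — rather than a single
  noisy 200-replicate draw. The small negative bias is the usual
  Jensen-gap of a ratio of small-sample means under overdispersion and
  vanishes as design sizes grow.
* Rounding of reported values is half-up at 3 decimals (`_rounding.py`);
  comparisons against published values allow ±0.002 for the
  rounded-input effect described above.

## Limitations

* RI_F depends on the co-flowering kernel variant; cross-study
  comparisons should confirm the same variant was used.
* Binary RI_MS/RI_MP collapse a continuum of pollen-placement overlap to
  {0, 1}; both are conservative operationalizations of a qualitative
  judgment.
* Conspecific baselines typically come from a companion breeding-system
  experiment; the index inherits any protocol differences between the
  two experiments.
* AC/RC carry no uncertainty quantification (none is defined for the
  published framework); totals of exactly 1.0 arise whenever any single
  barrier is complete, masking variation in the others.
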