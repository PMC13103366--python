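# Methods

## The statistic

MAJIC (Mean Across Jaccard Index Checkerboards) asks, for each *focal
species* *i* in a species-by-sample relative-abundance table, whether the
communities that contain it look systematically different from the
communities that lack it. The table is binarised into a presence/absence
matrix (bit = 1 iff relative abundance > `presence_threshold`, default 0, a
strict inequality), and the samples split into σᵢ⁺ (focal present) and σᵢ⁻
(focal absent). Writing J(s, t) for the binary Jaccard dissimilarity
1 − |Sₛ ∩ Sₜ| / |Sₛ ∪ Sₜ| between the species supports of two samples,

- µᵢ⁺ = mean of J over the C(n⁺, 2) sample pairs within σᵢ⁺,
- µᵢ⁻ = the same within σᵢ⁻,
- ∆µᵢ = µᵢ⁺ − µᵢ⁻.

∆µᵢ < 0 means communities containing the focal species are more mutually
similar — the species marks a *restrictive* (constrained) community state;
∆µᵢ > 0 marks a *facilitating* state with greater variability. (The sign
convention follows the definition ∆µᵢ = µᵢ⁺ − µᵢ⁻ literally; prose that
paraphrases the sign the other way round is easy to produce and we document
the convention here once.)

### The null and classification

The null model is a frequency-preserving shuffle: the focal species' presence
vector is permuted uniformly at random across samples (its prevalence is
preserved exactly — asserted on every shuffle) while the rest of the matrix
stays fixed. 10,000 shuffles by default. Because only one row moves, the
Jaccard values can be updated incrementally: with I and U the
intersection/union counts over the non-focal species for a sample pair, a
pair inside σ⁺ has dissimilarity 1 − (I+1)/(U+1) and a pair inside σ⁻ has
1 − I/U. Both n×n matrices are computed once per focal species; every
shuffle then only averages sub-blocks, so the full null ensemble is a few
matrix products regardless of how many species the table holds.

A focal species is called **state-associated** when its observed statistic
differs from the shuffle ensemble at α = 0.05, and **state-dissociated**
otherwise. Two test constructions are provided, because a single observed
µ⁺ value cannot feed a two-sample KS test directly:

- `ks_mode="pairwise"` (default): two-sided KS between the observed
  within-σ⁺ pair dissimilarities and the within-σ⁺ pair values pooled
  across all shuffles (pooled sample capped at 10⁵ values by uniform
  subsampling under the run seed). This compares distributions of like
  objects and is sensitive to any change in the σ⁺ pair-value distribution.
  Caveat: pair values within one split are not independent and Jaccard
  values are discrete, so the KS p-value is approximate (asymptotic above a
  10⁴ size product, exact below) and this mode should be read as a
  powerful detector rather than an exactly calibrated test.
- `ks_mode="permutation"`: the add-one-corrected two-sided empirical
  p-value of the observed µ⁺ against the null µ⁺ ensemble,
  p = (1 + #{|µ⁺ₖ − med| ≥ |µ⁺_obs − med|}) / (K + 1). This is exactly
  calibrated (type-I error ≈ α on neutral data; the acceptance suite checks
  the rate over 200 neutral tests against the binomial 99% band
  [0.02, 0.09]) but tests µ⁺ only, so it has little power against
  structure that lives mainly in σ⁻ (e.g. a facilitating focal species
  whose absence marks the restricted state).

Both p-values are recorded; the mode used for classification is stored in
every output row.

### The focal row in the Jaccard computation

By default (`include_focal=True`) the focal species' own (permuted, for
nulls) presence bit takes part in the Jaccard computation. Every σ⁺ pair
then shares at least the focal species, which deterministically lowers µ⁺
relative to µ⁻ — but the same bias applies to every shuffle, so it cancels
between observed and null. The practical consequence, covered by property
tests: the null ∆µ ensemble is *not* centred at zero with
`include_focal=True` (it is displaced negative alongside the observed
value), and is centred at zero with `include_focal=False`, where µ⁺ and µ⁻
average the same exchangeable pair values. `include_focal=False` is exposed
for sensitivity analysis.

### Degenerate cases

µ needs at least one sample pair, so splits with n⁺ < 2 or n⁻ < 2 (the
`min_group` default) are reported `not_computable`, never raised. Samples
that are entirely empty after filtering are dropped with a warning (an empty
community has no Jaccard relation). If two or more samples contain *only*
the focal species, a shuffle can place both in σ⁻ where their pairwise
Jaccard is 0/0; that focal species is likewise reported `not_computable`
with a logged warning. Random seeds: one master seed per run; the per-focal
seed is derived from the master seed and the (group, species-id) strings via
CRC-32 into a `SeedSequence`, so per-species results are independent of the
iteration order and of which other species are present.

## The abundance-effect stage

For each focal species *i* with a computable split, every other species *j*
is tested for a shift in relative abundance between σᵢ⁺ and σᵢ⁻ with a
two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact when the pooled
values are tie-free and n + m ≤ 20, otherwise the normal approximation with
tie and continuity corrections. Effect direction is the sign of the median
difference, falling back on the rank-sum orientation under a median tie.
P-values are Bonferroni-adjusted (p_adj = min(1, m·p)) within each focal
family (all targets of one focal species in one group) by default;
Benjamini–Hochberg and a single global family are available. Abundances are
tested on the original fraction scale without renormalisation.
`filter_effects` reproduces the reported subset: significant records whose
focal species is state-associated, optionally restricted to an interest set
of taxa (e.g. dominant *Bifidobacterium* and *E. coli*).

## Filtering, descriptors and defaults

- **Species filter** (per group, applied before MAJIC): a species is kept
  iff it reaches ≥ 0.1% relative abundance in ≥ 10% of the group's samples.
  The boundary is inclusive (exactly 10% keeps the species: the exclusion
  rule is "fewer than 10%"). Abundances are *not* renormalised after
  filtering, so the 20% dominance threshold keeps its meaning; a
  `renormalize` flag exists and is off by default.
- **CSI** (cross-sample Shannon index): per species, the Shannon entropy in
  nats of its relative-abundance vector across samples, normalised within
  the species. Bounded by ln N (N samples); attained only by an exactly even
  species; a single-sample species scores 0. Percentile rank is the
  fraction of other species with strictly smaller CSI (ties share a rank);
  the "top 5%" flag requires rank > 0.95. Natural logarithms throughout.
- **C-score**: for a species pair with occupancy counts rᵢ, rⱼ and
  co-occurrence count S, CU = (rᵢ − S)(rⱼ − S), averaged over all species
  pairs. A perfect two-species checkerboard on four samples scores 4.
- **Prevalence / high abundance**: fraction of samples with abundance > 0,
  and strictly > 0.20.
- **Dominance patterns**: each sample is classified by the number of
  "dominant" (> 20%) *Bifidobacterium* species and *E. coli* presence (> 0)
  into five categories (single/multiple/no dominant *Bifidobacterium* ×
  *E. coli* present/absent).

Defaults everywhere: 10,000 shuffles, α = 0.05, 10%/0.1% filter,
presence threshold 0, Bonferroni adjustment, `ks_mode="pairwise"`,
`include_focal=True`, `min_group=2`.

## The synthetic generator

The generator emulates *filtered* relative-abundance tables, not raw
profiler output: per-species occupancy probabilities drawn from
Beta(1, 3) (right-skewed prevalence spectrum), independent Bernoulli
occupancy per sample, log-normal(0, 1) abundances for present species,
per-sample renormalisation to sum exactly 1. Samples that come out empty
receive one uniformly chosen species, since an empty community has no
Jaccard relation. A designated focal species (id `focal`) is appended:

- **neutral** — focal occupancy is independent Bernoulli(0.5); any
  state-association call is a false positive by construction. This is the
  calibration anchor.
- **restrictive / facilitating** — the focal occupies exactly
  round(prevalence·n) samples; on the restricted side of the split the
  community is drawn from a restricted pool (occupancy pushed towards 1
  inside the pool and suppressed outside by the `contrast` parameter,
  defaults pool 15 of 60, contrast 0.8); the other side draws from the full
  pool at baseline. `contrast = 0` degenerates to the neutral generator;
  `contrast = 1` makes the restricted side deterministic.
- **abundance effect** — a neutral table whose planted target species'
  abundances are multiplied in σ⁺ before renormalisation. Planted targets
  are made ubiquitous (occupancy 1): a multiplicative abundance effect only
  exists where the species occurs, so the planted signal is purely an
  abundance difference. Renormalisation spills a mild negative effect onto
  the other species, as real compositions do; the truth sidecar records the
  targets and multipliers.

What the generator does *not* emulate: phylogenetic correlation between
species, host-wise repeated measures, sequencing depth/detection noise, and
genuinely sparse compositional count structure. Passing tests therefore
demonstrate correctness and calibration of the statistics under a clean
occupancy/abundance model, not robustness to profiler artefacts.

### Power of the abundance-effect stage

Under log-normal(0, 1) abundance noise, a ×3 multiplicative shift separates
σ⁺ from σ⁻ shares with AUC ≈ 0.67 (the noise-free-composition ceiling is
Φ(ln 3/√2) ≈ 0.78). A 20-vs-20 rank-sum therefore detects it after
Bonferroni adjustment in only ~10% of replicates; ≥95% detection at this
noise level would need roughly a ×8 effect. The validation suite asserts
the stronger bound and the assertion documents the shortfall; the
family-wise error control itself is confirmed (≈0 false-positive families
in 50 neutral replicates), and unit tests with a strong (×25) planted
effect confirm the detection machinery and direction handling.

## Problem sizes used in the validation suite

Oracle equivalence uses 100 random 12×8 matrices checked against a
set-based double-loop Jaccard implementation at 1e-12. Calibration uses 200
neutral tables of 40 samples × 60 species with 1,000 shuffles each;
planted-structure recovery and the Wilcoxon checks use 50 replicates. These
sizes give binomial standard errors of ~1.5% (calibration) and ~3%
(recovery) on the reported rates while the whole suite completes in well
under a minute of compute.
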