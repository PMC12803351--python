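# Methods

This note documents the models and procedures implemented in
`sugartrait`, the assumptions behind them, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Keyword census of sugar transporters

Sugar transporters are counted from free-text annotation products, not
from alignments or HMMs. A feature counts only if its product contains
every *gate term* ("sugar" and "transporter", case-insensitive
substrings) and at least one family token:

| family | tokens |
|---|---|
| ABC | `ABC` (case-sensitive, word-bounded), "ATP-binding cassette" |
| PTS | `PTS` (case-sensitive, word-bounded), "phosphotransferase" |
| MFS | `MFS` (case-sensitive, word-bounded), "major facilitator" |

Matching uppercase abbreviations case-sensitively on word boundaries
prevents, e.g., a lowercase "abc" inside an unrelated word from
counting, while spelled-out family names match case-insensitively. A
feature contributes at most one count per family (a product matching
two families increments both); a `per_occurrence` mode counts token
repeats within a product instead, for users who read "occurrences"
literally. Features sharing a `protein_id` are collapsed before
counting (identical proteins are often listed once per replicon);
the fallback key is (genome, feature id). Families are deliberately
not resolved by sugar specificity — the census approximates repertoire
size, not substrate range.

Glycolytic enzymes are screened the same way with per-enzyme term
lists. The shipped default covers nine enzymes across the
Embden–Meyerhof–Parnas (hexokinase with sugar kinase / glucokinase /
ROK-family alternates, 6-phosphofructokinase, pyruvate kinase),
pentose phosphate (glucose-6-phosphate dehydrogenase,
6-phosphogluconate dehydrogenase, ribose-5-phosphate isomerase) and
Entner–Doudoroff (G6PD again, phosphogluconate dehydratase, KDPG
aldolase) pathways, plus phosphoglucomutase for regression use. This
list is a configurable default, not a curated authority: laboratories
with their own enzyme panels should override `KeywordRuleset.enzyme_terms`.
A pathway is called complete only when all three of its required
enzymes are present; partial pathways are treated as non-functional.

Species selection takes the top 20 species per phylum by available
genome count (ties broken lexicographically by species name, for
determinism) and samples at most 20 genomes per species; genus-level
means subsample at most 100 genomes per genus. All sampling is
without replacement under a seeded generator whose child streams are
keyed by a stable digest of the phylum/species/genus label, so results
do not depend on process hash randomization or iteration order.

## Trait structure

Presence matrices binarize counts at zero (any transporter of a family
counts as carriage). Pairwise mutual information uses the plug-in
(maximum-likelihood) estimator on the empirical 2×2 joint table, in
bits, with 0·log 0 = 0. No bias correction is applied — at the scale
of hundreds to a thousand genomes the plug-in bias (~1/2n ln 2 per
degree of freedom) is negligible, and the estimator is the simplest
defensible choice. The diagonal reports each trait's entropy;
constant traits have zero entropy and zero MI with everything.
Repertoire groups assign each genome to its exact transporter
combination (the intersection semantics of an UpSet plot), so group
sizes partition the genome set and per-trait set sizes equal column
sums.

## qPCR fold changes

Fold change between a reference and a sample measurement of the same
strain is `2^ΔCt` with

    ΔCt = (Ct_ref − Ct_sample) + log2(normalizer_sample / normalizer_ref)

where the normalizer is culture volume (in vitro) or fecal weight (in
vivo). The weight term is implemented exactly as written: at equal Ct
a heavier sample yields a larger fold change. Technical duplicates
are averaged on the Ct scale before ΔCt (standard practice; averaging
on the linear scale would weight low-Ct wells more). Not-detected
(ND) reactions propagate as an explicit `not_detected` call rather
than being imputed; an optional mode imputes ND at the terminal cycle
(40) for users who want a bounded estimate. Expansion means fold
change strictly greater than 1.

The ratio t-test of fold changes against 1 is a one-sample t-test of
log2 fold changes against 0 — a ratio test is a location test on the
log scale, where replicate noise is closer to symmetric. Degenerate
zero-variance input returns p = 1 when all values equal 1 (null
exactly true) and p = 0 otherwise, with a signed infinite statistic.

## Growth statistics and the CFU mixed model

Growth-curve AUC is the trapezoidal integral of OD600 over hours with
no baseline subtraction by default (a flag subtracts the initial OD).
Spearman associations use average ranks for ties; the two-sided
p-value is an exact permutation tail probability for n ≤ 9 and the
usual t approximation beyond that.

The CFU regression is a random-intercept linear mixed model per
(timepoint, sugar concentration) stratum: binary gene-presence
indicators as fixed effects, a varying intercept per biological
repeat, fitted by maximum likelihood through statsmodels' MixedLM.
The default outcome scale is log10(CFU + 1) — CFU counts span orders
of magnitude, making raw-scale residual normality untenable — with a
raw mode available since the appropriate transform depends on the
assay. ML rather than REML keeps the likelihood comparable across
fixed-effect specifications; at the group counts involved (≥ 6
biological repeats) the difference in variance components is
immaterial. Predictors retained for regression must be present in
strictly more than 25% and strictly fewer than 75% of species —
near-constant indicators carry no contrast. Constant columns are
dropped with a warning; remaining rank deficiency is an error that
names the aliased predictors.

## Diet exposure

Meal records (patient, study day, 8-digit food code, grams) are summed
to patient-day sugar totals using a nutrient lookup of sugar grams per
100 g food. Unresolvable codes are skipped and counted in a log
message rather than failing the run. Each microbiome sample is paired
with the mean of the day totals over the two days before collection
(a day-3 sample gets the mean of days 1 and 2). Days without records
are dropped from the mean rather than zero-filled — an unrecorded day
is non-recording, not fasting — and a strict mode requires both prior
days. A sample with no prior-day records has undefined exposure and
is excluded from modeling.

## Compositional preprocessing

Feature tables are aggregated to genus level after discarding features
without a genus label, then renormalized to relative abundance. The
genus filter keeps a genus present at ≥ 0.01% relative abundance in at
least 10% of samples (proportion ≥ 0.10 on the raw fraction, no
rounding of sample counts), or reaching ≥ 10% abundance in any sample.
The CLR transform is natural-log (base choice is immaterial once
outcomes are standardized): `clr(x)_g = ln x_g − mean_g ln x_g`, rows
summing to zero by construction. Zeros are replaced before the log by
adding half the smallest nonzero relative abundance of the matrix to
every entry and renormalizing — a multiplicative-replacement variant
that perturbs all parts equally — with a fixed-pseudocount mode
available. Standardization uses the sample standard deviation (n − 1).

## Bayesian sugar-association models

Each genus is modeled independently:

    genus_i ~ Normal(μ_i, σ),  μ_i = α + β·sugar_i
    α ~ Normal(0, 1),  β ~ Normal(0, 1),  σ ~ Exponential(1)

with the CLR outcome standardized per genus and the lagged sugar
exposure standardized once over the analysis samples (not per genus).
Sampling uses an adaptive random-walk Metropolis sampler on
(α, β, log σ) with the log-σ Jacobian: the posterior is
three-dimensional and nearly Gaussian, so a gradient-based sampler
would add complexity without benefit. Each chain runs 1000 warmup
steps — Robbins–Monro step-size tuning toward ~30% acceptance, with
the proposal shape re-estimated from the warmup covariance from
mid-warmup on and frozen afterward — followed by 4000 post-warmup
steps thinned by 4, retaining 1000 draws per chain × 4 chains = 4000
draws. Initialization is (0, 0, 0) with jittered retries on a
non-finite posterior. Split R-hat and an autocorrelation-based ESS
are reported per parameter, with a warning above R-hat 1.01; typical
runs give R-hat < 1.01 and ESS around 1000.

Summaries report the posterior β mean, 66% and 95% equal-tail
intervals, and the 95% HPD interval computed as the shortest
contiguous window over the sorted draws; "excludes zero" refers to
the HPD. No multiple-testing adjustment is applied across genera —
each model is reported as its own posterior — but the count of
excludes-zero calls is surfaced so readers can judge the family-wise
picture. Per-genus seeds derive deterministically from one master
seed, so the whole table is reproducible and individual genera can be
re-run in isolation.

The second stage regresses per-genus β means (already on the z scale)
on the genus-mean count of one transporter family divided by its
maximum, with the same priors and sampler. The fitted mean is
simulated over the covariate range from the posterior draws with a
95% band, and a Spearman rank correlation between raw counts and β
means accompanies the regression. An all-zero covariate skips the
regression and flags the correlation undefined.

With σ fixed, the (α, β) posterior has the conjugate ridge closed
form `cov = (I + X'X/σ²)^(−1)`, `mean = cov·X'y/σ²`; this is used as
an independent oracle in tests, never as the sampler.

## Synthetic-data generator

The generator exists so every stage can be scored against known
truth. Defaults mirror the emulated study scale: 158 patients, 1,009
microbiome samples, 91 genera, genus-mean ABC counts spanning 0–46
(the top end matching the largest observed genus mean), residual CLR
noise σ = 0.5 on the z scale and lognormal daily sugar intake with a
~30 g median. Specifically:

* **Annotations** plant exact per-genome family counts using products
  that satisfy the keyword rules, interleaved with decoys that must
  not count (gate-term-missing, token-missing, lowercase-"abc"
  traps), plus a complete EMP enzyme set; the census round-trips the
  planted counts exactly, and feature order is shuffled because the
  census must be order-invariant.
* **Ct tables** invert the ΔCt equation for chosen true fold changes,
  optionally with Gaussian cycle noise and ND injection, so the
  pipeline recovers the truth exactly in noise-free mode.
* **Diet/abundance studies** draw daily sugar totals from a lognormal
  (a stand-in; the distribution of true intakes is not modeled
  here), emit meal logs whose day sums reproduce them exactly, and
  generate each genus's standardized CLR outcome as β·x_std + noise.
  Compositions are the softmax of the per-sample centered outcome
  vector, so CLR recovery is exact up to the centering; planted β
  vectors are therefore centered across genera — CLR data identify
  only contrasts, and an uncentered planted vector would shift every
  genus by the mean. Optional zero-inflation is applied pre-CLR, and
  recovery tests then use tolerance bands.
* **Trait/β pairs** draw genus counts uniformly on 0–46 and set
  true β = effect × (count/max) + Normal(0, 0.05), exercising the
  second stage directly.

What the generator does **not** emulate: phylogenetic correlation
among genomes, longitudinal autocorrelation within patients (models
are cross-sectional per sample), realistic annotation vocabulary
breadth, sequencing noise beyond rounding to integer counts, and
informative missingness in diet records. Passing recovery tests
therefore demonstrate correctness of the inference machinery under
the stated model, not robustness to these real-data features.

## Numerical choices and degenerate inputs

* Seeded child streams use `SeedSequence` spawn keys from stable
  digests; identical seeds give bit-identical MCMC draws.
* HPD windows use ⌈0.95·N⌉ draws, so HPD mass ≥ 0.95 − 1/N by
  construction and width never exceeds the equal-tail 95% width.
* MI terms with zero joint probability contribute 0; tiny negative
  rounding is clipped at 0.
* Ct values must lie in (0, 40]; normalizers must be positive.
* Empty annotations yield an all-zero census; an empty genus or an
  all-zero sample row is excluded with a warning or error as
  documented per function.
* Genera whose CLR column has zero variance are reported with status
  `zero_variance` and skipped, not silently dropped.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the calibration checks at
reduced but statistically meaningful sizes chosen as a deliberate
compromise between resolution and turnaround: 200 replicate datasets
at n = 150 for interval coverage (binomial SE ≈ 1.5% at 95% coverage),
40 null genera for the excludes-zero rate, 500 simulations for t-test
uniformity, 60 genera for two-stage recovery, and a 30-genus ×
200-sample end-to-end study. The library itself has no scale limits
beyond memory; the per-model sampler cost is O(1) in sample size after
sufficient statistics are computed.

## Known limitations

* Keyword censuses inherit annotation vocabulary: genomes annotated
  with non-standard product strings under- or over-count, and the
  default enzyme list is a stand-in for a curated panel.
* The per-genus models ignore between-genus dependence induced by
  compositionality; coefficients are associations, not causal
  effects, and no covariates (antibiotics, conditioning) are
  adjusted for.
* The exposure construction treats recorded intake as complete and
  equates a two-day mean with exposure; lag structure is fixed, not
  estimated.
* The mixed model assumes Gaussian residuals on the chosen CFU scale
  and a single variance component.
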