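# Methods

## Data model

A publication is a flat annotation record: `year` (2013–2017 by default),
anonymized `journal` label (J1–J6), `validated` (whether a stability
algorithm selected the internal control genes — the YAL/NAL split),
`icg_tested` and `icg_used` gene lists, and binary reporting flags
(`reported_stability`, `reported_260_280`, `reported_integrity`). Gene
symbols are normalized to HUGO-style canonical form through a
case/whitespace/hyphen-insensitive alias table before any counting;
unrecognized symbols are kept uppercased rather than dropped, so usage
counts never silently lose genes. Two schema constraints are enforced
rather than documented away: an unvalidated record cannot carry an
algorithm name, and it cannot report stability output (that output is
produced by the validation software; the CSV reader coerces such cells to
"no" with a warning instead of failing).

## Scoring

`SCORE = GENE + VALID + REPORT` with fixed weights (0/23/35, 0/50, 0/15).
The weights are constants of the rubric, not tunables. Because REPORT
presupposes VALID, the reachable values are exactly
{0, 23, 35, 50, 65, 73, 85, 88, 100}; the test suite verifies this by
enumeration. `icg_used` is deduplicated before the GENE component is
computed — a gene cannot serve twice in one normalization factor.

Percentages everywhere are rendered at one decimal, rounding halves away
from zero, computed in exact integer arithmetic (`normaudit._round`); each
reported percentage carries its numerator and denominator so the rounding
convention is checkable.

Technical articles (publications whose aim is itself reference-gene
determination) are *kept* in the headline full-corpus statistics and
excluded only on request (`--exclude-technical`), because the corpus-wide
denominators quoted throughout use the full 225. The one place the
exclusion is always applied is "denominator convention B" below.

## Usage statistics

`Count_X` counts publications using gene X (one instance per record).
The normalized impact `Count_X / Count_TOT` divides by the number of
*unique* genes in the subset — deliberately not the total instance count —
so it can exceed 1 and rewards subsets with narrow gene repertoires; the
per-publication factor `Count_X / N_pub` is the share of articles using the
gene. Selection ratios (selected/tested) summarize validation outcomes and
are computed from their marginal counts.

Denominator convention B: the single-gene share and integrity-reporting
rate of the non-validated subgroup are reported against the subgroup minus
its technical articles (156 = 158 − 2), alongside the full-subgroup figure.
The audit report always prints both, with a warning note, because the two
conventions give visibly different percentages (75.6% vs 74.7% for
single-gene use) and the source material for such audits is rarely explicit
about which it used.

## Inference

All estimators are implemented in this package on numpy/scipy primitives;
statsmodels appears only in the test suite as an independent oracle.

**Trend models.** OLS (Gaussian ML) for SCORE and logistic regression
(logit link, IRLS) for the validation indicator, over a candidate grid:
Journal main effect plus Year as polynomial degree 1–4 or as a factor, each
with or without the Journal × Year interaction. Year is centred at its
sample mean before powers are taken (conditioning only). AIC is
−2ℓ + 2k with k counting every estimated parameter *including* the
Gaussian error variance — the R `AIC()` convention, so values are
comparable to that ecosystem (statsmodels' OLS AIC is exactly 2 lower).
Ties within 1e−6 break toward fewer parameters, then listed order.
Term-level p-values use likelihood-ratio chi-square tests (refit without
the block), one uniform mechanism across families. The logistic response
is modelled with the logit link; the log link sometimes named for binary
responses is atypical (fitted means can exceed 1) and is not provided.

**Likelihood-ratio test.** `lr_test` accepts fits whose coefficient-name
sets nest; identical models return statistic 0, p = 1. Degrees of freedom
are parameter-count differences.

**Conway–Maxwell–Poisson.** pmf ∝ λ^y/(y!)^ν with log link on λ. The
normalizing constant Z(λ, ν) = Σ λ^j/(j!)^ν is accumulated in log space
until a term drops below the running sum × 1e−12 past the series mode
(≈ λ^{1/ν}, computed in log space so extreme optimizer proposals fail
cleanly), hard-capped at 100 000 terms. Regression maximizes the joint
likelihood over (β, log ν) with BFGS from three dispersion starts
(ν₀ ∈ {0.5, 1, 2}; β₀ from a Poisson IRLS fit), relative tolerance 1e−9,
max 500 iterations; the covariance is the inverse observed information via
a central-difference Hessian. The reported rate ratio is exp(β_group) — a
ratio of λ, not of means; under strong underdispersion the two differ
substantially (mean ≈ λ^{1/ν}), which is why the fixture's extremely
regular counts give a large fitted λ-ratio. The dispersion check is a
1-df likelihood-ratio test of ν = 1, with the verdict side taken from ν̂.

**Fisher exact test.** Two-sided p by full hypergeometric enumeration in
log space: sum of point probabilities ≤ the observed one (relative
tolerance 1e−7 on the comparison, the convention of mainstream software).
When every table in the support qualifies the p-value is exactly 1.

## Synthetic data

`generate_dataset` emulates the audited corpus: 225 publications over
2013–2017 and six journals (uniform weights), P(validated) = 67/225,
P(technical) = 2/225, gene counts from a CMP with shared ν = 1.8, baseline
λ = 2.0 (non-validated mean ≈ 1.4 genes/publication) and group log-rate
ratio log 1.44; gene identities are drawn without replacement from
subgroup profiles whose weights equal the observed per-publication rates
(GAPDH/ACTB/RNA18S dominant, the remaining mass spread over minor genes);
reporting flags are Bernoulli with the subgroup rates (integrity 0.701 vs
0.321, purity 0.015 vs 0.025, stability 36/67 given validation). Counts
are sampled by inversion of the truncated CMP CDF. Everything flows
through one seeded `numpy` generator; identical seeds give byte-identical
CSV output.

What the generator does **not** emulate: year-by-journal composition
effects (year and journal are independent of everything else by default),
correlation between reporting flags within an article, citation-driven
gene fashions over time, and any real per-article gene co-occurrence
structure. Passing tests on synthetic data therefore demonstrate estimator
correctness and pipeline determinism, not claims about any real corpus.

`fixture_dataset` is the deterministic counterpart: a 225-record dataset
with no randomness and no floating-point content that simultaneously
satisfies every anchored marginal (subgroup sizes 67/158, 24 records at
SCORE 100 and 49 at ≥ 85, subgroup gene-user counts for GAPDH/ACTB/RNA18S,
64 vs 50 unique genes, 47/67 integrity reporters, 1/67 vs 4/158 purity
reporters, 118 single-gene users among the 156 non-technical NAL records,
and tested-gene counts 38/29/8 in the validated subgroup). Where only a
percentage is known, the anchor count is the unique integer reproducing it
at the documented denominator under the one-decimal rounding rule.
Construction: fixed per-record gene-count slots; genes dealt by descending
target count to the records with the most free slots (ties by index);
flags assigned to leading record indices; years, journals and algorithm
names cycle. Cells not pinned by an anchor (e.g. per-year score means) are
whatever this deterministic rule produces and are not meaningful. The
builder re-verifies every anchor through the scoring and usage modules and
raises if any is violated. Filler gene symbols use the named minor
reference genes (EIF3K, PPIA, RPL19, RPS9, TBP, UXT) before synthetic
placeholders (GENE001…).

Two printed figures are deliberately *not* anchored: the corpus-wide
validated/non-validated sizes appear once as 67/158 and once as 72/156 in
the source material, and the fixture follows 67/158 with the technical
count (2) chosen so convention B's 156 denominator exists; and the
abstract-level claim that 158 articles score 0 is incompatible with the
subgroup gene-user counts (59 + 44 + 18 non-validated users of the big
three cannot all be single-gene articles within 118 single-gene slots), so
the fixture's score-0 count is 118.

## Recovery simulation

The count-model check does not target the published rate-ratio estimate on
the unavailable raw data; it targets *recovery*: simulate two groups of
2000 records from the generator's CMP (ν = 1.8, baseline λ = 2.0, true
rate ratio 1.44, seed 42), refit with `cmp_regression_fit`, and compare
exp(β̂) to the generating value. At these conditions the ML estimator is
efficient (empirical SD of the rate-ratio estimate ≈ 0.041, matching the
Wald SE) and 95% CI coverage is nominal; a fixed absolute band of ±0.05
around 1.44 corresponds to only ≈ 1.2 standard errors and is met by an
individual replicate about three quarters of the time — a sampling-noise
fact about the band, not an estimator defect. Problem sizes throughout the
suite (replicate counts of 50–200, group sizes 300–2000) were chosen as
the smallest that make the Monte-Carlo checks statistically meaningful.

## Known limitations

* The CMP rate ratio is link-scale; no mean-parameterized variant is
  offered.
* The alias table ships only the genes the audit names; real corpora need
  a fuller table (`GeneAliasTable.from_csv`).
* The logistic fitter flags complete separation rather than applying a
  penalized (Firth-type) correction.
* The fixture encodes marginals, not joint structure; cross-tabulations it
  was not anchored on (e.g. score by journal) carry no information.
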