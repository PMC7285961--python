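# normaudit

An audit pipeline for the quality of RT-qPCR normalization in published
research. Given a corpus of annotated publications — which internal control
genes (ICG) each article tested and used, whether a stability algorithm
(geNorm, NormFinder, BestKeeper) validated them, and which MIQE-relevant
details were reported — `normaudit` quantifies how compliant the field's
normalization practice actually is, and whether algorithm users behave
differently from everyone else.

## Who it is for

Meta-researchers and editors auditing reporting standards in gene-expression
literature, and methodologists who need the underlying statistical machinery
(underdispersed count regression, exact contingency tests, AIC model grids)
on small annotated tabular datasets.

## The model

Each publication receives a compliance score

```
SCORE = GENE + VALID + REPORT ∈ [0, 100]
```

with GENE ∈ {0, 23, 35} (≤1, 2, 3+ genes in the normalization factor),
VALID ∈ {0, 50} (stability-algorithm validation) and REPORT ∈ {0, 15}
(quantifiable stability output reported; requires VALID). Gene popularity in
a subset is summarized two ways: the per-publication factor
`Count_X / N_pub` and the normalized impact `Count_X / Count_TOT`, where
`Count_TOT` is the number of *unique* genes in the subset.

Counts of genes per publication are underdispersed, so the validated/
non-validated contrast is fitted with a Conway–Maxwell–Poisson regression,

```
P(Y = y) ∝ λ^y / (y!)^ν,   log λ_i = β₀ + β₁·validated_i,
```

where ν > 1 captures underdispersion (ν = 1 recovers Poisson) and
`exp(β₁)` is the rate ratio between subgroups. Usage and reporting
contrasts use the two-sided Fisher exact test; score and validation trends
over Journal and Year are chosen by AIC over a grid of polynomial-vs-factor
year forms with optional Journal × Year interaction.

## Worked example

The package ships a deterministic 225-record dataset that reproduces the
marginal statistics of a five-year, six-journal livestock-science corpus
(67 validated / 158 non-validated publications):

```python
from normaudit import fixture_dataset, proportion_scoring, usage_table
from normaudit import usage_contingency, fisher_exact_2x2

ds = fixture_dataset()
p = proportion_scoring(ds, 100, "eq")
print(f"SCORE == 100: {p.numerator}/{p.denominator} = {p.percent}%")
ut = usage_table(ds.subset(validated=True))
print("YAL unique genes:", ut.count_tot)
t = usage_contingency(ds, "RNA18S")
print("RNA18S table:", t.as_array().tolist(),
      "Fisher p =", round(fisher_exact_2x2(t).pvalue, 3))
```

prints

```
SCORE == 100: 24/225 = 10.7%
YAL unique genes: 64
RNA18S table: [[1, 66], [18, 140]] Fisher p = 0.016
```

— only 10.7% of publications reach full compliance; validated publications
draw on a more diverse gene pool (64 unique genes among 67 articles) and
use the much-criticized ribosomal RNA18S significantly less often than the
non-validated majority.

The same pipeline runs from the shell:

```
normaudit run --input fixture --out report/      # report.json + TSVs
normaudit score --input data.csv --thresholds 85,100 --json
normaudit simulate --seed 7 --out synth.csv      # stochastic analogue
```

`normaudit simulate` draws datasets with the same statistical structure
(CMP gene counts with a configurable group rate ratio, subgroup-specific
gene-frequency profiles, conditional reporting flags), reproducible per
seed; see `docs/methods.md` for what the generator does and does not
emulate.

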