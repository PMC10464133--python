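# kappakit

Two-rater inter-rater reliability (IRR) statistics for categorical
ratings: Cohen's kappa and the power-weighted kappa family (linear and
quadratic weighted kappa), with standard errors, confidence intervals,
tests, qualitative interpretation, and advice on which statistic fits a
given measurement scale.

It is written for the common clinical-research setting where two raters
(radiologists, pathologists, coders, an algorithm vs a reference
standard) each assign every subject to one of a few categories and the
question is how well they agree beyond chance — for example, RECIST 1.1
tumour-response calls (PR < SD < PD) against a reference standard.

## The statistics

For a fully-crossed design with two raters and *n* categories, let
*p<sub>ij</sub>* be the proportion of subjects rated category *i* by
rater A and *j* by rater B, with marginals *p<sub>i</sub>* (rows) and
*q<sub>j</sub>* (columns). All kappas are chance-corrected agreement
rates

&nbsp;&nbsp;&nbsp;&nbsp;κ = (P<sub>o</sub> − P<sub>e</sub>) / (1 − P<sub>e</sub>),

where the observed agreement P<sub>o</sub> = Σ<sub>ij</sub> w<sub>ij</sub> p<sub>ij</sub>
and the chance-expected agreement P<sub>e</sub> = Σ<sub>ij</sub> w<sub>ij</sub> p<sub>i</sub> q<sub>j</sub>
for an agreement-weight matrix w. The identity matrix (full credit for
exact matches only) gives **Cohen's κ**; the power scheme

&nbsp;&nbsp;&nbsp;&nbsp;w<sub>ij</sub><sup>(m)</sup> = 1 − (|i − j| / (n − 1))<sup>m</sup>,&nbsp;&nbsp; m ≥ 1,

gives partial credit for near misses on an ordered scale: m = 1 is the
**linear weighted kappa (LWK)**, m = 2 the **quadratic (QWK)**. For two
categories every power weighting collapses to Cohen's κ.

Inference uses the Fleiss–Cohen–Everitt large-sample (non-null)
variance with a two-sided Wald test of κ = 0, so "p < α" and "the
(1−α) CI excludes 0" always coincide; a subject-resampling percentile
bootstrap is available as a cross-check. Magnitude is labelled on the
Landis–Koch bands (slight/fair/moderate/substantial/almost perfect),
optionally gated to "no agreement" when the test is not significant.

Cohen's κ is prevalence-sensitive: at a fixed raw agreement it falls as
one category comes to dominate the marginals. `prevalence_paradox_demo`
demonstrates this on 2×2 models, and a joint-probability simulator
supports estimator-recovery and CI-coverage studies.

## Worked example

The bundled data are six 3×3 confusion matrices of treatment-response
calls (PR/SD/PD) against a reference standard for 31 patients with
liver metastases: two radiologists (R1, R2) and an automated
segmentation pipeline, on a testing dataset and a validation cohort.

```python
from kappakit import InterRaterModel

model = InterRaterModel.from_counts(
    [[1, 0, 2], [4, 3, 3], [1, 1, 16]],   # testing dataset, R1 vs reference
    labels=("PR", "SD", "PD"),
    rater_names=("R1", "reference"),
)
print(model.fit(statistic="weighted", m=1).summary())
```

```
Inter-rater agreement
======================================================
statistic:        linear kappa
raters:           R1 vs reference
subjects:         31
categories:       PR, SD, PD
------------------------------------------------------
kappa:              0.3764
observed agr.:      0.7742
expected agr.:      0.6379
std. error:         0.1353  (asymptotic)
95% CI:           [ 0.1113,  0.6416]
p-value (k=0):      0.0054
interpretation:   fair
======================================================
```

Reading it: the raters matched on 77% of subjects, but 64% agreement
was expected from their marginal category usage alone, leaving a
chance-corrected LWK of 0.38 (2 dp) — *fair* agreement, significantly
better than chance (p ≈ 0.005). `model.advise()` confirms the scale
calls for weighted kappa:

```
3 ordered categories: near-miss disagreements should earn partial
credit; report both linear and quadratic weighted kappa
```

The same toolkit runs from the shell:

```sh
kappakit compute --table ratings.csv --stats cohen,linear,quadratic --json out.json
kappakit advise --categories 3 --ordinal
kappakit reproduce-table1          # full reanalysis of the six bundled matrices
kappakit simulate --paradox        # prevalence-paradox demonstration
```

`reproduce-table1` prints each matrix with its marginal totals and the
three statistics with CIs and verdicts, e.g. for the testing dataset,
R1 vs reference: κ_c 0.35 (95% CI 0.11–0.60), LWK 0.38, QWK 0.40, all
p < 0.05; for R2 vs reference the three statistics are 0.22/0.20/0.18
with p > 0.05 — no agreement demonstrable beyond chance.

## Layout

- `src/kappakit/` — `scale`, `weights`, `table`, `core` (estimation),
  `inference`, `interpret`, `model` (Model/Results surface), `simulate`,
  `datasets` (bundled matrices), `io`, `report`, `cli`
- `tests/` — unit, property (hypothesis) and acceptance tests
- `docs/methods.md` — statistical methods, conventions and limitations
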