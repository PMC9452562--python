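# pdxscreen

Analysis pipeline for preclinical CDK4/6-inhibitor resistance studies in
ER⁺ breast cancer: mRECIST-style response calling in patient-derived
xenografts (PDX), a composite immunohistochemistry (IHC) biomarker for
predicting resistance, ex vivo spheroid/EdU readouts with a ROC-derived
response cutoff, allele-aware *RB1* "double hit" calling with
exposure-association logistic models, and geNorm-based qPCR normalization —
plus seedable synthetic-data generators so every stage is testable without
animals, slides, or controlled-access cohorts.

It is written for translational and computational oncology groups who run PDX
drug screens and biomarker analyses and want the scoring and statistics as
reusable, tested code rather than spreadsheet conventions.

## What it computes

**Tumor response (`growth`).** Caliper pairs become volumes via the ellipsoid
formula V = (L × W²)·π/6. Percent change against the day-0 baseline,
ΔV% = 100·(V_t − V₀)/V₀, is banded RECIST-like on the best (most negative)
change at ≥ 10 days on treatment:

    CR ≤ −95 < PR ≤ −30 < SD ≤ +20 < PD

Cohorts are summarized as the preclinical response rate pRR = (CR+PR)/n and
benefit rate pCB = (CR+PR+SD)/n, with bootstrap (n = 2000) standard errors.
Relative tumor volume RTV = V_t/V₀ is banded at 0.7 and 1.2 for trajectory
plots.

**Composite biomarker (`biomarkers`).** p16 and total pRb are scored 0–4,
cyclin E1/D1 on the Allred 0–8 scale. A sample is predicted resistant if any
rule fires, in order: basal-like intrinsic subtype; p16 ≥ 2; pRb ≤ 2;
cyclin E1 > 4 or cyclin D1 > 6. Cutoffs are Youden-optimal
(J = sensitivity + specificity − 1) and overridable. Concordance is reported
as sensitivity/specificity/accuracy/PPV/NPV with "resistant" as the positive
class. KI67 rules: Luminal A/B split at %KI67 < 15; antiproliferative
response at day 15 iff ln(%KI67) < 1.

**Ex vivo (`exvivo`).** Spheroid areas and EdU fractions as percent of
vehicle; a model is ex vivo sensitive when its area change is ≤ −25%
(boundary inclusive). Four-parameter-logistic IC50 fitting on log dose after
day-0 normalization and vehicle relativization; IC50 is the dose at 50% of
control growth, never extrapolated.

**Genomics (`genomics`).** Coding mutations are recognized from a controlled
nine-term consequence vocabulary or parsed from HGVS-protein strings
(`p.M695Nfs*26` → frameshift, `p.K810*` → stop gained, `p.X180_splice` →
splice). Deletions are called from allele-specific copy number (minor and
major < 0.01 → homozygous; minor only → heterozygous) or from log-ratio bands
(deep < −1 ≤ shallow < −0.4 ≤ unaltered). A coding mutation plus a
heterozygous deletion is a **double hit**. Two logistic models relate
alteration status to prior drug exposure: M1, exposure ~ mutation + deletion
+ mutation×deletion; M2, exposure ~ double-hit indicator; both with Wald
inference and explicit separation flags.

**qPCR (`qpcr`).** geNorm stability values M (mean SD of pairwise log₂
expression ratios) rank candidate reference genes, with iterative exclusion
and the pairwise-variation V statistic; comparative-Ct normalization against
the geometric mean of the references (efficiency fixed at 2); per-gene group
comparisons with Benjamini–Hochberg FDR.

`stats` carries the shared machinery (IRLS logistic with Wald inference,
Fisher exact, BH, ROC); `synthetic` the generators; `validation` the TSV/CSV
schemas; `reporting` the worked-example reproduction; `plots` simple
waterfall/spaghetti/ROC renderings.

## Worked example

```bash
python examples/growth_response.py
```

```
measurement table: 2464 rows, 21 models
...
class counts: {'CR': 1, 'PR': 2, 'SD': 2, 'PD': 16}  (n = 21)
pRR (CR+PR): 14.3%  -> reported 14%
pCB (CR+PR+SD): 23.8%  -> reported 24%
mean day-35 change: 222.4% (bootstrap SE 33.4)
```

A 21-model simulated screen with one complete response, two partial
responses and two stable diseases yields a 14% response rate and a 24%
benefit rate: roughly one model in seven shrinks by at least 30%, and adding
stable disease brings the fraction deriving any benefit to about one in
four. The other scripts in `examples/` walk the composite biomarker, the ex
vivo ROC/IC50 readouts, *RB1* double-hit calling with the association
models, and qPCR normalization the same way.

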