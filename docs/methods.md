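# Methods

This note documents the models and procedures pdxscreen implements, the
defaults that matter, the synthetic-data assumptions, and the numerical and
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Tumor growth and response calling

Caliper pairs (length L, width W, mm) are converted to volumes with the
ellipsoid formula V = (L × W²)·π/6; the smaller dimension is squared, so the
operation is symmetric in its arguments and width > length on ingest is
resolved by swapping. Percent volume change at day t is
ΔV%(t) = 100·(V_t − V₀)/V₀ against a mandatory day-0 baseline.

Response classes are banded on the **best response**, the minimum ΔV% over
the treatment window, with boundaries closed on the sensitive side:
CR ≤ −95 < PR ≤ −30 < SD ≤ +20 < PD. The best-response minimum is restricted
to days ≥ 10 (`MIN_BEST_RESPONSE_DAY`, overridable): by continuity the first
post-baseline measurement lies near 0% and would otherwise place every tumor
— including ones that triple by day 35 — in the SD band, making PD
uncallable. The ≥ 10 d floor is the convention used for preclinical
mRECIST-style screens. The day-35 change is reported separately from the
best response because screens conventionally plot the end-of-window value
while classifying on the best value; when day 35 itself was not measured the
nearest record within ±3 days is used (earlier day wins a tie), else the
day-35 field is absent.

Relative tumor volume RTV_t = V_t/V₀ is banded PD > 1.2, SD ∈ [0.7, 1.2],
PR/CR < 0.7. The lower bound is read as 0.7 (an RTV cannot be negative).

Model-level calls average the per-tumor ΔV% trajectories of a model/arm at
each shared day and classify the best mean change, mirroring mean-of-tumors
waterfall reporting. Cohort summaries report pRR = 100·(CR+PR)/n and
pCB = 100·(CR+PR+SD)/n both exact and rounded half-away-from-zero (the
rounded values are what screen reports print). The bootstrap SE of a mean
percent change is the SD of 2000 resampled means, deterministic given the
seed.

## Composite IHC biomarker

Scales: p16 and total pRb are semiquantitative ordinals 0–4; cyclin E1/D1
use the Allred 0–8 score, the proportion bin (0%, <1%, 1–10%, 11–33%,
34–66%, >66% → 0–5) plus intensity 0–3. Continuous H-scores (0–300) are a
distinct type used only by the per-SD odds-ratio analysis; no implicit
conversion exists between the scales.

The composite rule evaluates, in order: basal-like intrinsic subtype → p16 ≥
2 → pRb ≤ 2 → (cyclin E1 > 4 or cyclin D1 > 6); the first satisfied rule is
recorded and the sample is predicted resistant; if none fires it is
sensitive. The order affects only which rule is reported as fired, never the
binary call. The "4/6" cyclin cutoff is read positionally: E1 > 4, D1 > 6.
Normal-like subtype does not fire the basal rule. A missing score cannot
fire its rule; a panel is unclassifiable only when the subtype is unknown
and all four scores are missing.

The Youden search maximizes J = sensitivity + specificity − 1 over all
distinct observed score values (score = threshold counts as positive), in
either direction. Ties on J break toward higher sensitivity, then the lower
threshold — for a resistance screen, missing a resistant case is the costly
error. Concordance metrics derive exactly from the 2×2 table with
"resistant" as the positive class.

KI67 rules: Luminal A iff %KI67 < 15; antiproliferative response at day 15
iff ln(%KI67) < 1, i.e. KI67 below e ≈ 2.72% — the log is taken on the
percentage as printed, not on a fraction, otherwise typical Luminal-B
baselines (ln 15 ≈ 2.7) could never classify as resistant. A KI67 of exactly
0 is clamped to a vanishing positive percentage and therefore calls
sensitive, flagged in the docstring.

The per-SD odds ratio z-scores the continuous marker before a univariate
logistic fit, so OR = exp(β) is the odds multiplier per 1 SD.

## Ex vivo readouts

Relative spheroid area is 100 × mean(treated areas)/mean(vehicle areas) per
condition (median available as an option); replicate wells are averaged
first, matching mean-spheroid-area reporting. The readouts are scale
invariant. EdU fractions are percent positive nuclei, relativized to vehicle
the same way. The ex vivo response cutoff defaults to −25% area change and
is boundary inclusive (a change of exactly −25 calls sensitive); the source
convention states the cutoff without boundary semantics, and inclusivity
keeps the sensitive call aligned with "reduction at least as deep as the
cutoff". The ROC uses per-model mean changes, not per-replicate values, and
lower change = positive (sensitive) class.

IC50 fitting: wells are day-0-normalized (growth = day6/day0), the per-dose
mean growth is relativized to vehicle mean growth — in that order — and a
four-parameter logistic bottom + (top − bottom)/(1 + 10^(h·(x − x₀))) is fit
on x = log₁₀ dose by least squares on the percent scale, initialized from
the response quantiles with the hill-slope sign free. The reported IC50 is
the dose where the fitted curve crosses 50% of control growth, solved
analytically from the parameters; if 50% is not bracketed by the fitted
asymptotes or the crossing falls outside the observed dose range, the result
is flagged `not_reached` with no extrapolated value.

## Genomic hit calling and exposure association

The coding-mutation vocabulary is the nine-term set {frameshift, stop
gained, splice acceptor, splice donor, start lost, stop lost, missense,
inframe deletion, inframe insertion}; the "deleterious" subset is the five
truncating terms. Protein-change parsing covers the printed HGVS styles
(`fs*N`, terminal `*`, `_splice`, `p.M1?`, single-residue substitution) and
returns a generic splice term — acceptor vs donor is not recoverable from
`p.X###_splice` — which both rule sets accept. Parsing never raises;
unrecognized records map to "unknown" and never qualify.

Copy-number state comes from either dialect: allele-specific CN (minor and
major < 0.01 → homozygous deletion; minor only → heterozygous) or log-ratio
bands (deep < −1 ≤ shallow < −0.4 ≤ unaltered; gains collapse to
unaltered). When both are present, allele CN wins — the two dialects come
from different platforms and the allele-specific call is the more direct
zygosity measurement. Hit categories per sample/gene: homozygous deletion
dominates; a coding mutation plus heterozygous deletion is a double hit;
then mutation-only, deletion-only, none. Any qualifying variant sets the
mutation flag (presence, not burden); the deepest loss wins when several
segments cover the locus. Calls are order-independent and idempotent.

Association models: M1 regresses exposure on mutation, deletion and their
interaction; M2 on the double-hit indicator alone. Both are reported because
the exact published formulas are not printed; M1 isolates the interaction
from marginal single-hit effects, M2 is the pooled higher-powered contrast,
and they agree in sign when marginal effects are absent (property-tested).

Logistic fits use hand-written IRLS (Fisher scoring), convergence tolerance
1e-8 on the step, maximum 100 iterations, with Wald SEs, z, two-sided normal
p-values and ±1.96·SE CIs. Separation is detected as a diverging coefficient
sup-norm (> 30, beyond any estimable odds ratio on standardized or binary
designs) or a singular information matrix; a separated fit withholds
estimates entirely rather than reporting a numerically diverged point. No
small-sample corrections are applied. Fisher's exact test delegates to
scipy (conditional two-sided hypergeometric p) with the sample cross-product
OR, optionally Haldane-corrected for zero cells. BH q-values are the step-up
formula q_(i) = min_{j≥i} m·p_(j)/j, capped at 1.

## qPCR

geNorm M for gene j is the mean over partners k of the SD across samples of
the pairwise log₂ expression ratio, which under fixed efficiency 2 equals
Ct_k − Ct_j; lower M is more stable, identical genes give M = 0, and M is
invariant to per-sample Ct shifts. Iterative exclusion drops the highest-M
gene until the requested panel size (the conventional stopping statistic
V_{n,n+1} is implemented but a fixed final pair of 2 is the default use).
Normalization is comparative Ct: relative expression = 2^−(Ct_target −
mean Ct_references), i.e. 2^(−ΔCt) against the geometric mean of the
reference quantities, with efficiency fixed at 2 (no efficiency
correction). Samples missing any reference Ct are excluded and listed. Group
comparisons default to the rank-sum test — normality is not asserted for
small PDX panels — with Welch's t available, followed by BH adjustment.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a master config whose seed is
mandatory; each draws from its own RNG stream derived from the master seed
plus a stable per-generator label (CRC32), so adding a generator never
shifts another's output and regeneration is byte-identical. Truth keys are
returned separately, never embedded in the analysis inputs.

**Growth.** V(t) = V₀·exp(r·t) per tumor with the class rate r back-solved
from a noise-free day-35 target: CR −97.5%, PR −60%, SD −5%, PD +300%,
vehicle +300% (mid-band for the response classes; the PD/vehicle target
corresponds to a doubling roughly every two weeks and keeps the earliest
eligible best-response day several noise SDs above the +20% band edge).
Defaults: 21 models split 1/2/2/16 across CR/PR/SD/PD, 2–8 tumors per model,
vehicle + treated arms, measurement days 0–35 twice weekly, baselines
uniform in 100–300 mm³, 10% lognormal multiplicative volume noise,
dimensions back-solved at aspect ratio 1.5, welfare truncation at 1500 mm³.
Not emulated: inter-tumor growth-rate heterogeneity within a model,
non-exponential kinetics, dropout other than volume truncation.

**Biomarkers.** Each sample draws a true class (resistant prevalence 0.65,
near the screen's 15/23 R:S split); with probability ε (default 0.15) the
panel realizes the opposite composite call, one uniformly chosen rule firing
for resistant-call panels. Measured accuracy and sensitivity against the
truth are therefore 1 − ε in expectation — the generator encodes the rule
structure exactly, so passing tests show the classifier implements its
definition and tracks planted noise, not that real IHC scores behave this
way.

**Genomics.** Exposure ~ Bernoulli(71/582). Among the unexposed,
(mutation, deletion) are independent Bernoulli(p_mut, p_del); among the
exposed the joint cell probabilities are tilted by exp(θ) on the (1,1) cell
and renormalized, which makes the exposure-odds cross-product ratio across
the four cells equal exp(θ) exactly — the logistic interaction coefficient
targets θ with no approximation. Defaults p_mut = 0.30, p_del = 0.45 were
chosen a priori by the expected-events-per-cell rule: at the default cohort
sizes the smallest interaction cell keeps roughly ≥ 10 expected exposed
double hits, the regime where Wald inference is approximately calibrated.
They are generic alteration-flag prevalences for calibration studies, not
literal single-gene population frequencies; single-gene double hits in real
cohorts are rarer, and small-sample inference on them is correspondingly
less well calibrated. Optional realization emits protein-change strings that
round-trip through the parser and allele-CN records consistent with the
flags.

**Ex vivo.** Spheroid area changes are class-conditional,
sensitive ~ N(−50, 10)% and resistant ~ N(0, 10)%, across 37 models with 3
replicate wells at 5% lognormal noise — well-separated classes, so ROC AUC
near 1 is expected by construction. Dose plates realize a known 4PL
(IC50 1 µM, hill 1, top 100, bottom 0) on 8 log-spaced doses (10⁻³–10² µM)
plus vehicle wells, 5-fold vehicle growth over 6 days, lognormal well noise.

**qPCR.** Per-sample offsets (SD 1 cycle) are shared by all genes, so
ratio-stable reference genes exist by construction (gene noise 0.05 cycles);
unstable candidates add 1-cycle gene noise; a −2-cycle shift on designated
target genes in the treated half of samples provides a detectable group
effect.

## Problem sizes

Test-suite and acceptance-script simulation sizes were chosen so the full
run completes in well under a minute on one CPU while leaving the binomial
or Monte-Carlo error comfortably inside each asserted tolerance: 200
replicates × 200 samples for composite concordance (SE of the mean accuracy
≈ 0.2 points against a 3-point tolerance), 500 null replicates for the KS
uniformity check, 200 replicates for CI coverage, 100 plates for IC50 bias,
and dense grids (thousands of points) for the band-classifier oracles.

## Known limitations

- The logistic Wald inference carries no small-sample or separation-adjacent
  corrections (no Firth penalization); sparse-cell cohorts should expect
  anti-conservative p-values, and the separation flag is the guardrail.
- The 4PL fit reports least-squares point estimates only; no CI on IC50.
- `parse_protein_change` handles the printed HGVS styles, not the full HGVS
  grammar (no delins, extensions, or frame-preserving duplications).
- The composite classifier consumes pathologist-scored ordinals; no image
  quantification is attempted.
- geNorm's V-based panel-size choice is available but not wired into any
  default pipeline; the default is a fixed pair of references.
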