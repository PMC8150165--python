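# Methods

## Classifier

GMLVQ represents each class by a prototype vector w in standardized feature
space and measures dissimilarity with a learned quadratic form

    d(w, x) = (x − w)ᵀ Λ (x − w),    Λ = Ωᵀ Ω,

where Ω is an unrestricted d×d matrix. Λ is symmetric positive
semi-definite by construction; it is renormalised to trace(Λ) = 1 after
every update, which prevents metric collapse and makes diag(Λ) a
probability-like measure of per-feature importance — the basis of the
steroid relevance ranking and of the backward panel reduction.

Training minimises the relative-distance cost Σᵢ φ(μᵢ),
μᵢ = (d_J − d_K)/(d_J + d_K), where d_J is the distance to the nearest
prototype of sample i's own class and d_K the nearest wrong-class
prototype. μ ∈ [−1, 1], negative iff correctly classified; φ is the
identity by default (a sigmoid with configurable slope is available).
Gradients are analytic:

    ∂μ/∂d_J = 2 d_K/(d_J+d_K)²,   ∂μ/∂d_K = −2 d_J/(d_J+d_K)²,
    ∂d/∂w = −2 Λ (x−w),           ∂d/∂Ω = 2 Ω (x−w)(x−w)ᵀ.

Defaults: one prototype per class, initialised at the class-conditional
mean plus seeded jitter (σ = 0.01 z-units); Ω = I/√d; 80 epochs of batch
gradient descent with prototype step 0.5 and metric step 0.01 (both applied
to the mean gradient). A step that would increase the cost is undone and
retried with halved rates (up to 30 halvings), so the recorded training
cost is non-increasing — chosen over stochastic updates for exact
reproducibility of the validation suite; a seeded stochastic mode exists.
The metric step is deliberately a small fraction (1/50) of the prototype
step: slow metric adaptation keeps split-averaged relevance rankings
stable, which matters more here than fast cost reduction.

Degenerate cases: a sample coinciding with prototypes of both classes
(d_J + d_K = 0) contributes 0 with a logged warning; exact prediction ties
resolve to the lowest class label in sort order; 2-D projections use the
two leading eigenvectors of Λ scaled by √eigenvalue, with a fixed sign
convention and a zero-filled second coordinate (plus warning) when
rank(Λ) < 2.

The binary ROC statistic is the signed relative distance
μ̂(x) = (d_neg − d_pos)/(d_neg + d_pos): antisymmetric under swapping the
arms, and thresholding at 0 reproduces the nearest-prototype label.

## Preprocessing

Concentrations (μg/L) are creatinine-corrected to μg steroid/g creatinine
(× 100/creatinine[mg/dL]); an uncorrected per-litre mode supports the
sensitivity analysis. Values are log10-transformed with a per-feature
floor of half the smallest positive value — imputation preserves subjects
with below-detection values rather than dropping them — then z-scored with
the population-SD convention (deterministic; the n vs n−1 distinction is
immaterial at cohort size but tests need exactness). In validation, floors
and z statistics are fitted on training subjects only. Covariates (age,
BMI, sex coded F=0/M=1) are appended on their raw scale before that single
standardisation step, so they obey the same no-leakage discipline.

Enzyme-activity ratios are computed on corrected, non-log values (the
creatinine factor cancels): 11β-HSD1 ≈ (THF + 5αTHF)/THE, A-ring
reductase ≈ 5αTHF/THF, plus total glucocorticoid output as the sum of the
11 cortisol/cortisone metabolites. Zero denominators flag the ratio as
missing (NaN) instead of aborting a batch.

## Validation design

For a binary stage contrast, `repeated_split_validation` draws stratified
random train/test partitions (default 100 splits, 10% test), fits
preprocessing and classifier on the training side, scores the held-out
side, and reports per-split AUCs, their mean, a 2.5/97.5-percentile
interval, a pooled ROC curve (vertical averaging on a 101-point FPR grid),
and per-feature relevances averaged over splits. Percentile CIs over
splits were chosen over DeLong as the distribution-free match to a
repeated-validation design. AUC is computed by threshold sweep and
trapezoid (equal to Mann-Whitney concordance with half-credit ties; the
test suite verifies this against exhaustive pair enumeration).

Backward elimination re-validates at every panel size and removes the
steroid with the smallest mean relevance (ties alphabetical); covariates
are exempt, defining the reduced-panel-plus-covariates variant. A
fixed-ranking mode (rank once, prune in that order) is provided; the
sequential mode is the default. Group comparisons of ratios use
tie-corrected Kruskal-Wallis with Dunn's post hoc z-tests,
Bonferroni-adjusted over the pairs (the conventional correction; the
analysis threshold is p < 0.05).

## Synthetic cohorts

The generator emulates the study's cohort table: 275 subjects (106
controls; 121 NAFLD split 13/13/13/41/41 across F0–F4; 48 alcohol-related
cirrhosis), per-group age, BMI, sex ratio, T2D prevalence, HbA1c, ALT,
AST, platelets from the published demographics (controls' AST/platelets
and albumin, not reported, use normal-range values), clipped to
physiological ranges. Serum chemistry is drawn so mean FIB-4 is higher in
F3–F4 than F0–F2 by construction. Steroids are drawn log-normally
(within-class log10 SD 0.35, roughly two-fold biological variation) around
per-metabolite baselines spanning 1.4–3.4 log10 μg/L, with a 1 μg/L
detection floor reported as 0 (not detected). NAS scores are drawn
independently of the steroid signal, mirroring the negative
NASH-classification finding. Urinary creatinine is log-normal with median
100 mg/dL.

Class signal enters as mean shifts, in noise-SD units, on
contrast-specific metabolite lists taken from the published discriminatory
rankings; shifts add over contrasts whose positive arm contains the class,
and the alcohol-cirrhosis class inherits the F4 profile plus its own
aetiology shift on five ethanol-responsive metabolites. The full
32-steroid assay list is not public; the default panel is the 26
metabolites named in the analysis padded with six configurable
placeholders.

Effect magnitudes (top effects 1.0/0.8/0.6/0.6 per contrast list, decaying
linearly to 70% across the ten ranks) were fixed against the closed-form
Gaussian separability of the shift model so that (a) the ordering of
contrast difficulty matches the clinical picture — aetiology hardest, then
screening for any NAFLD, then stage separation with near-perfect
control-vs-cirrhosis detection — and (b) each contrast's informative
metabolites are recoverable by the relevance ranking above the
finite-sample noise floor at the cohort's size (n ≈ 121 for the staging
contrast, d = 32). Those two goals conflict at clinically realistic
separability: at AUC ≈ 0.92 the weakest informative metabolites are
statistically indistinguishable from noise features at this n, so the
default cohort is deliberately more separable (AUC ≈ 0.99 for the staging
contrast) than real patients. Consequently, passing tests demonstrate
correctness of the machinery — no leakage, calibrated null behaviour,
relevance recovery, panel-reduction fidelity — not clinical performance;
absolute AUCs from the simulator should not be quoted as estimates of
real-world accuracy. Other unmodelled features of real data include
inter-metabolite correlation (features are independent given class),
batch/instrument drift, missing-not-at-random patterns beyond the
detection floor, and medication or diurnal effects.

## Serum comparator scores

APRI = (AST/ULN)/platelets × 100 with ULN = 40 IU/L by default (the ULN is
configurable; no value was stated). FIB-4 = age × AST/(platelets × √ALT) —
the established form with √ALT in the denominator; a printed variant with
"× √ALT" is a typographical error and is not replicated (the standard form
is also the one consistent with hand-checked values). NFS is the published
affine form; BARD uses strict inequalities (BMI > 28 → 1, AST/ALT > 0.8 →
2, T2D → 1) as printed. Scores are used only as continuous ROC
comparators; no risk-category thresholding.

## Problem sizes in the shipped checks

The test suite and the results script use scaled problem sizes chosen as
adequate for their statistical purpose: 20 independent cohorts × 10 splits
for the separability/relevance battery, 3 splits for the leakage check, 50
splits per contrast and 15 per elimination step in
`scripts/acceptance.py`. All randomness is seed-derived; identical seeds
reproduce every artifact byte-for-byte.

## Known limitations

* One prototype per class: heterogeneous contrast arms (e.g. F0–F3 pooled
  against F4) are represented by a single mixture mean, which can cost
  accuracy when the arm is multimodal.
* Identity φ optimises margin, not error rate; a separable training set
  may still end with isolated misclassifications if that lowers the total
  cost.
* Relevance is a property of the learned metric, not a causal effect
  estimate; correlated informative features can share or concentrate
  relevance arbitrarily.
* The percentile CI reflects split-resampling variability on one cohort,
  not sampling variability of the cohort itself.
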