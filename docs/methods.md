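# Methods

## Problem

After cataract surgery an eye's residual refraction depends on the power of
the implanted intraocular lens (IOL). Choosing that power from preoperative
biometry is the core prediction problem of cataract surgery. This package
implements a machine-learning approach: instead of a closed-form power
formula, it *learns* the mapping from biometry to the lens power that would
have left each eye emmetropic, using the surgical record itself as
supervision, and evaluates the learned models against the clinic's
formula-based choices with the standard refractive prediction-error
statistics.

## Vergence optics and target engineering

The optical core is a thin-lens pseudophakic vergence model. With mean
keratometry `K` (D), axial length `AL` (mm), effective lens position `ELP`
(mm), IOL power (D) and vertex distance `V` (mm), the residual refraction
at the spectacle plane is obtained by propagating vergence back from the
retina:

    V3   = 1336 / (AL − ELP)
    1/V1 = ELP/1336 + 1/(V3 − IOL)
    Rx   = 1 / ( V/1000 − 1/(K − V1) )

1336 is the reduced intraocular refractive index × 1000. The implementation
uses the algebraically equivalent form `Rx = (K−V1)/((V/1000)(K−V1) − 1)`,
which is continuous through the emmetropic point `K = V1` (where the naive
form divides by zero although the refraction is simply 0). Positive `Rx`
denotes a hyperopic residual.

`ELP` is predicted by the SRK/T chain (corneal radius `r = 337.5/K`,
corrected axial length with the long-eye polynomial above 24.2 mm, corneal
width and height, `ACDconst = 0.62467·A − 68.747`, offset `−3.336`), with
the corneal-height square-root argument clamped at zero for the
steep-cornea degeneracy, as common SRK/T implementations do. The SRK/T
emmetropic power formula (with `na = 1.336`, `nc = 1.333`, retina-corrected
optical length) provides the simulated clinic's lens choice.

From each surgical record the *ideal* lens power is engineered in three
steps: the per-eye sensitivity `Rx_05IOL = Rx(IOL) − Rx(IOL+0.5)`
(≈ 0.35 D per half-diopter for the average eye, reproducing the familiar
"1 D of IOL ≈ 0.7 D at the spectacle plane" rule), then

    IOL_Ideal   = IOL_implanted + (Rx_post / Rx_05IOL) · 0.5
    Rx_predicted = ((IOL_implanted − IOL_predicted)/0.5) · Rx_05IOL + Rx_post

`IOL_Ideal` is the training target; `Rx_predicted` back-calculates the
residual a *predicted* power would have produced, and cancels exactly to 0
when the prediction equals the ideal power — the round-trip identity the
test suite asserts to 1e−9 D. Because `Rx` is a Möbius function of IOL
power, the half-diopter secant slightly linearizes it; the curvature over
the population is below 0.02 D per D², so an engineered target differs from
the exactly-emmetropizing power by under ~0.01 D at commercial 0.5 D
rounding (and is exact when the implanted power already equals the
required power).

Two modeling choices are deliberately conservative: the vergence formula
uses the measured `AL` (not the retina-corrected length SRK/T uses
internally), which leaves a formula gap of up to ~0.3 D in short eyes and
~0.03 D on average; and a single configurable A-constant (default 119.1)
drives the ELP used in target engineering. Vertex distance defaults to the
standard 12 mm phoropter convention and is configurable.

## Cohort pipeline

Filters run in a fixed order — completeness, range bounds (ACD 1–5 mm,
AL 15–40 mm, K 30–60 D, age 18–99 y, implanted power 6–35 D), acuity
consistency (uncorrected no better than corrected; equality allowed, since
excluding clinically common equality would be aberrant — a strict variant
is configurable), post-operative CDVA ≤ 0.3 logMAR, astigmatism ≤ 3 D,
follow-up ≥ 25 days, free-text keyword exclusion (surgical complications,
corneal pathology, prior refractive surgery; the shipped default lists are
configuration, not code), fellow-eye axial-length agreement (> 1 mm
difference excludes both eyes), and finally a single-pass ±3σ rule over
K/ACD/AL/age/Rx_pre/Rx_post with boundary cases retained. The first failing
rule is the recorded reason; filters mark rather than drop, so
retained + excluded always reconstructs the input.

The cleaned cohort is split at case level 70/30 into selection and
verification sets by a seeded uniform draw. All five predictors
(K, ACD, AL, age, Rx_pre) *and* the target are mapped to [−1, 1] by the
selection-set min/max (the `mapminmax` convention); verification cases with
any predictor strictly outside the selection range are cleared before
evaluation, with boundary values retained.

## Models

**SVM-RM** is epsilon-insensitive support vector regression with the
polynomial kernel `(⟨x,x′⟩ + 1)²` and the study's hyperparameters
(ε = 0.0282, box constraint C = 0.0049 on the normalized scale, kernel
scale 1 — the scale was unspecified and defaults to 1, configurable).
The model is fitted on a seeded 70% partition of the selection set via a
standard convex SVR solver; the untouched 30% holdout supplies the reported
MSE. The original Bayesian hyperparameter search is not reproduced; the
published optimum is the default and a plain search utility can be layered
on top.

**MLNN-EM** is a median ensemble of ten networks, each 5 inputs → 5 tanh
units → 1 linear output (36 parameters). Each member draws its own
70:15:15 train/validation/test split and its own Nguyen–Widrow
initialization (input-weight rows scaled to `β = 0.7·H^(1/n)`, biases
spread over [−β, β] with alternating sign) from an independent seeded
stream. Training is exact Levenberg–Marquardt: the analytic Jacobian of the
network, damping divided by 10 on an accepted step and multiplied by 10 on
a rejected one (cap 1e10, at which training stops with the best weights so
far). One epoch is one accepted step. Early stopping halts after 20
consecutive epochs without a strict validation-MSE decrease (the reading of
"failed to improve or remained the same") and returns the weights at the
validation minimum; `max_epochs` defaults to 1000, far beyond observed
stopping epochs (≈ 5–70). The hidden-layer topology search trains a full
ensemble per candidate size and selects the size minimizing
median + 1·STD of member test MSE, ties toward fewer neurons.

Predictions are denormalized back to diopters; inputs outside the
normalizer's range raise, mirroring the verification-clearing policy.
Whether the ensemble members share one split was unspecified; independent
member splits were chosen as the more natural reading of re-randomizing
each training cycle. Models serialize to a versioned JSON (weights or dual
coefficients, normalizer, config) so training and evaluation are separate
pipeline stages.

## Evaluation

Per-eye signed errors: the clinical baseline's error is the achieved
post-operative refraction (target emmetropia); a model's error is the
back-calculated `Rx_predicted`. Summaries per axial-length subgroup
(SHORT ≤ 22 mm, 22 < MEDIUM < 24 mm, LONG ≥ 24 mm, plus ALL) report mean
signed error, mean/median absolute error, sample STD, extremes, and
percentages within ±0.25/0.50/0.75/1.00 D using closed intervals |e| ≤ t
(configurable to strict).

Paired comparisons: Wilcoxon signed-rank on absolute errors (zeros
dropped; exact tie-aware enumeration of the rank-sum distribution for
n ≤ 25, normal approximation with tie correction beyond, doubled-tail
two-sided p); McNemar with Yates' continuity correction on the
within-threshold indicators, with the numerator clamped at zero when the
discordant counts differ by less than 1; and the exact binomial sign test.
Bonferroni correction uses the number of comparisons in the emitted table
as the family size, reported alongside every adjusted p, since the original
family size was unstated. All three tests are validated against brute-force
enumerations in the suite.

## Synthetic cohort

No patient-level predictors were ever deposited for this study design, so
the pipeline is exercised on a generative model of the study conditions.

*Biometry.* Age (56.89 ± 7.25 y, truncated 36–78), K (43.27 ± 1.40 D,
39.39–47.51), ACD (3.10 ± 0.32 mm, 2.21–4.10) and AL (23.03 ± 0.92 mm,
19.94–26.26) are truncated normals; preoperative refraction is a truncated
skew-normal (mean 1.85 D, SD 1.52 D, bounds −3.88 to 6.63 D, shape +3 —
the reported population is distinctly non-normal and right-skewed). A
Gaussian copula imposes an AL–Rx_pre correlation of −0.40 (long eyes are
myopic; no joint distribution was reported, so this is a modelling choice
flagged as such) and a within-patient correlation of 0.85 for the ~30% of
patients contributing both eyes, with age shared exactly.

*Outcomes.* The clinic implants the SRK/T emmetropic power at the
surgeon's A-constant, rounded to 0.5 D steps (ties toward the lower,
myopic-safe power) and clamped to 6–35 D. The eye's true ELP is the SRK/T
prediction at the true A-constant (119.1) plus N(0, 0.25 mm); the observed
refraction is the vergence-model residual at the true ELP plus
N(0, 0.15 D) measurement noise, quantized to 0.125 D (consistent with
eighth-diopter refraction records). The surgeon constant defaults to
119.54: the 0.44 offset is a calibration — chosen once from the forward
model's sensitivity (≈ 1.4 D of power per A unit, ≈ 0.69 D of refraction
per diopter of power) — that places the clinical baseline's mean error
near −0.46 D and its ±0.50 D rate near 58%, the regime the study's
baseline occupied; likewise the noise defaults follow a variance budget
reproducing a baseline error STD ≈ 0.43 D. These are calibrations of the
simulation's *conditions*, not empirical claims about any clinic.

Ground truth (true ELP, the exactly-emmetropizing power from the
closed-form inversion of the vergence model, the noise-free outcome) is
emitted separately and never visible to models. The generator does not
model device error structure, toric outcomes, per-surgeon effects, or a
phakic-eye optical model for Rx_pre (its only pipeline role is as a
predictor, so marginal + correlation fidelity suffices). Passing tests on
this cohort demonstrate that the pipeline recovers what its own forward
model encodes — not that the models would achieve these accuracies on real
eyes.

## Determinism and problem sizes

All randomness flows from one master seed through named substreams
(synthetic, split, svm, mlnn member i), so a saved config reproduces a run
bit-for-bit. The default end-to-end run uses the full 2,194-eye cohort and
completes in seconds; tests use 50–10,000-eye cohorts chosen per check
(large where a distributional property needs resolution, small where the
check is structural). The full 1–350 topology sweep is implemented but
exercised on small ranges in the suite, a full sweep being a cost, not a
correctness, question.

## Known limitations

- The vergence model is thin-lens and spherical-equivalent only; no
  toric/cylinder modelling, no thick-lens or ray-tracing optics, and no ELP
  formulas beyond SRK/T.
- The clinical baseline's miscalibration is modelled solely as an
  A-constant offset; real clinics mix surgeon adjustment and lens-model
  effects the generator does not represent.
- The published study's exact selection/verification membership and trained
  weights are unrecoverable; only the published split *fraction* and
  hyperparameters are honored, so verification counts differ from the
  published 1,539/655 at the published 70/30 ratio.
- With the study's tiny box constraint the SVR underfits curvature in the
  synthetic cohort slightly more than the network ensemble does; both
  nevertheless reach normalized MSE of order 3e−3, the regime the study
  reports.
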