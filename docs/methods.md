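# Methods

This note documents the models, defaults, and design choices behind the
package: what is simulated and why, which quantities are exact, and what the
synthetic results do and do not say about real patients.

## The battery and its rubric

The battery has three drawing tasks — a wireframe cube copy, two overlapping
figure-eight curves, and a clock face showing ten minutes past five — scored
all-or-nothing at 2, 1, and 5 points respectively (total 0–8). The rubric's
arithmetic has a sharp consequence used as a test: the total 4 is
unreachable, so the score support is {0, 1, 2, 3, 5, 6, 7, 8}.

Screening uses a cut-off t: positive (suspected impairment) iff total ≤ t.
The default t = 7 makes only a perfect battery screen negative. The
alternative strict reading (positive iff total < t) is selectable via
`ScreenPolicy(inclusive=False)`; the inclusive reading is the default
because it is the interpretation consistent with a highly sensitive
screening cut at "7 out of 8".

## Drawing representation and preprocessing

Drawings are ordered pen strokes (x, y, t) on a fixed canvas, origin
top-left, y down. Timestamps are carried through serialization but ignored
by classification: the battery scores static drawings. Rasterization draws
strokes as connected round-capped segments (Pillow); preprocessing crops the
ink bounding box, rescales it aspect-preserving into a square grid with a
10% margin, and normalizes intensities to [0, 1], ink-high. Defaults:
96×96 output, 2 px strokes on a 256×256 canvas — small enough for CPU
training, thick enough to survive the downsampling. Preprocessed output is
translation-invariant (to within a pixel) by construction, which a property
test checks.

## Synthetic drawings and the correctness rubric

No drawing corpus ships with the package; generators produce labeled
drawings from canonical templates with parametric distortions:

- **vertex jitter** (px): Gaussian displacement of template control points —
  cube vertices (shared across incident edges so corners stay attached),
  lemniscate centers/scales, clock numerals and hand angles;
- **stroke drop** (probability per stroke);
- **wobble** (px amplitude, cycles/stroke): sinusoidal tremor perpendicular
  to the stroke direction, tapered so endpoints stay pinned;
- **closure gap** (px): arc length trimmed from closed curves;
- **clock-specific errors**: a missing hand, hands at a wrong time, and
  0–12 numerals removed or relocated.

Ground-truth correctness is defined by generator-side geometric checks with
documented thresholds (module constants in `roca.synth`): the cube needs all
12 edges with endpoints within 10 px of their canonical vertices; the
infinities must be two closed curves (endpoint gap ≤ 6 px) whose point sets
intersect; the clock needs a closed round face (radial coefficient of
variation ≤ 0.15), all 12 numerals within 15° of their 30°-spaced slots,
and both hands within 20° of the ten-past-five configuration. Clock
correctness is all-or-nothing, matching the single 5-point award.

Labeled datasets draw "correct" examples from a mild-tremor distortion and
"incorrect" examples from per-task failure modes far from the rubric
thresholds; a candidate whose rubric verdict disagrees with its intended
label is re-drawn (fresh sub-seed), so labels are sound by construction.
Two empirical properties are tested: label soundness on every generated
dataset, and monotonicity of the rubric pass rate in jitter and drop
probability.

What the generator does **not** emulate: real handwriting style, pressure
and speed dynamics, device heterogeneity, and the drawing phenotypes of
specific dementia etiologies. Classifier accuracy on these drawings
therefore demonstrates that the pipeline (rasterize → preprocess → CNN →
condense → score) works end-to-end and is learnable at desk scale; it says
nothing about accuracy on patient drawings.

## The classifier

A squeeze-and-expand CNN: 3×3 stride-2 stem convolution (16 channels),
max-pool, then fire modules — 1×1 squeeze followed by parallel 1×1 and 3×3
expand convolutions concatenated along channels, each squeeze narrower than
its combined expands — with 2×2 pooling after the first two, a 1×1
convolution to one channel per class, global average pooling, and softmax.
Default stack: fire specs (8,16,16), (16,32,32), (16,32,32) on 96×96 input;
six classes (task × correct/incorrect). Deeper or wider stacks are
expressible through `NetConfig`.

Forward and backward passes are written directly in numpy (k² strided
tensor contractions for convolutions; max-pool backward splits gradient
evenly across tied maxima, zero-padding any odd trailing row/col). The full
parameter gradient is verified against central finite differences in the
test suite. Training is seeded mini-batch Adam on cross-entropy with a
held-out validation split; defaults epochs 40, batch 32, learning rate
2e-3, validation fraction 0.2 — the configuration used for the package's
desk-scale experiment (600 drawings, ~3 minutes on one CPU, held-out
condensed accuracy ≥ 0.9). Everything is deterministic given the seeds; the
training report carries a `nondeterminism_flags` list that stays empty on
platforms with deterministic numpy reductions.

Training starts from scratch by default. A transfer-learning hook
(`TrainSpec.pretrained_source`) accepts an externally supplied checkpoint
with a matching class inventory; no weight download is required or
attempted.

Condensation maps each class name to correct/incorrect by its suffix — a
total, deterministic mapping. Drawing-level evaluation treats *incorrect
drawing* as the positive class (the classifier's job is to flag errors).

## Simulated cohorts

Patients are simulated as: status ~ Bernoulli(prevalence), per-task
incorrectness ~ independent Bernoulli given status, score via the rubric,
demographics from categorical/normal marginals. Defaults: prevalence 17/46;
failure probabilities (intact, impaired) of cube (0.05, 0.40), infinity
(0.10, 0.45), clock (0.08, 0.60) — a clearly but imperfectly separating
battery (closed-form AUC ≈ 0.88) chosen once as a realistic screening
regime; demographic marginals follow a 46-patient clinic cohort (52%
female, 78% secondary education, 63% employed, 76% ACE-3). Conditional
independence of task failures given status is the simplest structure
consistent with the validation design, which uses no inter-task
correlation. The alternative 16/46 prevalence reading is selectable.

Covariates carry no effect on the score by default, so the specificity of
the regression analyses is testable; effects are injected explicitly:
`with_status_effect(spec, d)` shifts each task's impaired failure
probability by d/8 so the expected score gap is exactly d points, and
`age_impairment_interaction=c` adds c per standard deviation of age to
impaired patients' failure probabilities (true score-on-age interaction
slope −8c/15 points per year, exact while probabilities stay inside [0,1]).

`closed_form_performance` is the package's exact oracle: it enumerates the
2³ correctness patterns per status, multiplies probabilities across tasks,
and derives sensitivity/specificity/accuracy/PPV/NPV at any cut plus the
AUC as the concordance P(score_imp < score_int) + ½·P(tie). Monte-Carlo
estimates are tested to converge to it within 3 binomial standard errors at
n = 10,000.

## Statistics

**Chance model.** The random classifier selects class i with probability
q_i independent of the input; against priors p_j the confusion cells are
q_i·p_j. Algebraic consequences (all tested): cells sum to 1; chance NPV
equals the negative-class prior for any non-degenerate q (the q in numerator
and denominator cancels); chance accuracy is ½ for uniform binary q at any
prior, and 1/K in the K-class case. Selection probabilities default to
uniform; an empirical-prior option exists for multiclass drawing baselines.

**ROC and Youden.** One ROC point per achievable threshold (all distinct
scores plus a strict sentinel), low score = positive by default. AUC is the
trapezoid over the step curve, which equals the Mann–Whitney concordance
with ties counted ½; an independent concordance implementation and scipy's
U statistic verify this to 1e-12 on random instances. The Youden threshold
maximizes J = sensitivity + specificity − 1, ties broken toward the
strictest achievable threshold.

**Bootstrap.** Percentile intervals (not BCa — nothing in the validation
design requires more), resampling patients with replacement at the original
n; drawings are the resampling unit only for drawing-level accuracy.
Resamples on which a statistic is undefined (e.g. single-status) are
redrawn and counted. The p-value against chance is the fraction of
resampled statistics at or below the chance value (≤, conservative); when
the count is zero it is reported as "< 1/n_boot". Nested simulation checks
~95% coverage of the 95% interval for a mean at n = 200.

**Threshold sweep.** Metrics and percentile CIs at every cut 0..8;
undefined metric values within a resample are excluded from that metric's
percentiles (count reported) so extreme cuts complete. The
screening-optimal threshold maximizes sensitivity + NPV over cuts where
both are defined, ties toward the strictest cut — a deliberate package
choice, since "jointly maximal" needs a tie rule and sensitivity and NPV
are the two quantities a screening examination optimizes.

**Sample size.** Hanley–McNeil variance
V(A, n₁, n₂) = [A(1−A) + (n₁−1)(Q₁−A²) + (n₂−1)(Q₂−A²)]/(n₁n₂) with
Q₁ = A/(2−A), Q₂ = 2A²/(1+A). The required equal group size is the smallest
n with A − 0.5 ≥ z_α·√V₀(n) + z_power·√V_A(n), V₀ evaluated at A = 0.5.
Defaults: one-sided α = 0.05, power 0.8, both exposed. Under these defaults
the formula gives 25 per group at A = 0.70 and 6 per group at A = 0.90;
published applications of the formula sometimes quote smaller figures
without stating α or sidedness, and no parameter setting is tuned here to
match any particular quoted figure.

**Regressions.** OLS (statsmodels) of score on age plus indicator-coded
categoricals with the most frequent level as reference; the interaction
analysis regresses score on {covariate, status, covariate × status}, once
per covariate, with no multiplicity adjustment (matching the validation
design it mirrors). Rank-deficient designs raise an error naming the
collinear terms (identified from the SVD null space); a constant outcome
returns zero slopes with R² flagged undefined. Age is not centered.
Coefficients are verified against a brute-force normal-equations solve.

## Reproducibility and problem sizes

Every random operation takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `SeedSequence`, and rerunning a
configuration reproduces every artifact byte-for-byte. The package's
standard experiment sizes — 600 training drawings, 120 held-out drawings,
simulated cohorts of 46 (headline) and 10,000 (oracle-convergence), 500
outer replications for bootstrap-coverage checks — were chosen as the
smallest sizes at which the respective checks are statistically meaningful,
and are what the test suite and `scripts/acceptance.py` run.

## Known limitations

- Synthetic drawings are geometric caricatures; no claim transfers to
  patient drawings without real data.
- Task failures are conditionally independent given status; real batteries
  show correlated failures, which would change metric variances (though not
  the closed-form machinery, which could be extended with a copula).
- The score is discrete with eight reachable values, so the ROC has few
  operating points and the Youden maximizer can be non-unique (hence the
  explicit tie rule).
- The CNN engine is plain numpy: fine at 96×96 and desk scale, not meant
  for large images or datasets.
- Percentile bootstrap intervals undercover slightly at small n; the
  coverage test quantifies this at n = 200.
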