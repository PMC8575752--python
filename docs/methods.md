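# Methods

This note documents the models behind `ivuscal`, the calibrated
constants and why they take the values they do, and the limits of what
the synthetic experiments demonstrate.

## 1. Pullback geometry and eligibility

A pullback is a polar intensity grid `frames[frame][aline][sample]`
(8-bit).  Imaged length is `n_frames / frame_rate × pullback_speed`;
with the defaults (30 frames/s, 0.5 mm/s) a 40 mm pullback is exactly
2400 frames.  Frame rate (30 f/s) and the 256 × 512 polar grid are
defaults typical of 40 MHz mechanically rotating catheters; they are
configurable because acquisition systems differ.  Eligibility is
length ≥ 40 mm — boundary inclusive — with none of the three operator
flags (stent struts, poor quality, false lumen) set; among several
eligible pullbacks per patient the longest wins, ties broken by input
order.  Indices are 0-based; frame 0 is the distal-most frame.

The native format is a multi-frame grayscale TIFF (row = A-line,
column = radial sample) plus a JSON sidecar, chosen over DICOM because
vendor IVUS DICOM layouts are proprietary; DICOM support is limited to
grayscale frame extraction.

## 2. The phantom

Envelope-detected ultrasound speckle is Rayleigh distributed, so every
voxel starts as a Rayleigh(σ = 25) draw, multiplied by 3 inside the
wall band (lumen radius 160 samples, wall 96 samples by default).  A
calcium deposit occupies a frame interval × circumferential A-line arc
(wrapping modulo the A-line count) at a leading-edge depth inside the
wall.  On covered A-lines the profile ramps linearly to intensity 250
over 2 samples at the interface and everything distal is multiplied by
0.15 — the simplest rendering consistent with the defining "sharp
white border + dark distal shadow" appearance.  Shadowing extends to
the end of the A-line (no distal recovery).  Overlapping deposits
merge with the shallowest interface winning.  The mask is true exactly
on covered (frame, A-line) cells, so `ground_truth_ics` of a deposit
list and `compute_ics` of the rendered mask agree by construction
(union semantics; an invariant asserted in the tests).

Deposit populations are Poisson in number (mean 6 per pullback) with
log-normal arc widths (median 32 A-lines) and axial lengths (median 12
frames).  No public characterization of annotated calcium-arc sizes
exists; these values were chosen once so that a typical phantom has a
low-double-digit percentage of positive A-lines — scores on the scale
of clinical pullbacks (the example pullback in the README scores 106).
The guide-wire artifact, NURD, side lobes, and blood-speckle dynamics
are deliberately not simulated: they would make labels ambiguous
without changing what the detector tests demonstrate.

## 3. Per-A-line detection

Five features operationalize the calcium signature (the original
detector's feature set is not published, so this one is designed from
the definition itself): peak intensity beyond the 16-sample ring-down
zone, maximum 2-sample rise (edge sharpness), distal/proximal mean
intensity ratio around the peak (shadow ratio, denominator floored at
1), fraction of distal samples below intensity 30 (dark fraction), and
peak depth.  Classification is strictly per A-line — no neighborhood
smoothing — because the score itself is defined per A-line.

The SVM is a soft-margin RBF machine with class weights inversely
proportional to class frequency; C ∈ {1, 10} and γ ∈ {scale, 0.1} are
picked by seeded 5-fold cross-validation (F1 objective) on a
stratified subsample of at most 12 000 A-lines — an RBF SVM needs far
fewer rows than the ~500k A-lines of a 20-pullback training set, and
the subsample size only has to be large enough that the margin is
stable.  The fitted solution (standardization, support vectors, dual
coefficients, intercept, γ) is serialized to JSON and prediction is
computed directly from it, so a round-tripped model reproduces
decisions bit-for-bit.

The rule-based detector thresholds the same features (peak ≥ 200,
sharpness ≥ 25, shadow ratio ≤ 0.35).  On noise-free renders both
detectors reproduce the ground truth exactly — the oracle-equivalence
property used throughout the tests.  Undefined precision/recall (zero
denominators) are reported as NaN with an explicit flag, never
silently 0 or 1.

On default (noisy) phantoms the held-out per-A-line metrics are
essentially perfect, comfortably above the 0.89 / 0.92 / 0.85
accuracy/precision/recall reported for the original detector on real
annotated pullbacks.  That gap is informative: the phantom's
calcium signature is cleaner than clinical imaging, so these numbers
validate the pipeline, not clinical performance.

## 4. Scoring

`compute_ics` counts positive cells over all (frame, A-line) cells;
every A-line of every frame counts (no frame sub-sampling).  The score
is kept real-valued; display rounding is one decimal.  Dichotomization
sends ties to the high group ("high" is defined as ICS ≥ cutoff,
default 85); the even-n median is the midpoint of the central order
statistics.

## 5. The synthetic cohort

Covariates are drawn independently at their registry prevalences
(age ~ N(65.7, 11.1²) clipped to [30, 95]; binary prevalences such as
hypertension 63.7%, diabetes 20.6%, previous stroke 5.4%), except eGFR
which is negatively linked to age (eGFR = 145 − age + N(0, 17²),
clipped), reproducing both its median (~79 ml/min) and spread.  Only
marginals are published, so no further joint structure is identified —
a deliberate simplification documented here rather than guessed.

**√ICS model.**  √ICS = 4.4825 + 0.07·age + 2.46·stroke + ε,
ε ~ N(0, 5.87²), clipped to [0, √1000]; ICS = (√ICS)².  The age and
stroke coefficients are the structural effects; all other covariates
have zero coefficient (they showed no independent association).  The
intercept and noise SD are calibrated (400k-draw simulation, bisection
on the intercept) so the population median ICS is 85.0 (median √ICS
9.22) and the quartiles fall near 27/175, close to the clinical 25/169;
about 6% of patients clip at 0, matching a score range that reaches 0.
Clipping attenuates the fitted age coefficient slightly (recovered mean
≈ 0.066–0.068 across replicates, still centered on 0.07 within
tolerance).

**Events.**  Four competing causes (death, stroke, MI,
revascularization) have exponential cause-specific hazards
λ_c = B·f_c·exp(η), with cause fractions f_c proportional to the
published per-endpoint 6-year event counts (68/14/31/80).  The linear
predictor η carries the ICS effect — log 1.51 for the high group
(threshold scenario) or log 1.21 per 100 units (continuous scenario) —
plus an age effect of 0.04394 per year.  The age term is structurally
necessary: with a shared group effect of 1.51 alone, incidences of
51.8% (high) and 36.4% (low) at 2191 days are unattainable, because on
the cumulative-incidence scale that split implies a marginal contrast
of ~1.61; the confounding pathway ICS←age→hazard supplies the
difference, exactly as adjusted-vs-unadjusted contrasts differ in the
clinical data.  B and the age effect were solved jointly
(`scipy.optimize.fsolve` on a 400k-patient simulated population) to
hit both group incidences; the continuous-scenario baseline was solved
the same way against the overall 44.4%.  All four causes share the
POCE-level effect so the composite hazard stays exactly proportional;
per-cause effects are not separately enforced (they are too noisy to
calibrate from printed counts).  The target-vessel flag is drawn
conditionally (P = 0.525 for revascularization, 0.645 for MI); in the
continuous scenario the revascularization flag probability rises with
ICS such that the target-vessel-revascularization cause-specific
hazard carries HR 1.37 per 100 units while any-revascularization keeps
the composite effect.

Censoring is the minimum of exponential loss to follow-up (rate
1/12000 per day, so ~17% are lost before 6 years) and administrative
censoring at 2191 days; the observed record is the first event among
all causes and censoring — exactly one row per patient.

## 6. The analysis stack

Numerics delegate to lifelines (KM, log-rank, Aalen–Johansen, Cox with
Efron ties, Schoenfeld tests) and statsmodels (OLS; Breslow-ties Cox via
PHReg), behind interfaces that own the cause-specific bookkeeping:
competing causes censor at their event time, endpoint indicators may
require the target-vessel flag, and the all-cause incidence of a cause
set is the sum of its Aalen–Johansen curves (which reduces to 1 − KM
exactly for a composite covering all causes, and for a single cause
with no competitors).  The Cox Newton iteration runs to precision
1e-11 so the partial-likelihood gradient at the reported optimum
vanishes to < 1e-6 — asserted against a hand-written no-ties partial
likelihood.  Efron is the default tie method (better calibrated than
Breslow under ties; the two agree exactly without ties, also asserted);
confidence intervals are Wald on the log-hazard scale.

`analyze_cohort` emits, per endpoint (POCE, any/target-vessel
revascularization, any/target-vessel MI, stroke, all-cause mortality):
event counts, 6-year cumulative incidence overall and by ICS group, and
two cause-specific Cox models (group indicator; ICS per 100 units),
adjusted for {age, diabetes, eGFR, ACS presentation, previous CABG} —
a configurable default, since the original adjustment sets per endpoint
are not published — with the POCE models stratified on diabetes
(separate baseline per stratum).  Endpoints with fewer than 15 events
fall back to univariate models with an explicit note, mirroring how
sparse endpoints are handled clinically.  Because only the first event
per patient exists in the generated data, secondary-endpoint analyses
treat other first events as competing risks.  The √ICS model building
fits each candidate univariately and includes those with p strictly
below 0.1 in one joint OLS fit, logging every univariate p.

No confidence intervals are attached to cumulative incidences (no
method for them is fixed by the design being emulated).

## 7. Replication experiment sizes

The packaged experiments (`ivuscal.benchmarks`, run by
`scripts/acceptance.py` and the acceptance tests) use: 20 training +
10 held-out pullbacks of 100 × 256 × 512 for detection; 50 cohorts for
the ICS distribution; 200 cohorts for incidence calibration, hazard
ratio recovery (per scenario), and the age coefficient.  These sizes
put Monte-Carlo error well inside the comparison tolerances (e.g. the
SE of the mean recovered log-HR over 200 replicates is ~0.01) while
keeping the full run at a couple of minutes on one CPU.

## 8. What passing does and does not show

The phantom and cohort generators are emulations: passing their tests
shows the detector, score, and statistical machinery are correct and
well calibrated **under the stated models** — Rayleigh speckle,
idealized calcium rendering, independent covariates, constant hazards,
exponential censoring.  It does not validate clinical detection
performance (real speckle, reverberation, and annotation ambiguity are
harder), nor the clinical effect estimates themselves, and constant
cause-specific hazards mean the generated incidence curves have
exponential shape rather than the shape of the clinical curves.
Known further limitations: no guide-wire artifact; no modeling of
treatment assignment as a hazard modifier; revascularization status
does not modify hazards, so subgroup analyses by vessel
revascularization are qualitative only.
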