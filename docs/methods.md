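# Methods

This note documents the models implemented in `iscee`, the choices made where
the design was genuinely open, and what the synthetic cohort does and does
not establish about behavior on real recordings.

## Signals, units, preprocessing

Canonical units are acceleration in g, angular velocity in deg/s, altitude in
m, energy expenditure (EE) in kcal/day, and time in seconds from session
start. EE supplied per minute is converted (×1440) at ingest. Eight sensor
sites are modeled: both wrists, both ankles, both feet, chest, hip.

Acceleration is high-pass filtered with a 2nd-order Butterworth at 0.25 Hz
(gravity removal); altitude is low-pass filtered at 0.2 Hz (barometric noise
suppression). Filtering is zero-phase (forward–backward `sosfiltfilt`):
analysis is offline, so there is no reason to accept group delay; the
effective magnitude response is the square of the one-pass response, which the
filter tests check analytically. The gyroscope is used unfiltered — only
acceleration and altitude filters are part of the procedure. Streams are
aligned onto a common clock by linear interpolation over the intersection of
time supports, never extrapolating. The default analysis rate is 50 Hz; the
features used are low-frequency, so recordings at 200 Hz are downsampled at
ingest.

Each activity bout is cut into non-overlapping 60-s windows covering minutes
[4, 8) of the bout, so oxygen-uptake kinetics have settled before the first
window; resting EE (REE) measurements average minutes [14, 18) of a supine
rest. Windows are gated before model fitting: a kept window is complete
(all expected sites present), steady-state, and carries a measured EE. The
steady-state criterion — which replaces a manual visual check with a
reproducible rule — is: coefficient of variation of the within-window EE
samples < 15 % and window mean within 20 % of the following window's mean;
both thresholds are configurable, and manual override flags are honored.

## Feature bank

Statistical features follow the grammar `STAT(signal_location)` with
`STAT ∈ {MEAN, MEDIAN, SD, VAR, RMS, IQR, PERC_p (p ∈ {1,3,5,25,75,95,99}),
AC}`, signals `a_M` (high-passed acceleration magnitude), `ω_M`
(angular-velocity magnitude), `ω_Z` (ankle sagittal angular velocity), `H`
(low-passed altitude), and dominance-relative locations resolved from
handedness (DW/NDW wrists, DA/NDA ankles, DF/NDF feet, Ch chest, Hi hip).
SD/VAR use the n−1 denominator; quantiles interpolate linearly between order
statistics. The default bank holds 382 named features: 14 statistics × 3 signals at all
8 sites plus a 4th signal (`ω_Z`) at both ankles (364 statistical features),
12 high-level features, 5 demographics and REE; clinical scores add further
columns. The exact
composition of the original study's 351-feature bank is not published in its
main text, so the bank here covers every published feature name and is
extensible; models only ever address features by name.

Open definitions resolved as follows:

* **Activity counts (AC)** — no published formula; defined as the time
  integral of the rectified high-pass-filtered acceleration magnitude
  (units g·s). It is device-independent, linear in amplitude, zero for no
  movement.
* **Laterality index** — symmetric ratio
  (AC_dom − AC_nondom)/(AC_dom + AC_nondom) ∈ [−1, 1], 0 when both sides are
  zero; the upper-vs-lower variant compares summed wrist AC against summed
  ankle AC.
* **Step detection** — local maxima of the 5 Hz-low-passed ankle sagittal
  angular velocity with height ≥ max(20 deg/s, 0.3 × window 95th percentile)
  and ≥ 0.3 s inter-peak gap; one peak = one step of that leg. The
  thresholds are package decisions validated against the simulator's
  ground-truth event lists (sensitivity and PPV ≥ 99 % at zero sensor
  noise) and are configurable.
* **Step length** — "static method": 0.415 × height (men), 0.413 × height
  (women).
* **Stride-time variance** — sample variance of successive same-leg
  inter-step intervals pooled over legs; legs with < 3 steps contribute
  nothing, and fewer than 2 intervals in total yields NaN (an explicit
  missing marker — models reject rows with missing selected features rather
  than imputing).
* **Cross-correlation** — maximum normalized cross-correlation of the
  mean-removed left/right acceleration magnitudes over lags within ±1 s;
  zero-variance input gives 0 by convention.

## Resting EE

Five prediction equations are shipped as a versioned JSON coefficient table
with a provenance string per equation: Harris–Benedict (1919, rounded form),
updated Harris–Benedict (Roza–Shizgal 1984; the package default), Mifflin–St
Jeor (1990), and the Müller (2004) whole-sample equation (MJ/day, converted
at 239.006 kcal/MJ). The BMI-class-specific Müller variant requires
coefficients that are only available in its primary source; it ships
unconfigured and raises an explicit error unless the user supplies the class
table — transcribing uncertain coefficients from memory was judged worse
than refusing.

## Activity classification

A kNN gate with k = 10 and squared-inverse-distance voting over five
features: `PERC_95(ω_Z_DA)`, `IQR(ω_Z_DA)`, `PERC_99(ω_M_Ch)`,
`PERC_25(ω_M_NDW)`, `SD(H_NDW)`. Features are standardized per training fold
(the source description is silent on scaling; the features span deg/s and
meters, so unscaled Euclidean distance would be dominated by one unit —
standardization is the default and accuracy is then scale-invariant).
Zero-distance neighbors decide by majority among themselves; ties break by
the fixed class order sedentary < low-intensity < high-intensity < walking.
Evaluation is leave-one-subject-out (LOSO): one fold per subject, pooled
confusion matrix. `classify` is verified exactly against a brute-force kNN
oracle on random instances up to 200 rows.

## EE regression

**Relative-error MLR.** `EE = β0 + Σ βi·Fi` with coefficients minimizing
Σ_j ((pred_j − y_j)/y_j)². Dividing the design and target by y_j turns this
into ordinary least squares against a vector of ones — i.e. weighted least
squares with weights 1/y_j² — solved by `numpy.linalg.lstsq` with an explicit
rank check (collinear features are named in the error). The closed form is
verified against a derivative-free Nelder–Mead minimizer (objective agreement
to 1e-6 relative) and recovers generating coefficients to 2 % under 5 %
multiplicative noise at n = 500. Features enter raw (unstandardized), so
coefficients stay interpretable. Predictions are affine and never clipped;
negative estimates are reported as-is.

**ANN ensemble.** Single hidden layer of logistic-sigmoid units (3–6 per
preset; logistic chosen over tanh, configurable), linear output, trained by a
hand-written Levenberg–Marquardt loop on standardized inputs/targets:
analytic Jacobian, μ adaptation (×10 on rejection, ÷10 on acceptance).
Each net draws its own random 70/30 train/validation split and Nguyen–Widrow
initial weights; training stops at 500 epochs, when the error-gradient
infinity norm drops below 1e-6, or when validation error rises six times in a
row (the best-validation weights are kept — early-stopping semantics, also
used for non-convergent fits). The ensemble (default 100 nets, configurable
down to a handful for quick runs) predicts the mean over nets. A master seed
fans out per-net seeds through `numpy` `SeedSequence.spawn`, so results are
bit-reproducible.

**Architectures.** *Direct*: one regressor on its published feature set.
*Class-conditional*: four regressors, each trained only on windows of its
true class, routed at prediction time either by the true label (the
perfect-classification scenario) or by the kNN gate. Misrouted windows are
deliberately predicted by the wrong class model — no silent correction.
The published per-model feature sets are shipped as fixed named presets; the
selection search that produced them is not reimplemented (it was never
described), though an exploratory greedy forward-selection utility exists,
clearly marked as not part of the published procedure.

## Evaluation statistics

Per-window percent error is (pred − meas)/meas × 100. MAE and mean signed
error (MSE — a bias, not a squared error) are averaged within subject first
and reported mean ± SD across subjects, so subjects with more surviving
windows do not dominate; per-window pooling is available behind a flag.
Bland–Altman agreement uses bias ± 1.96·SD(differences, n−1). Equivalence is
a paired TOST with zone ±10 % of the mean measured EE: two one-sided paired
t-tests against the zone bounds, equivalent iff both p < α = 0.05; with
degenerate variance the mean difference is compared to the zone directly.
The TOST implementation's rejection rate matches the analytic power
approximation in Monte-Carlo tests, and shrinking the zone is verified to be
monotone. MET conversion uses 1 MET = 3.5 mL O₂·kg⁻¹·min⁻¹ and an energy
equivalent of oxygen of 4.86 kcal/L (RER-neutral; configurable — calorimeter
software applies proprietary conversions, so the constant is explicit here).

## Guideline translation

Each walking speed (1–6 km/h, plus cohort averages) carries a profile:
energy cost of 30 min of walking above rest (kcal), cadence (steps/min),
resting EE and measured daily EE (kcal/day). Minutes to reach an energy
target are `target / cost_per_30min × 30`; step goals are
`minutes × cadence`. Where a profile has no measured 30-min cost (1–2 km/h
and the all-speed average), it derives from the additional daily EE
(measured − resting, divided by 48 half-hours) — the two quantities agree
wherever both were measured. Rounding is half-away-from-zero to integer
minutes/steps, applied once at output. Published step-goal cells were
computed from unrounded cadence/EE intermediates that are not printed, so
they are validated to ±1 %, while minute cells reproduce exactly. One
published additional-EE cell (6 km/h) is internally inconsistent with its own
REE and daily-EE entries (suspected digit transposition); the package
reports the recomputed difference.

## Synthetic cohort

The generator's defaults are the study conditions: 30 subjects, 12
activities (three per class) of 8 min each → 4 windows per bout = 1,440
candidate windows; the dropout probability 140/1440 reproduces the ~90.3 %
retention after quality gating. Subject demographics come from truncated
normals matching the cohort (age 54.1 ± 11.9 in [27, 72], weight 75.5 ± 16.2
in [44, 106], height 1.71 ± 0.09 in [1.48, 1.91], 2:1 male). Measured REE is
the updated Harris–Benedict estimate × (1 + N(0, 0.10)), so the REE-equation
evaluation has a known error level (E|N(0, 0.1)| ≈ 8 % MAE). Activity MET
draws use published class/activity means and SDs (rest 0.9 ± 0.2 through
climbing stairs 7.1 ± 1.7); the EE label converts the drawn MET through the
same constants module as the evaluation code, so MET round-trips are exact
by construction at zero noise. Walking cadence follows the published
speed–cadence table (e.g. 105 steps/min at 4 km/h), realized as anti-phase
per-leg gyro burst trains with 20 ms timing jitter; ground-truth step events
ride along in a sidecar.

Movement amplitude scales with the drawn MET relative to the class's mean
MET, so windows that cost more energy also move more — across activities
within a class, not just within one activity. Two deliberate realism
features shape model comparisons the way real data do: walking arm swing is
mostly a personal trait (amplitude ∝ 0.8 + 0.2×intensity), which degrades
the wrist-heavy *direct* feature set on walking windows; and light
high-intensity activities (weight lifting at MET ≈ 2) produce intermittent,
low-amplitude signals overlapping the low-intensity class, so the classifier
confuses exactly the activities that are confusable in practice and
misrouting carries a moderate, realistic cost.

Signal morphology is deliberately simple — windowed sinusoids, gaussian
swing bursts, white noise over gravity. The simulator does not emulate
sensor clock drift, saturation, soft-tissue artifact, walking aids, or
free-living behavior; passing tests therefore demonstrate that the pipeline
recovers known structure under its own assumptions, not field accuracy on
real iSCI recordings.

## Problem sizes and numerical choices

Test and acceptance runs scale the simulation to keep runs quick while
preserving the properties under test: the classifier and retention checks
use the full 30-subject cohort at the default 50 Hz; the model-ordering
study (class-conditional with true labels ≤ with classifier routing ≤
direct, over 20 seeds) uses 12-subject cohorts at a 25 Hz analysis rate,
which leaves every per-class fit comfortably overdetermined. I/O writes
numbers with 10 significant digits (round-trips agree to ~1e-9); the
missing-value sentinel is NaN and is never silently zero-filled; kNN
tie-breaks and zero-distance handling are fixed as described so repeated
runs are bit-identical.

## Known limitations

* The feature bank's 36/52-per-site composition cannot be matched exactly to
  the original (unpublished supplementary list); the bank is a superset of
  every published feature name.
* The BMI-dependent Müller REE equation is inert without user-supplied
  coefficients.
* ANN results depend on ensemble size; small ensembles (< 20 nets) retain
  noticeable seed-to-seed variance.
* The guideline-translation profiles are measured constants of the original
  cohort; applying them to other populations is an extrapolation.
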