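# Methods

This note documents the models, parameter choices and numerical
decisions behind `eegvrp`, and what the synthetic study does and does
not establish about real infant EEG.

## The VRP statistic

For one session, each channel's Welch PSD over 0–30 Hz is normalized to
a relative-power distribution (rows sum to 1), each channel is
summarized by its *peak* relative power, and VRP is the sample standard
deviation (n−1) of those 32 summaries. Two readings of "per-electrode
relative power measurement" exist in the literature this statistic comes
from — the peak value of the relative-power spectrum, or the value at
the channel's raw-PSD peak frequency. When the normalization band equals
the search band the two coincide, which is the default configuration
here; a `mean` summary mode is also exposed as a diagnostic alternative,
and the mode used is recorded in every `SessionFeature` and features CSV
so the choice is auditable.

Properties that follow directly and are enforced by tests: VRP ≥ 0;
VRP = 0 when all channels have identical spectra; VRP is invariant to
any positive per-channel rescaling of the signal (normalization is
within-channel), and therefore to electrode-gain differences — this is
the property that makes it comparable across sessions and subjects
without amplitude calibration.

## Preprocessing

* **Re-referencing** to the mean of T7/T8. Subtracting a common
  reference is idempotent in effect: once the reference pair averages to
  ~0, further applications change nothing.
* **Bandpass**: the literature specifies only "an IIR bandpass
  0.3–30 Hz". We realize it as a 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`), the conventional choice: zero phase
  keeps spectral estimates undistorted, and the squared magnitude
  response stays maximally flat in-band. Measured gains: <1% at DC,
  within [0.95, 1.05] at 10 Hz, <0.1 at 60 Hz.
* **Epoching**: 2 s non-overlapping epochs, trailing remainder
  discarded. 2 s gives 0.5 Hz spectral resolution, appropriate for a
  0–30 Hz analysis and for sessions of 14–82 s. Epoch length is
  configurable.
* **Rejection**: an epoch is dropped if any channel sample exceeds
  200 µV in absolute value. The rejection criterion in the source
  literature is unstated; an absolute threshold is the simplest rule
  that provably removes the generator's artifact model (below).
  Sessions retaining under 14 s are flagged (and excluded only in strict
  mode), mirroring the shortest sessions analyzed in practice.

Data conservation is exact: retained epochs + rejected epochs +
discarded remainder account for every input sample.

## Spectral estimation

Welch PSD per retained epoch (2 s Hamming segments, 50% overlap —
with 2 s epochs this reduces to one tapered periodogram per epoch),
averaged with equal weight across epochs; frequency spacing 0.5 Hz, 61
bins in [0, 30]. The DC bin participates in normalization but is ~0
after the 0.3 Hz high-pass. Band endpoints are inclusive.

## Synthetic generator

Per channel the signal is

    x(t) = A_c sin(2π f_c t + φ_c)  +  b(t)  +  ε(t),

with `b` Gaussian noise with one-sided density K f^(−α) (α = 1.5,
scaled so its SD is 15 µV; synthesized in the frequency domain so the
periodogram is unbiased for the target density), `ε` white with SD 2 µV,
and one oscillation per channel centered at 6 Hz (infant alpha/theta
range) with amplitude 10 µV. Cross-channel heterogeneity is a single
spread parameter σ_h jittering each channel's `f_c` (Hz) and
`log A_c` by N(0, σ_h²). This is deliberately the simplest spectral
model whose cross-channel heterogeneity maps monotonically onto VRP; it
is a stand-in, not an estimate of any real cohort's spectra.

Artifacts are rectangular common-mode bursts, amplitude 10× the clean
signal SD, 0.5 s long, Poisson arrivals at 2/min — unambiguous for the
absolute-amplitude rejection rule, by design.

Cohort structure (defaults = the study conditions the package targets):
22 TD and 11 AR subjects (AR subtypes in a 6:4:1
preterm-high/preterm-low/fullterm-high mix), visit-1 ages uniform on
[38, 203] d (TD) and [40, 225] d (AR, adjusted), visit 3 at +60 d for 13
TD and 9 AR returnees, session durations uniform on [20, 82] s,
σ_h = 0.2 (TD) vs 0.35 (AR). Groups differ **only** through σ_h by
default, so any classification signal must flow through the statistic
under test; a direct group effect on scores (β_group) is available but
defaults to 0.

Each subject has a latent spectral "trait": visit-wise channel jitters
share a fraction ρ = `visit_stability` = 0.7 of their variance across
visits. Without this, visit-1 VRP would carry no information about
visit-3 outcomes by construction and the future-prediction analysis
would be meaningless.

Developmental scores are linear in age, group and the session's
**ground-truth expected VRP** (computed from the noise-free theoretical
spectrum of the drawn channel profiles on the Welch bin grid) plus
Gaussian noise. Five raw subscales rise with age (slopes 0.05–0.14
points/day); the total raw score is their sum; composites sit on the
mean-100/SD-15 scale clipped to [40, 160]; percentile ranks are the
normal-CDF transform of the composites. β_vrp defaults are negative
(more heterogeneity → lower scores) and sized so the within-group VRP
effect SD is comparable to the score noise SD on the ground-truth
feature. Because the analysis uses the *measured* VRP — whose
within-group correlation with the ground truth is modest at realistic
session lengths — the same-visit and future-visit score effects survive
in only a minority of replicate studies at n = 33, while group
classification (which rides on the large between-group VRP contrast)
is robust across seeds. This is the "preliminary small study" regime
the defaults emulate: a strong group biomarker whose incremental
score-model contribution is borderline at this sample size. With the
ground-truth feature (fast path) or larger β_vrp / lower noise, the
score effects are detected reliably, as the power-simulation tests
verify.

### What the generator does *not* emulate

No volume conduction or head-model forward solution, no sleep-state or
arousal dynamics, no ocular/muscle artifact classes with distinct
spectra, no age-dependent spectral maturation. Passing tests therefore
show the *pipeline* is correct and well calibrated under the stated
statistical structure — not that VRP is a validated biomarker in real
infants.

### Measured vs expected VRP

The rendered-EEG measured VRP is systematically larger than the
ground-truth expected VRP (Welch estimation noise inflates the
cross-channel SD of a max statistic, and taper leakage varies by
channel), and below σ_h ≈ 0.15 this estimation-noise floor dominates, so
mean measured VRP is flat in σ_h there. Monotonicity is therefore
assessed over the generator's operative range σ_h ∈ [0.2, 0.6], where
the per-level mean measured VRP through the full chain is strictly
ordered (Spearman ρ ≈ 1 over 5 levels × 20 seeds, 40 s sessions).
Because scores are generated from the ground truth while the analysis
uses the measured feature, score-model effects are attenuated exactly as
real measurement noise would attenuate them.

## Inference layer

* **Logistic screen**: maximum-likelihood fit of `at_risk ~ VRP`
  (statsmodels), LRT = 2(ℓ_full − ℓ_null) against χ²(1) — df is the
  parameter-count difference, 1 for one added predictor. Odds ratios
  are reported per native VRP unit *and* per SD of the feature, with the
  scale recorded, because VRP's native unit is a few hundredths and the
  per-unit OR is astronomically scaled. A constant feature is reported
  as degenerate (OR 1, p 1). **Complete separation** is detected before
  fitting (a threshold on the feature splits the classes); the fit then
  switches to a bounded-slope ML estimate (|slope·SD| ≤ 20 on the
  standardized scale) with an explicit warning — estimates stay finite,
  the LRT approaches its saturated bound 2n·ln2, and nothing diverges
  silently.
* **LOOCV**: each subject predicted from the other n−1 with the same
  fitting rules; a single-class training fold predicts its class
  frequency (the majority class at threshold 0.5). The 0.5 decision
  threshold is configurable.
* **Linear models**: OLS with intercept. Adjusted
  R² = 1 − (1−R²)(n−1)/(n−p−1). BIC = k ln n − 2ℓ̂ with the Gaussian-MLE
  variance and k counting intercept, slopes *and* the variance
  parameter — the convention of R's `BIC()` for `lm`, verified against R
  to 1e-6 in the test suite (statsmodels' `bic` attribute omits the
  variance parameter and differs by ln n).
* **Nested comparison**: partial
  F = ((RSS₀−RSS₁)/q) / (RSS₁/(n−p₁−1)); identical models give F = 0,
  p = 1; non-nested or different-outcome pairs are rejected. The
  12-outcome same-visit table applies **no** multiple-testing correction
  to the primary p-values (matching common practice in the exploratory
  setting it mirrors) but emits a Holm-adjusted column alongside for
  transparency.
* **Null-model definition**: the baseline is `age + at_risk` by default;
  an age-only null is available via `null_includes_risk=False` /
  `--age-only-null`, since both definitions appear in the exploratory
  literature this pipeline is shaped after.
* **Future-visit prediction**: subjects observed at both visits
  contribute visit-1 age/risk/VRP against the visit-3 outcome (fine
  motor by default); the 2- vs 3-regressor comparison reports Δadjusted
  R² and the partial-F p.

Adjusted age is used as the age regressor throughout, for raw and
composite outcomes alike.

## Calibration results the tests compute

* Type-I error of the nested F-test on VRP under the null generator
  (equal σ_h, β_vrp = 0): within 5% ± 2 points over 1000 replicates at
  n = 33.
* LOOCV with an uninformative feature collapses to the majority class:
  mean accuracy within 5 points of the 22/33 base rate over 200
  replicates; specificity near 1, sensitivity near 0.
* 95% CI coverage of the generating β_age and β_vrp at 200 sessions:
  within 95% ± 5 points over 500 replicates.
* Measured-VRP monotonicity in σ_h as above.

Monte-Carlo replicate counts (1000 / 500 / 200) and session sizes were
chosen so each calibration check resolves its tolerance comfortably;
the inference-layer replicates use the generator's fast path (cohort
table + ground-truth expected VRP, no EEG rendering), while full-chain
properties are checked on rendered EEG.

## Known limitations

* The spectral model is one oscillation + 1/f background per channel;
  real infant EEG has multiple, state-dependent rhythms.
* Expected VRP is computed on the Welch bin grid with the sinusoid's
  power assigned to its nearest bin; it is a ranking-faithful proxy for
  the measured statistic, not an unbiased predictor of its level.
* The separation-bounded logistic slope is a pragmatic device to keep
  reports finite under complete separation, not a principled penalized
  estimator (no Firth correction).
* EDF files can be read (via MNE) but recordings are written as CSV
  matrix + label sidecar; no EDF export.
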