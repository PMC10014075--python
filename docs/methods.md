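# Methods

This note records the models implemented in `loomhab`, the defaults and the
numerical choices, in enough detail to judge what a passing test suite does
and does not establish.

## Stimulus kinematics

Angular size follows the standard looming law θ(t_rel) = 2·arctan((l/|v|)/t_rel),
the only law consistent with a size-to-speed parameterization; virtual
collision is at t_rel = 0 and θ is clipped to [θ_init, θ_final]. Expansion
onset/offset are the closed-form inversions (l/|v|)/tan(θ/2). Two parameter
sets are built in: the behavioral rig (l/|v| = 240 ms, 4→140°, 2.5 s hold,
20 Hz refresh) and the imaging rig (480 ms, 3→80°, 10 s hold, 30 Hz).

Luminance profiles are defined through the rendered dark-pixel fraction on a
flat screen: dark loom = background × (1 − dark fraction); dimming uses the
identical time course with no edge; brightening inverts its polarity;
checkerboard holds the background level (equal-area dark/bright checks on
mid-gray). The disk's angular-to-pixel mapping is linear (px/degree) or
gnomonic (tan(θ/2) × viewing distance), both exposed in `ScreenGeometry`;
the dimming profile is computed in screen-pixel fraction, not solid angle.
Frames are sampled at frame centers, (i + 0.5)/refresh. Because the profile
and the render count the same pixels, their agreement is exact rather than
approximate.

Calcium regressors convolve a per-kind stimulus drive (normalized angular
size for looming kinds, luminance decrease/increase for dimming/brightening)
with a causal exponential kernel, default τ = 3.5 s for a nuclear GCaMP-class
indicator, truncated at 5τ, max-normalized. An ISI regressor uses the
complement of the stimulus-on indicator, and a motor regressor convolves the
rectified motor trace.

## Behavioral analysis

Tail deflection is the signed mean perpendicular distance of 10 tail points
from the head-axis midline, in mm; tracking gaps are linearly interpolated
up to 3 frames and longer gaps are an error. Flick detection thresholds the
rectified trace at 0.4 mm for peaks (10/20 px with a warning when only pixel
calibration exists) after a 40 ms moving average — at 120 Hz an unsmoothed
0.4 mm threshold sits ~3σ above realistic tracking noise and produces
dozens of false peaks per session, while the smoothing window is an order of
magnitude shorter than a flick. Onset is the **last** upward crossing of
0.2 mm before the peak (rejects slow drift), linearly interpolated between
samples; events are separated by a 0.5 s refractory gap; the counter-bend is
the largest opposite-sign excursion within 0.3 s after the peak.

Trial assignment windows: responses are valid from the time the stimulus
reaches 5° of angular size until collision + 1 s (`main`) or until 5 s after
expansion ends (`first_encounter`); earlier events are tagged
`excluded_early`, later in-trial events `excluded_late`, all others
`spontaneous`. Unresponded trials carry peak amplitude 0, so the mean
amplitude over all trials equals response rate × mean responded amplitude.

The spontaneous rate is events per second over all time with θ ≤ θ_init.
The Poisson correction subtracts the probability of at least one spontaneous
flick in the validity window, clip(p_obs − (1 − e^{−λT}), 0, 1). Two
consequences worth knowing: (i) when evoked and spontaneous responses
overlap the correction is p₁(1 − e^{−λT}) below the true evoked probability
(≈ 0.5 instead of 0.6 at λ = 0.0266 Hz, T ≈ 6.5 s) — this bias belongs to
the estimator, not the implementation; (ii) in-window spontaneous events are
indistinguishable from evoked ones, so measured response times and direction
fractions are diluted toward the spontaneous distribution (uniform timing,
50/50 direction).

Habituation curves fit a·e^{−t/τ} to the corrected per-trial probabilities
with trial time t = k·ISI (the convention used to plot such curves), with a
seeded 1000-resample bootstrap over fish for the 95% band. The fit is
rejected when the 95% CI on τ exceeds 10× its estimate or τ exceeds 50× the
observed span (a flat curve leaves τ unconstrained — it can fit exactly with
arbitrary large τ, so a CI rule alone cannot flag it).

Response typing standardizes (response time, positive peak, negative peak,
peak ratio) and runs K-means (default k = 5, seed mandatory); cluster ids
are reordered by descending mean |positive peak|, ties broken by original
index. Fin motion is the per-frame SD over pixels of consecutive-frame
differences in each fin window, averaged across fins and smoothed; the beat
frequency is the inverse median peak spacing and the tuck time the last beat
before a reference event.

## Tuning codes

ROIs are pre-selected by one-sided Pearson correlation with the stimulus or
ISI regressor (r ≥ 0.3) or motor regressor (r ≥ 0.5); only positive
correlations count as "responsive" (anti-correlated cells would otherwise
pollute the clusters). Trial averages subtract a 5 s pre-onset baseline and
use a window of stimulus duration + 10 s truncated at the trial period.

The 4-bit code correlates the **concatenated across-type profile** with
per-type regressors that are zero outside their own segment, bit = 1 iff
r > 0.2; bit order (dimming, dark loom, brightening, checkerboard) with
weights 8/4/2/1, which pins LS (dark loom + checkerboard) to decimal 5, DS
(dimming + dark loom) to 12 and brightening-only to 2. Two numerical
choices matter here:

* Profile (not per-segment) correlation keeps the null tail of r narrow:
  a cell's strong response in its own segments enters the variance
  normalization, shrinking spurious correlations in other segments. A
  per-segment mode (`method="segment"`) is provided.
* Each segment is mean-centered before concatenation. A small error in the
  estimated baseline shifts a whole segment coherently and correlates with
  the regressor's in-segment mass; without centering this fattens the null
  tail of r several-fold (measured: ~8–11% false-positive bits per stimulus
  type at the 0.2 threshold, versus <1% with centering).

Near-constant averages are guarded by a variance floor (r undefined → bit 0,
correlation NaN); a missing stimulus type leaves the bit undefined and the
cell out of the 16-cluster census. Peak latency is the argmax of the trial
average (earliest on ties; flat averages are NaN).

## Habituation dynamics

Per-trial peaks are the maxima of baseline-subtracted response windows; a
trial is "responded" when its peak exceeds 2× the pooled pre-onset SD, and
cells with fewer than 3 responded trials are excluded. The fit
a·e^{t·(1/τ)} + c uses nonlinear least squares with bounds a ≥ 0,
|1/τ| ≤ 0.5 s⁻¹ and c ≤ min(peak) + 0.1·range(peak). The c ceiling is the
statement that the offset is the non-habituating floor of the series;
without it the three-parameter model is weakly identified on flat series
(c can absorb all but one point, letting 1/τ wander to noise-determined
values — in simulation ~25% of flat cells escaped |1/τ| < 2×10⁻³ s⁻¹ that
way, which destroys the stable class). Initialization: for decreasing series
c₀ = last peak, a₀ = first − last, 1/τ₀ from log-linear regression of
peak − c₀; flat/growing series initialize c₀ just below the minimum instead.
The 95% CI on 1/τ is the linearized covariance interval; a fit is ill-fit
when that CI is at least 10× the population's largest |1/τ|.

Classification thresholds come from the histogram of well-fit 1/τ values:

* bins are zero-centered (the near-zero peak can be far narrower than one
  bin; uncentered edges split it or displace its fitted mean by up to half
  a bin), Freedman–Diaconis width by default;
* the histogram is fitted with a sum of Gaussians, one per prominent peak
  (2–3, means anchored within ±2 bins of their peak). A strict two-Gaussian
  fit is unstable when the data contain a third (potentiating) mode — the
  near-zero component intermittently migrates onto it, inverting the
  thresholds;
* component σ is floored at one bin width: sub-bin structure is not
  resolvable from counts, and the fitted near-zero width would otherwise be
  an artifact of bin placement;
* thresholds are the near-zero mean ± FWHM/2 (FWHM = 2√(2 ln 2)·σ). An
  override mode passes externally supplied thresholds through unchanged.

Well-fit cells are labelled depressing / potentiating / stable by the
thresholds; ill-fit cells by the sign of 1/τ (never stable). The
pre-exposure contrast reports medians/SEs and Kruskal–Wallis p-values for
trials 1 vs 10 within condition and trial 11 across the dimming and wait
conditions; fully tied groups report p = 1.

## Laterality and GABA

Hemispheres come from the atlas x-coordinate relative to a configured
midline; cells within ±2 µm are ambiguous and excluded from counts.
HI = (n_ipsi − n_contra)/n_total for single-eye stimulation; monocular
populations get per-eye indices and binocular populations an index relative
to the right eye. Binocularity needs both eye protocols (responsive to one
eye → monocular, both → binocular, neither → none); a single-eye dataset is
an error. GABA calls binarize the red channel (Otsu by default, manual
threshold available) and label a cell GABAergic iff the red label covers
strictly more than 70% of its ROI pixels. Region summaries keep a region
only with ≥ 10 cells from ≥ 3 fish.

## Synthetic data: what it emulates, what it does not

The behavioral generator plants trial-locked escapes with probability
p₁·e^{−k·ISI/τ_h} (defaults p₁ = 0.6, τ_h = 60 s), evoked onsets at a
truncated Gaussian 1.3 ± 0.5 s before collision restricted to the validity
window, direction away from the stimulated eye with probability 0.76,
spontaneous Poisson flicks at 0.0266 Hz everywhere, half-sine flick
waveforms (1.0 ± 0.2 mm, 0.3 s, optional counter-bend at half amplitude)
and white tracking noise. The calcium generator plants 4-bit codes and
per-trial amplitudes a·e^{t·(1/τ)} + c on the unit-peak single-trial
regressor with white Gaussian noise (SNR = mean amplitude / noise SD); the
habituation clock of each pathway starts at the first trial of its own
stimulus type, matching the per-type decline of trial averages. Dynamics
classes draw 1/τ from N(−7.5×10⁻³, 1.5×10⁻³) (depressing),
N(−3.76×10⁻⁵, 2.25×10⁻⁵) (stable) and N(+5×10⁻³, 1.5×10⁻³) s⁻¹
(potentiating — a moderate ~6× growth over a 10-trial ISI-40 session, chosen
once as a realistic counterpart to the depressing rate). Hemispheres are
contralateral with configurable probability (0.93 for LS-like, 0.49 for
DS-like populations), GABA flags Bernoulli per population. ROI images plant
exact red-pixel counts per cell, so overlap fractions are pixel-exact and
rounding never crosses the 70% boundary; tail videos render a 10-point
polyline whose mean offset equals the planted deflection, plus fin patches
whose texture intensity ramps as a sawtooth (one motion-energy spike per
beat). All generators are deterministic given (config, seed).

Passing tests on these data show the estimators recover known structure
under white noise and exact trial-locking. They do not establish robustness
to photobleaching or slow drift (an optional linear drift exists but is off
by default), motion artifacts, neuropil contamination, overlapping ROIs,
non-Poisson spontaneous behavior, tracking failures beyond 3-frame gaps, or
real calcium-indicator nonlinearity.

## Sizes and defaults used by the checks

The test suite and the acceptance script run cohorts of 20–200 fish,
populations of 200–800 cells, sessions of 5–10 trials at ISI 10–40 s and
images up to 512², sizes at which every recovery statistic stabilizes while
a full run stays comfortably in the minutes range on one core. Bootstrap
bands use 1000 resamples; Monte-Carlo fit checks 500 replicates.

## Known limitations

* The Poisson correction subtracts rather than deconvolves the spontaneous
  probability (the study's own rule); see the bias noted above.
* 1/τ thresholds depend on the histogram's bin scale whenever the near-zero
  peak is sub-bin; the printed reference thresholds can be reproduced only
  through the override mode, not re-derived from other data.
* The 3-parameter exponential is intrinsically ill-conditioned on series
  that are flat relative to noise; the amplitude-positivity and offset
  bounds regularize but cannot remove that.
* Binocularity uses the tuning-code bit under each eye's protocol; the rare
  "binocular resetting" phenotype is not modelled beyond flagging.
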