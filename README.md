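# loomhab

Analysis pipeline for **habituation of looming-evoked escape behavior in
larval zebrafish** and its neural correlates: stimulus generation, tail-flick
detection, spontaneous-rate-corrected response probabilities, calcium-imaging
tuning codes, habituation-dynamics classification, hemispheric/binocularity
indices and GABAergic labeling — together with a synthetic-data generator
that produces every input with known ground truth.

It is written for researchers who study visually evoked escape and its
habituation in head-embedded, tail-free larvae: behavioral rigs that track
the tail at high frame rate while an expanding disk is projected to one eye,
and 2-photon rigs that record nuclear-GCaMP fluorescence at 1 Hz during
repeated dark-looming / checkerboard-looming / dimming / brightening
stimulation.

## The model

**Stimulus.** A looming disk simulates an object of half-size *l*
approaching at constant speed *|v|*; its angular size follows

    θ(t) = 2·arctan( (l/|v|) / t_rel )

with *t_rel* the time remaining to virtual collision, clipped to
[θ_init, θ_final]. Whole-field dimming reuses the dark loom's dark-pixel
fraction as its luminance time course (no moving edge); brightening inverts
its polarity; an expanding checkerboard keeps mean luminance constant and
isolates the motion component.

**Behavior.** Tail deflection is the signed mean perpendicular distance of
10 equidistant tail points from the midline. A flick is detected when the
rectified deflection exceeds 0.4 mm (its onset is the last upward crossing
of 0.2 mm before the peak). The per-trial escape probability across fish is
corrected for spontaneous flicks, assumed Poisson with rate λ:

    p_corr = clip( p_obs − (1 − e^{−λ·T}), 0, 1 )

over the validity window *T* (from θ = 5° until 1 s after collision), and
the habituation curve is fitted with *a·e^{−t/τ}*.

**Neural tuning and dynamics.** Each ROI's trial-averaged response profile
across the four stimulus types is correlated with per-type regressors
(stimulus drive convolved with a causal exponential calcium kernel); each
correlation above *r* = 0.2 sets one bit of a 4-bit code, (dimming,
dark-loom, brightening, checkerboard) with weights 8/4/2/1 — so
looming-sensitive (LS) cells form cluster 5 and dimming-sensitive (DS) cells
cluster 12. Per-cell response-peak series over trials are fitted with
*a·e^{t/τ} + c*; the population histogram of 1/τ is fitted with a Gaussian
mixture and the near-zero component's FWHM sets the thresholds that split
cells into **depressing / potentiating / stable**. Hemispheric indices
(HI = (n_ipsi − n_contra)/n_total, −1 = fully contralateral), binocularity
classes, and GABA calls (binarized red gad1b channel covering > 70% of an
ROI) complete the picture.

## Worked example

Run the whole pipeline on synthetic data (every stage writes CSV/TIFF/JSON
outputs plus a run report):

```bash
loomhab run --seed 1 --out runout
```

prints (abridged):

```json
{
  "spontaneous_rate_hz": 0.0234,
  "habituation_tau_s": 52.4,
  "first_trial_p_corr": 0.559,
  "direction_away_fraction": 0.671,
  "code_recovery_fraction": 0.995,
  "dynamics_fractions": {"depressing": 0.553, "potentiating": 0.187, "stable": 0.260},
  "hi_ls": -0.76,
  "hi_ds": -0.044,
  "gaba_fraction": 0.25,
  "gaba_call_accuracy": 1.0
}
```

Reading these numbers: a 20-fish cohort was simulated with a first-trial
escape probability of 0.6 decaying with τ = 60 s over 10 trials at ISI 10 s,
on top of spontaneous flicks at 0.0266 Hz. The pipeline re-detected the
flicks, measured the spontaneous rate (0.0234 Hz here, within sampling error
of the planted rate), corrected the per-trial probabilities and recovered
τ ≈ 52 s. On the imaging side, 99.5% of 200 simulated ROIs recovered their
planted 4-bit tuning code; a 300-cell habituation session recovered the
planted 55/18/27% depressing/potentiating/stable split as 55.3/18.7/26.0;
the looming-sensitive cluster came out strongly contralateral (HI −0.76 on
50 cells) while the dimming-sensitive cluster was bilateral (HI −0.04); and
all 24 GABA calls on the rendered red-channel image matched the planted
labels.

The same stages are available piecemeal (`loomhab sim ...`,
`loomhab behavior detect|assign|curve|classify`, `loomhab tune code`,
`loomhab dynamics fit`, `loomhab lateral hi|gaba|regions`) and as a library:

```python
import loomhab as lh

cfg = lh.BehaviorSimConfig(n_fish=50)
traces, truth = lh.simulate_behavior_session(cfg, seed=0)
events = lh.detect_flicks(traces[0])
table = lh.assign_responses(events, cfg.train, mode="main")
```

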