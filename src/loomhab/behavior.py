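"""Behavioral event detection and habituation analysis from tail-tracking traces.

The behavioral readout is the tail deflection trace: the signed mean
perpendicular distance of 10 equidistant tail points from the midline,
calibrated to millimetres (negative = away from the stimulated eye).  From it
the module detects tail flicks by threshold crossing (onset at 0.2 mm, peak at
0.4 mm), assigns them to stimulus trials under the validity-window rules,
corrects response probabilities for spontaneous Poisson flicks, fits the
habituation curve ``a*exp(-t/tau)``, and clusters response types by K-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .stimulus import StimulusTrain, time_to_theta

#: default flick thresholds (mm, and their px equivalents for uncalibrated data)
ONSET_THRESH_MM = 0.2
PEAK_THRESH_MM = 0.4
ONSET_THRESH_PX = 10.0
PEAK_THRESH_PX = 20.0


@dataclass
class TailTrace:
    """Uniformly sampled, calibrated tail-deflection time series.

    ``deflection_mm`` is signed; by convention negative deflection points away
    from the stimulated eye.  ``px_per_mm`` is kept for provenance; traces
    built directly in mm may leave it at its default.  An uncalibrated trace
    (``units="px"``) carries raw pixel deflections instead.
    """

    deflection_mm: np.ndarray
    fps: float
    px_per_mm: float | None = None
    t0_s: float = 0.0
    units: str = "mm"

    def __post_init__(self) -> None:
        self.deflection_mm = np.asarray(self.deflection_mm, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_mm is not None and self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.deflection_mm)) / self.fps

    @property
    def duration_s(self) -> float:
        return len(self.deflection_mm) / self.fps


@dataclass
class FlickEvent:
    """A single detected tail flick.

    ``onset_s`` is the last upward crossing of the onset threshold before the
    peak; ``peak_amp_mm`` keeps the sign of the bend.  ``provenance`` is set by
    :func:`assign_responses` (evoked / spontaneous / excluded_early /
    excluded_late); freshly detected events are ``unassigned``.
    """

    onset_s: float
    peak_s: float
    peak_amp_mm: float
    counter_peak_amp_mm: float | None = None
    type_label: int | None = None
    provenance: str = "unassigned"


def tail_deflection(points_px: np.ndarray, midline_point: np.ndarray,
                    midline_dir: np.ndarray, px_per_mm: float, fps: float,
                    max_gap_frames: int = 3) -> TailTrace:
    """Signed mean perpendicular tail-point distance from the midline, in mm.

    Parameters
    ----------
    points_px : (n_frames, 10, 2) array
        Per-frame (x, y) pixel coordinates of 10 equidistant tail points.
        Frames with any NaN are treated as tracking gaps and linearly
        interpolated up to ``max_gap_frames`` consecutive frames.
    midline_point, midline_dir
        A point on the embedded head axis and its direction vector; the
        deflection sign follows the perpendicular (left-normal) of that axis.
    """
    pts = np.asarray(points_px, dtype=float)
    if pts.ndim != 3 or pts.shape[1] != 10 or pts.shape[2] != 2:
        raise ValueError("points_px must have shape (n_frames, 10, 2)")
    d = np.asarray(midline_dir, dtype=float)
    d = d / np.linalg.norm(d)
    normal = np.array([-d[1], d[0]])
    rel = pts - np.asarray(midline_point, dtype=float)
    dist_px = rel @ normal                      # (n_frames, 10) signed distances
    defl = dist_px.mean(axis=1) / px_per_mm
    bad = ~np.isfinite(defl)
    if bad.any():
        idx = np.arange(len(defl))
        # reject gaps longer than max_gap_frames
        runs = np.split(idx[bad], np.where(np.diff(idx[bad]) > 1)[0] + 1)
        for run in runs:
            if len(run) > max_gap_frames:
                raise ValueError(f"tracking gap of {len(run)} frames exceeds max_gap_frames")
        defl[bad] = np.interp(idx[bad], idx[~bad], defl[~bad])
    return TailTrace(deflection_mm=defl, fps=fps, px_per_mm=px_per_mm)


def _cross_time(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t1
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def detect_flicks(trace: TailTrace, peak_thresh_mm: float = PEAK_THRESH_MM,
                  onset_thresh_mm: float = ONSET_THRESH_MM, refractory_s: float = 0.5,
                  counterbend_window_s: float = 0.3, smooth_s: float = 0.04
                  ) -> list[FlickEvent]:
    """Detect tail flicks by threshold crossing on the rectified deflection.

    Peaks are local maxima of ``|deflection|`` at least ``peak_thresh_mm``
    high and separated by ``refractory_s``; each event's onset is the last
    upward crossing of ``onset_thresh_mm`` before its peak (linearly
    interpolated between samples).  The counter-bend is the largest
    opposite-sign excursion within ``counterbend_window_s`` after the peak.
    A short moving average (``smooth_s``) suppresses single-sample noise
    peaks before thresholding.  Uncalibrated (pixel) traces fall back to the
    10/20 px thresholds with a warning.
    """
    x = trace.deflection_mm
    if trace.units == "px" and peak_thresh_mm == PEAK_THRESH_MM:
        warnings.warn("uncalibrated trace: applying thresholds in pixels (10/20 px)")
        peak_thresh_mm, onset_thresh_mm = PEAK_THRESH_PX, ONSET_THRESH_PX
    w = max(1, int(round(smooth_s * trace.fps)))
    if w > 1:
        x = np.convolve(x, np.ones(w) / w, mode="same")
    absx = np.abs(x)
    dist = max(1, int(round(refractory_s * trace.fps)))
    peaks, _ = find_peaks(absx, height=peak_thresh_mm, distance=dist)
    t = trace.time_s
    events: list[FlickEvent] = []
    for p in peaks:
        # last upward crossing of the onset threshold before the peak
        onset_t = t[p]
        for i in range(p, 0, -1):
            if absx[i - 1] < onset_thresh_mm <= absx[i]:
                onset_t = _cross_time(t[i - 1], t[i], absx[i - 1], absx[i], onset_thresh_mm)
                break
        else:
            onset_t = t[0]
        sign = np.sign(x[p]) if x[p] != 0 else 1.0
        # counter-bend: largest opposite-sign excursion shortly after the peak
        j1 = min(len(x), p + 1 + int(round(counterbend_window_s * trace.fps)))
        counter = None
        if j1 > p + 1:
            seg = x[p + 1 : j1]
            opp = seg * sign < 0
            if opp.any():
                cand = seg[opp]
                counter = float(cand[np.argmax(np.abs(cand))])
        events.append(FlickEvent(onset_s=float(onset_t), peak_s=float(t[p]),
                                 peak_amp_mm=float(x[p]), counter_peak_amp_mm=counter))
    return events


# ---------------------------------------------------------------------------
# Trial assignment and probabilities
# ---------------------------------------------------------------------------

def response_window(train: StimulusTrain, mode: str = "main",
                    theta_valid_deg: float = 5.0) -> tuple[float, float]:
    """Validity window bounds relative to trial onset for the given mode.

    ``main``: from the time the stimulus reaches ``theta_valid_deg`` (5 deg)
    until 1 s after projected collision.  ``first_encounter``: until 5 s
    after the stimulus stops expanding.
    """
    p = train.params
    theta0 = max(p.theta_init, min(theta_valid_deg, p.theta_final))
    t_lo = time_to_theta(p, theta0)
    if mode == "main":
        t_hi = p.collision_s + 1.0
    elif mode == "first_encounter":
        t_hi = p.expansion_duration_s + 5.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return t_lo, t_hi


def assign_responses(events: list[FlickEvent], train: StimulusTrain,
                     mode: str = "main", theta_valid_deg: float = 5.0) -> pd.DataFrame:
    """Assign detected flicks to stimulus trials; returns the trial table.

    A trial counts as responded iff at least one event onset falls inside its
    validity window; the first qualifying event defines the response time
    (relative to collision, negative = before) and the signed peak amplitude.
    Trials without a response carry ``peak_amp_mm = 0``.  Event provenance is
    updated in place: evoked / excluded_early / excluded_late / spontaneous.
    """
    t_lo, t_hi = response_window(train, mode, theta_valid_deg)
    p = train.params
    onsets = np.asarray(train.onsets_s)
    if len(onsets) > 1 and t_hi > (onsets[1] - onsets[0]):
        raise ValueError("validity window overlaps the next trial (ISI too short)")
    stim_end = p.duration_s
    rows = []
    events_sorted = sorted(events, key=lambda e: e.onset_s)
    for ev in events_sorted:
        ev.provenance = "spontaneous"
    for k, onset in enumerate(onsets):
        collision = onset + p.collision_s
        responded, rtime, amp = False, np.nan, 0.0
        for ev in events_sorted:
            rel = ev.onset_s - onset
            if rel < 0 or rel >= max(stim_end, t_hi):
                continue
            if rel < t_lo:
                ev.provenance = "excluded_early"
            elif rel <= t_hi:
                ev.provenance = "evoked"
                if not responded:
                    responded = True
                    rtime = ev.onset_s - collision
                    amp = ev.peak_amp_mm
            else:
                ev.provenance = "excluded_late"
        rows.append({"trial": k, "onset_s": onset, "collision_s": collision,
                     "kind": p.kind.value, "eye": p.eye.value, "responded": responded,
                     "response_time_s": rtime, "peak_amp_mm": amp})
    return pd.DataFrame(rows)


def stimulus_free_intervals(train: StimulusTrain, session_end_s: float) -> list[tuple[float, float]]:
    """Intervals with no stimulus on screen (theta <= theta_init)."""
    ivals, prev = [], 0.0
    dur = train.params.duration_s
    for onset in train.onsets_s:
        if onset > prev:
            ivals.append((prev, onset))
        prev = onset + dur
    if session_end_s > prev:
        ivals.append((prev, session_end_s))
    return ivals


def spontaneous_rate(events: list[FlickEvent], intervals: list[tuple[float, float]]) -> float:
    """Spontaneous flick rate (Hz): events inside the stimulus-free intervals
    divided by the total stimulus-free time."""
    total = float(sum(b - a for a, b in intervals))
    if total <= 0:
        raise ValueError("total stimulus-free time must be positive")
    n = sum(1 for ev in events if any(a <= ev.onset_s < b for a, b in intervals))
    return n / total


def corrected_probability(p_obs, rate_hz: float, window_s: float):
    """Subtract the Poisson probability of >=1 spontaneous flick in the window.

    ``clip(p_obs - (1 - exp(-rate*window)), 0, 1)``; equals ``p_obs`` at rate 0
    and is monotone non-increasing in both rate and window length.
    """
    if rate_hz < 0 or window_s <= 0:
        raise ValueError("rate must be >= 0 and window > 0")
    p = np.asarray(p_obs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_obs must lie in [0, 1]")
    out = np.clip(p - (1.0 - np.exp(-rate_hz * window_s)), 0.0, 1.0)
    return float(out) if np.isscalar(p_obs) else out


@dataclass
class HabituationCurve:
    """Cohort habituation curve with exponential fit ``a*exp(-t/tau)``."""

    t_s: np.ndarray
    p_obs: np.ndarray
    p_corr: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    a: float = np.nan
    tau_s: float = np.nan
    tau_ci: tuple = (np.nan, np.nan)
    fit_ok: bool = False


def habituation_curve(responded: np.ndarray, train: StimulusTrain, rate_hz: float,
                      window_s: float, n_boot: int = 1000, seed: int = 0) -> HabituationCurve:
    """Per-trial corrected response probability across fish, with exponential fit.

    Parameters
    ----------
    responded : (n_fish, n_trials) bool array
        Trial-by-trial response flags, one row per fish, trials aligned by index.
    rate_hz, window_s
        Spontaneous rate and validity-window length for the Poisson correction.

    The per-trial probability is the fraction of fish that responded,
    spontaneous-corrected; ``a*exp(-t/tau)`` is fitted over trial times
    ``t = k * ISI`` (the convention used for plotting habituation curves,
    where each data point sits at an integer multiple of the ISI).  A seeded bootstrap over fish
    (``n_boot`` resamples) gives the 95% band.  The fit is rejected
    (``fit_ok=False``) when the 95% CI on tau is wider than 10x its estimate,
    which flags flat (tau -> infinity) curves.
    """
    R = np.asarray(responded, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need a (n_fish >= 2, n_trials) response matrix")
    if R.shape[1] < 2:
        raise ValueError("need at least two trials to fit a habituation curve")
    t = np.arange(R.shape[1]) * float(train.isi_s)
    p_obs = R.mean(axis=0)
    p_corr = corrected_probability(p_obs, rate_hz, window_s)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, R.shape[1]))
    for b in range(n_boot):
        rows = rng.integers(0, R.shape[0], R.shape[0])
        boot[b] = corrected_probability(R[rows].mean(axis=0), rate_hz, window_s)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    curve = HabituationCurve(t_s=t, p_obs=p_obs, p_corr=p_corr, band_lo=lo, band_hi=hi)
    if np.all(p_corr == 0):
        return curve  # nothing to fit; diagnostic: fit_ok stays False
    model = lambda tt, a, tau: a * np.exp(-tt / tau)
    tau0 = max(t[1], -(t[-1] - t[0]) / np.log(max(p_corr[-1], 1e-3) / max(p_corr[0], 1e-3))
               if p_corr[-1] < p_corr[0] else t[-1])
    try:
        popt, pcov = curve_fit(model, t, p_corr, p0=[max(p_corr[0], 1e-3), tau0],
                               bounds=([0.0, 1e-6], [1.5, 1e9]), maxfev=10000)
        a_hat, tau_hat = popt
        sd_tau = float(np.sqrt(pcov[1, 1]))
        ci = (tau_hat - 1.96 * sd_tau, tau_hat + 1.96 * sd_tau)
        curve.a, curve.tau_s, curve.tau_ci = float(a_hat), float(tau_hat), ci
        # reject when the CI is wide relative to tau or tau is far beyond the
        # observed span (a flat curve: tau -> infinity is unconstrained)
        curve.fit_ok = bool(np.isfinite(sd_tau) and (ci[1] - ci[0]) < 10.0 * tau_hat
                            and tau_hat <= 50.0 * max(t[-1], 1e-9))
    except RuntimeError:
        pass
    return curve


def classify_response_types(features, k: int = 5, seed: int = 0,
                            order_by: str | int = "peak_pos") -> np.ndarray:
    """K-means response typing on standardized flick features.

    ``features`` is a DataFrame (or array) with one row per event and the
    columns (response time, positive peak amplitude, negative peak amplitude,
    peak ratio).  Features are z-scored; labels are re-indexed so cluster 0
    has the largest mean |positive peak|, with ties broken by original index.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k must not exceed the number of events")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate rows can leave clusters empty
        raw = km.fit_predict(Z)
    if isinstance(order_by, str):
        cols = list(features.columns) if isinstance(features, pd.DataFrame) else []
        col = cols.index(order_by) if order_by in cols else 1
    else:
        col = order_by
    amp = np.abs(X[:, col])
    means = np.array([amp[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)])
    order = np.argsort(-means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def direction_stats(trial_table: pd.DataFrame, away_sign: float = -1.0) -> float:
    """Fraction of responded trials whose tail flick was directed away from
    the stimulated eye (by sign convention, negative = away).  NaN if no
    trial was responded."""
    resp = trial_table[trial_table["responded"]]
    if len(resp) == 0:
        return float("nan")
    return float((np.sign(resp["peak_amp_mm"]) == np.sign(away_sign)).mean())


# ---------------------------------------------------------------------------
# Pectoral fins
# ---------------------------------------------------------------------------

@dataclass
class FinMotion:
    """Fin-motion trace with detected beats."""

    time_s: np.ndarray
    trace: np.ndarray
    beat_times_s: np.ndarray
    beat_freq_hz: float
    tuck_time_s: float | None = None


def fin_motion(frame_stack: np.ndarray, left_window: tuple, right_window: tuple,
               fps: float, smooth_s: float = 0.1,
               reference_event_s: float | None = None) -> FinMotion:
    """Quantify pectoral-fin motion from a video stack.

    Per fin, the trace is the per-frame standard deviation (over pixels) of
    the difference between consecutive frames inside the fin window; the left
    and right traces are averaged and smoothed with a moving average.  Beats
    are peaks of the smoothed trace; the beat frequency is the inverse median
    peak spacing, and the tuck time is the last beat before
    ``reference_event_s`` (e.g. a large tail flick).
    """
    stack = np.asarray(frame_stack, dtype=float)
    traces = []
    for (y0, y1, x0, x1) in (left_window, right_window):
        win = stack[:, y0:y1, x0:x1]
        if win.shape[1] == 0 or win.shape[2] == 0:
            raise ValueError("empty fin window")
        d = np.diff(win, axis=0)
        tr = d.reshape(d.shape[0], -1).std(axis=1)
        traces.append(np.concatenate([[0.0], tr]))
    trace = np.mean(traces, axis=0)
    w = max(1, int(round(smooth_s * fps)))
    if w > 1:
        trace = np.convolve(trace, np.ones(w) / w, mode="same")
    time_s = np.arange(len(trace)) / fps
    span = trace.max() - trace.min()
    peaks, _ = find_peaks(trace, prominence=0.2 * span if span > 0 else None)
    beat_times = time_s[peaks]
    freq = 1.0 / float(np.median(np.diff(beat_times))) if len(beat_times) >= 2 else float("nan")
    tuck = None
    if reference_event_s is not None and len(beat_times):
        before = beat_times[beat_times < reference_event_s]
        tuck = float(before[-1]) if len(before) else None
    return FinMotion(time_s=time_s, trace=trace, beat_times_s=beat_times,
                     beat_freq_hz=freq, tuck_time_s=tuck)
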