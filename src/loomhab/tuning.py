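"""Stimulus-tuning classification of calcium ROIs via regressor correlation.

Responsive ROIs are selected by Pearson correlation with stimulus / ISI /
motor regressors (thresholds 0.3 / 0.3 / 0.5).  Each cell then receives a
4-bit tuning code from the correlations of its trial-averaged response
profile with the four per-stimulus-type regressors at threshold r > 0.2; the
bit order MSB->LSB is (dimming, dark-looming, brightening, checkerboard) with
weights 8/4/2/1, so looming-sensitive (LS) cells — dark loom + checkerboard —
land in cluster 5 and dimming-sensitive (DS) cells — dimming + dark loom —
in cluster 12.

Correlations are one-sided: only positive r counts as responsive.  By default
the correlation is computed on the concatenated across-type profile against a
regressor that is zero outside its own type's segment, which keeps the null
tail of r narrow; per-segment correlation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import (LoomingParams, RegressorSet, ScreenGeometry, StimulusTrain,
                       build_regressor)

#: bit order (MSB -> LSB) and weights of the 4-bit tuning code
BIT_NAMES = ("dm", "dl", "br", "cb")
BIT_WEIGHTS = {"dm": 8, "dl": 4, "br": 2, "cb": 1}
KIND_TO_BIT = {"dimming": "dm", "dark_loom": "dl", "brightening": "br", "checker_loom": "cb"}

R_STIM = 0.3
R_MOTOR = 0.5
R_CODE = 0.2
_VAR_FLOOR = 1e-12


@dataclass
class RoiTraceSet:
    """Fluorescence matrix (ROI x frame) with per-ROI identifiers.

    Frames share a clock with the session's stimulus trains; ``fs`` is the
    imaging rate (1 Hz in the reference protocol).
    """

    F: np.ndarray
    fs: float
    roi_ids: np.ndarray
    fish_ids: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.roi_ids = np.asarray(self.roi_ids)
        self.fish_ids = np.asarray(self.fish_ids)
        if len(self.roi_ids) != self.F.shape[0] or len(self.fish_ids) != self.F.shape[0]:
            raise ValueError("roi_ids / fish_ids must match the number of ROI rows")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with a variance floor: near-constant inputs give NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    xc = x - x.mean()
    yc = y - y.mean()
    vx, vy = xc @ xc, yc @ yc
    if vx < _VAR_FLOOR or vy < _VAR_FLOOR:
        return float("nan")
    return float((xc @ yc) / np.sqrt(vx * vy))


def select_responsive(F: np.ndarray, stim_regressor: np.ndarray, isi_regressor: np.ndarray,
                      motor_regressor: np.ndarray | None = None,
                      r_stim: float = R_STIM, r_motor: float = R_MOTOR) -> pd.DataFrame:
    """Select ROIs correlated with the stimulus sequence, ISI, or motor output.

    An ROI is retained iff its (one-sided, positive) Pearson r with the
    stimulus or ISI regressor reaches ``r_stim`` (0.3), or with the motor
    regressor reaches ``r_motor`` (0.5).  Returns one row per ROI with the
    three correlations, the retained flag and a reason tag recording which
    criterion fired.
    """
    F = np.asarray(F, dtype=float)
    for name, reg in (("stimulus", stim_regressor), ("isi", isi_regressor),
                      ("motor", motor_regressor)):
        if reg is not None and len(reg) != F.shape[1]:
            raise ValueError(f"{name} regressor length does not match trace length")
    rows = []
    for i in range(F.shape[0]):
        r_s = pearson_r(F[i], stim_regressor)
        r_i = pearson_r(F[i], isi_regressor)
        r_m = pearson_r(F[i], motor_regressor) if motor_regressor is not None else np.nan
        reasons = []
        if r_s >= r_stim:
            reasons.append("stimulus")
        if r_i >= r_stim:
            reasons.append("isi")
        if np.isfinite(r_m) and r_m >= r_motor:
            reasons.append("motor")
        rows.append({"roi": i, "r_stim": r_s, "r_isi": r_i, "r_motor": r_m,
                     "retained": bool(reasons), "reason": "+".join(reasons)})
    return pd.DataFrame(rows)


def trial_average(trace: np.ndarray, onsets_frames: np.ndarray, window_frames: int,
                  baseline_frames: int = 5) -> tuple[np.ndarray, int]:
    """Baseline-subtracted mean response across repetitions of one stimulus type.

    Segments of ``window_frames`` aligned at each onset are averaged after
    subtracting the mean of the ``baseline_frames`` preceding the onset
    (clipped at the recording start).  Returns ``(average, n_repetitions)``;
    a single available repetition is still averaged (n_repetitions = 1 flags
    it for the caller).
    """
    trace = np.asarray(trace, dtype=float)
    segs = []
    for f0 in np.asarray(onsets_frames, dtype=int):
        if f0 < 0 or f0 + window_frames > len(trace):
            raise ValueError("trial window outside the recording")
        base = trace[max(0, f0 - baseline_frames): f0]
        b = base.mean() if len(base) else 0.0
        segs.append(trace[f0 : f0 + window_frames] - b)
    if not segs:
        raise ValueError("no repetitions")
    return np.mean(segs, axis=0), len(segs)


@dataclass
class TuningCode:
    """4-bit stimulus-tuning code with the underlying correlations.

    ``bits`` maps bit name -> 0/1 (or None when that stimulus type was not
    presented, in which case ``decimal`` is None and the cell is excluded
    from the 16-cluster census).
    """

    bits: dict
    correlations: dict

    @property
    def decimal(self) -> int | None:
        if any(v is None for v in self.bits.values()) or set(self.bits) != set(BIT_NAMES):
            return None
        return sum(BIT_WEIGHTS[k] * int(v) for k, v in self.bits.items())


def decimal_to_bits(decimal: int) -> dict:
    """Inverse of the code's bit weighting (0-15 -> bit dict)."""
    if not 0 <= decimal <= 15:
        raise ValueError("decimal code must lie in 0..15")
    return {k: (decimal // BIT_WEIGHTS[k]) % 2 for k in BIT_NAMES}


def tuning_code(trial_averages: dict, regressor_segments: dict, r_code: float = R_CODE,
                method: str = "profile") -> TuningCode:
    """Assign the 4-bit tuning code from trial-average/regressor correlations.

    Parameters
    ----------
    trial_averages, regressor_segments
        Dicts keyed by bit name (``dm``, ``dl``, ``br``, ``cb``); a missing
        stimulus type leaves that bit undefined.
    method
        ``"profile"`` (default): the across-type concatenated average is
        correlated with a regressor that is zero outside that type's own
        segment.  ``"segment"``: each average is correlated only with its own
        type's regressor segment.
    """
    present = [k for k in BIT_NAMES if k in trial_averages]
    bits: dict = {k: None for k in BIT_NAMES}
    corrs: dict = {k: float("nan") for k in BIT_NAMES}
    if method == "profile":
        # Each segment is mean-centered before concatenation: a small error in
        # the pre-trial baseline shifts a whole segment coherently and would
        # otherwise correlate with the regressor's in-segment mass, fattening
        # the null tail of r well beyond 1/sqrt(n).
        segs = [np.asarray(trial_averages[k], dtype=float) for k in present]
        profile = np.concatenate([s - s.mean() for s in segs])
        offsets = np.cumsum([0] + [len(s) for s in segs])
        for j, k in enumerate(present):
            reg = np.zeros(len(profile))
            seg = np.asarray(regressor_segments[k], dtype=float)
            reg[offsets[j]: offsets[j + 1]] = seg - seg.mean()
            r = pearson_r(profile, reg)
            corrs[k] = r
            bits[k] = int(np.isfinite(r) and r > r_code)
    elif method == "segment":
        for k in present:
            r = pearson_r(trial_averages[k], regressor_segments[k])
            corrs[k] = r
            bits[k] = int(np.isfinite(r) and r > r_code)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TuningCode(bits=bits, correlations=corrs)


def peak_latency(average: np.ndarray, fs: float, onset_frame: int = 0) -> float:
    """Seconds from stimulus onset to the maximum of the trial average.

    Ties report the earliest maximum; a flat average is undefined (NaN).
    """
    avg = np.asarray(average, dtype=float)
    if len(avg) == 0:
        raise ValueError("empty trial average")
    if np.ptp(avg) < 1e-12:
        return float("nan")
    return float((int(np.argmax(avg)) - onset_frame) / fs)


# ---------------------------------------------------------------------------
# Whole-population convenience path
# ---------------------------------------------------------------------------

def regressor_segment(params: LoomingParams, geom: ScreenGeometry, kernel_tau: float,
                      fs: float, window_frames: int) -> np.ndarray:
    """Unit-peak single-trial calcium regressor for one stimulus type."""
    train = StimulusTrain(params=params, n_trials=1, isi_s=0.0)
    reg: RegressorSet = build_regressor(train, geom, kernel_tau=kernel_tau, fs=fs,
                                        n_samples=window_frames)
    return reg.stimulus


def default_window_frames(train: StimulusTrain, fs: float, hold_extra_s: float = 10.0) -> int:
    """Trial-average window: stimulus duration + 10 s, truncated at the ISI period."""
    dur = train.params.duration_s
    period = dur + train.isi_s
    return int(round(min(dur + hold_extra_s, period) * fs))


def assign_codes(rois: RoiTraceSet, trains: dict, geom: ScreenGeometry,
                 kernel_tau: float = 3.5, r_code: float = R_CODE,
                 baseline_s: float = 5.0, method: str = "profile") -> pd.DataFrame:
    """Compute trial averages and tuning codes for every ROI in a session.

    ``trains`` maps bit names to the :class:`StimulusTrain` of that stimulus
    type (all on the session clock shared with ``rois.F``).  Returns one row
    per ROI with bits, decimal code and per-type correlations.
    """
    fs = rois.fs
    segments, windows, onset_frames = {}, {}, {}
    for k, train in trains.items():
        if k not in BIT_NAMES:
            raise ValueError(f"unknown stimulus bit {k!r}")
        w = default_window_frames(train, fs)
        windows[k] = w
        segments[k] = regressor_segment(train.params, geom, kernel_tau, fs, w)
        onset_frames[k] = np.round(np.asarray(train.onsets_s) * fs).astype(int)
    base = int(round(baseline_s * fs))
    rows = []
    for i in range(rois.F.shape[0]):
        avgs = {k: trial_average(rois.F[i], onset_frames[k], windows[k], base)[0]
                for k in trains}
        code = tuning_code(avgs, segments, r_code=r_code, method=method)
        row = {"roi_id": rois.roi_ids[i], "fish_id": rois.fish_ids[i],
               "decimal": code.decimal}
        row.update({f"bit_{k}": code.bits[k] for k in BIT_NAMES})
        row.update({f"r_{k}": code.correlations[k] for k in BIT_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
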