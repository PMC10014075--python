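"""Looming-stimulus kinematics, luminance profiles, frame renders and calcium regressors.

A looming stimulus simulates an object of half-size ``l`` approaching at
constant speed ``|v|``; its angular size follows

    theta(t) = 2 * arctan((l/|v|) / t_rel)

where ``t_rel`` is the time remaining to virtual collision.  The expansion
starts when theta reaches ``theta_init`` and is held at ``theta_final`` for a
configurable time before the screen returns to background.  Four stimulus
kinds are supported:

* ``dark_loom`` — dark disk expanding on a bright background,
* ``checker_loom`` — expanding dark/bright checkerboard disk on mid-gray
  (constant mean luminance, isolates the motion component),
* ``dimming`` — whole-field luminance decrease matching the dark loom's
  dark-pixel fraction, without any moving edge,
* ``brightening`` — same time course as dimming with inverted polarity.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class StimulusKind(str, enum.Enum):
    DARK_LOOM = "dark_loom"
    CHECKER_LOOM = "checker_loom"
    DIMMING = "dimming"
    BRIGHTENING = "brightening"


class Eye(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


LOOMING_KINDS = (StimulusKind.DARK_LOOM, StimulusKind.CHECKER_LOOM)


@dataclass(frozen=True)
class LoomingParams:
    """Geometry and timing of a single stimulus presentation.

    Parameters
    ----------
    kind
        One of the four stimulus kinds.  Dimming/brightening reuse the
        looming parameters to define their (edge-free) luminance time course.
    l_over_v
        Size-to-speed ratio in seconds (e.g. 0.240 or 0.480).
    theta_init, theta_final
        Initial and final angular size in degrees, ``0 < init < final < 180``.
    hold_s
        Time the stimulus is held at its final size before disappearing.
    refresh_hz
        Display refresh rate (frames per second).
    eye
        Which eye faces the stimulated wall.
    """

    kind: StimulusKind = StimulusKind.DARK_LOOM
    l_over_v: float = 0.240
    theta_init: float = 4.0
    theta_final: float = 140.0
    hold_s: float = 2.5
    refresh_hz: float = 20.0
    eye: Eye = Eye.LEFT

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", StimulusKind(self.kind))
        object.__setattr__(self, "eye", Eye(self.eye))
        if not self.l_over_v > 0:
            raise ValueError("l_over_v must be positive")
        if not (0.0 < self.theta_init < self.theta_final < 180.0):
            raise ValueError("need 0 < theta_init < theta_final < 180 degrees")
        if self.hold_s < 0:
            raise ValueError("hold_s must be >= 0")
        if not self.refresh_hz > 0:
            raise ValueError("refresh_hz must be positive")

    # -- derived timing ----------------------------------------------------
    @property
    def expansion_duration_s(self) -> float:
        onset, offset = expansion_window(self)
        return onset - offset

    @property
    def duration_s(self) -> float:
        """Total on-screen time: expansion plus hold at final size."""
        return self.expansion_duration_s + self.hold_s

    @property
    def collision_s(self) -> float:
        """Virtual collision time, measured from stimulus (expansion) onset."""
        return expansion_window(self)[0]


@dataclass(frozen=True)
class StimulusTrain:
    """A stimulus repeated ``n_trials`` times separated by ``isi_s``.

    ``onsets_s`` are expansion-onset times from session start.  If omitted
    they are generated with period ``duration + isi`` starting at ``start_s``.
    """

    params: LoomingParams
    n_trials: int
    isi_s: float
    start_s: float = 0.0
    onsets_s: tuple = ()

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.isi_s < 0:
            raise ValueError("isi_s must be >= 0")
        if not self.onsets_s:
            period = self.params.duration_s + self.isi_s
            onsets = tuple(self.start_s + k * period for k in range(self.n_trials))
            object.__setattr__(self, "onsets_s", onsets)
        else:
            object.__setattr__(self, "onsets_s", tuple(float(t) for t in self.onsets_s))
            if len(self.onsets_s) != self.n_trials:
                raise ValueError("onsets_s length must equal n_trials")
            if np.any(np.diff(self.onsets_s) <= 0):
                raise ValueError("onsets_s must be strictly increasing")
            if np.any(np.diff(self.onsets_s) < self.params.duration_s - 1e-9):
                raise ValueError("trials overlap: spacing shorter than stimulus duration")

    @property
    def end_s(self) -> float:
        return self.onsets_s[-1] + self.params.duration_s + self.isi_s

    def collision_times_s(self) -> np.ndarray:
        return np.asarray(self.onsets_s) + self.params.collision_s


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat-screen render geometry.

    The disk's apparent angular size is mapped to a pixel radius either
    linearly (``px_per_degree``) or by gnomonic projection from the viewing
    distance (``width_mm``/``distance_mm``); exactly one mapping must be
    configured.  ``background_level`` is the normalized background luminance.
    """

    width_px: int = 256
    height_px: int = 256
    px_per_degree: float | None = None
    width_mm: float | None = None
    distance_mm: float | None = None
    background_level: float = 1.0
    check_px: int = 16

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        linear = self.px_per_degree is not None
        gnomonic = self.width_mm is not None and self.distance_mm is not None
        if linear == gnomonic:
            raise ValueError("configure exactly one of px_per_degree or (width_mm, distance_mm)")

    def disk_radius_px(self, theta_deg: float) -> float:
        """Pixel radius of a disk of angular diameter ``theta_deg``."""
        half = math.radians(theta_deg) / 2.0
        if self.px_per_degree is not None:
            return (theta_deg / 2.0) * self.px_per_degree
        px_per_mm = self.width_px / self.width_mm
        return self.distance_mm * px_per_mm * math.tan(half)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def angular_size(params: LoomingParams, t_rel):
    """Angular size (degrees) at ``t_rel`` seconds before virtual collision.

    Implements ``theta = 2 arctan((l/|v|) / t_rel)`` clipped to
    ``[theta_init, theta_final]``; at ``t_rel == 0`` the unclipped limit is
    180 degrees.  Accepts scalars or arrays; raises on negative ``t_rel``.
    """
    t = np.asarray(t_rel, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_rel must be >= 0 (time remaining to collision)")
    with np.errstate(divide="ignore"):
        theta = 2.0 * np.degrees(np.arctan(np.where(t > 0, params.l_over_v / np.maximum(t, 1e-300), np.inf)))
    theta = np.clip(theta, params.theta_init, params.theta_final)
    return float(theta) if np.isscalar(t_rel) else theta


def expansion_window(params: LoomingParams) -> tuple[float, float]:
    """Times-to-collision at which expansion starts and ends.

    Returns ``(onset_t_rel, offset_t_rel)`` with
    ``onset = (l/|v|)/tan(theta_init/2)`` (theta reaches theta_init) and
    ``offset = (l/|v|)/tan(theta_final/2)``; onset > offset.
    """
    onset = params.l_over_v / math.tan(math.radians(params.theta_init) / 2.0)
    offset = params.l_over_v / math.tan(math.radians(params.theta_final) / 2.0)
    return onset, offset


def time_to_theta(params: LoomingParams, theta_deg: float) -> float:
    """Seconds from expansion onset until angular size reaches ``theta_deg``."""
    if not params.theta_init <= theta_deg <= params.theta_final:
        raise ValueError("theta_deg outside [theta_init, theta_final]")
    onset, _ = expansion_window(params)
    t_rel = params.l_over_v / math.tan(math.radians(theta_deg) / 2.0)
    return onset - t_rel


def theta_at(params: LoomingParams, t):
    """Angular size at time ``t`` (seconds) from expansion onset.

    During the hold period (and any later time) the size stays at
    ``theta_final``; negative ``t`` (pre-onset) returns ``theta_init``.
    """
    onset, _ = expansion_window(params)
    t_arr = np.asarray(t, dtype=float)
    t_rel = np.clip(onset - t_arr, 0.0, None)
    theta = angular_size(params, t_rel)
    return theta


# ---------------------------------------------------------------------------
# Rendering and luminance
# ---------------------------------------------------------------------------

def _disk_mask(geom: ScreenGeometry, radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: geom.height_px, : geom.width_px]
    cy = (geom.height_px - 1) / 2.0
    cx = (geom.width_px - 1) / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def _dark_fraction(geom: ScreenGeometry, theta_deg: float) -> float:
    """Fraction of screen pixels covered by the rendered disk (clipped at bounds)."""
    mask = _disk_mask(geom, geom.disk_radius_px(theta_deg))
    return float(mask.sum()) / mask.size


def luminance_profile(params: LoomingParams, geom: ScreenGeometry, t) -> np.ndarray | float:
    """Mean normalized screen luminance at time(s) ``t`` from stimulus onset.

    dark_loom:   background * (1 - dark-pixel fraction of the rendered disk)
    dimming:     identical time course, no rendered edge
    brightening: same time course, inverted polarity (dark -> background)
    checker_loom: constant background (equal-area dark/bright checks)
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    bg = geom.background_level
    if params.kind is StimulusKind.CHECKER_LOOM:
        out = np.full(t_arr.shape, bg)
    else:
        out = np.empty(t_arr.shape)
        for i, ti in enumerate(t_arr):
            if ti < 0:
                out[i] = bg
            else:
                out[i] = bg * (1.0 - _dark_fraction(geom, float(theta_at(params, ti))))
        if params.kind is StimulusKind.BRIGHTENING:
            final = bg * (1.0 - _dark_fraction(geom, params.theta_final))
            out = np.where(t_arr < 0, final, bg + final - out)
    return float(out[0]) if scalar else out


def render_frames(params: LoomingParams, geom: ScreenGeometry) -> np.ndarray:
    """Render the stimulus as a float32 stack in [0, 1], one frame per refresh.

    Frames are sampled at frame centers, ``t_i = (i + 0.5)/refresh_hz``, from
    expansion onset through the end of the hold.  Dark/checker looms draw a
    disk centered on screen; dimming/brightening are uniform fields whose
    level equals :func:`luminance_profile` at that frame time.
    """
    n_frames = max(1, int(round(params.duration_s * params.refresh_hz)))
    times = (np.arange(n_frames) + 0.5) / params.refresh_hz
    bg = geom.background_level
    stack = np.full((n_frames, geom.height_px, geom.width_px), bg, dtype=np.float32)
    if params.kind in (StimulusKind.DIMMING, StimulusKind.BRIGHTENING):
        levels = luminance_profile(params, geom, times)
        stack *= 0.0
        stack += np.asarray(levels, dtype=np.float32)[:, None, None]
        return stack
    if params.kind is StimulusKind.CHECKER_LOOM:
        yy, xx = np.mgrid[: geom.height_px, : geom.width_px]
        checks = ((xx // geom.check_px + yy // geom.check_px) % 2).astype(np.float32)
    for i, ti in enumerate(times):
        mask = _disk_mask(geom, geom.disk_radius_px(float(theta_at(params, ti))))
        if params.kind is StimulusKind.DARK_LOOM:
            stack[i][mask] = 0.0
        else:  # checkerboard disk
            stack[i][mask] = checks[mask]
    return stack


# ---------------------------------------------------------------------------
# Regressors
# ---------------------------------------------------------------------------

@dataclass
class RegressorSet:
    """Stimulus / ISI / motor regressors on a common clock, each max-normalized."""

    time_s: np.ndarray
    stimulus: np.ndarray
    isi: np.ndarray
    motor: np.ndarray | None = None


def _exp_kernel(kernel_tau: float, fs: float) -> np.ndarray:
    """Causal exponential-decay kernel, truncated at 5 tau, unit peak."""
    n = max(2, int(round(5.0 * kernel_tau * fs)))
    return np.exp(-np.arange(n) / (kernel_tau * fs))


def _normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def stimulus_drive(train: StimulusTrain, geom: ScreenGeometry, fs: float,
                   n_samples: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample stimulus drive and on-indicator for a whole train.

    The drive is the normalized angular-size profile for looming kinds, the
    luminance *decrease* for dimming, and the luminance *increase* for
    brightening; zero between trials.  Returns ``(time_s, drive, stim_on)``.
    """
    p = train.params
    if n_samples is None:
        n_samples = int(round(train.end_s * fs))
    time_s = np.arange(n_samples) / fs
    drive = np.zeros(n_samples)
    stim_on = np.zeros(n_samples, dtype=bool)
    # profile within one trial, sampled once
    n_local = int(round(p.duration_s * fs)) + 1
    t_local = np.arange(n_local) / fs
    if p.kind in LOOMING_KINDS:
        theta = theta_at(p, t_local)
        profile = (theta - p.theta_init) / (p.theta_final - p.theta_init)
    else:
        lum = np.atleast_1d(luminance_profile(p, geom, t_local))
        lo, hi = lum.min(), lum.max()
        span = hi - lo if hi > lo else 1.0
        if p.kind is StimulusKind.DIMMING:
            profile = (lum[0] - lum) / span
        else:  # brightening: luminance increase
            profile = (lum - lum[0]) / span
    for onset in train.onsets_s:
        i0 = int(round(onset * fs))
        seg = profile[: max(0, min(n_local, n_samples - i0))]
        if i0 < n_samples and len(seg):
            drive[i0 : i0 + len(seg)] = seg
            stim_on[i0 : i0 + len(seg)] = True
    return time_s, drive, stim_on


def build_regressor(train: StimulusTrain, geom: ScreenGeometry, kernel_tau: float = 3.5,
                    fs: float = 1.0, motor_trace: np.ndarray | None = None,
                    n_samples: int | None = None) -> RegressorSet:
    """Convolve stimulus drive (and ISI / motor signals) with a calcium kernel.

    Each regressor is the corresponding drive convolved with a causal
    exponential kernel ``exp(-t/kernel_tau)`` sampled at ``fs`` and
    max-normalized to unit peak.  The ISI regressor is driven by the
    complement of the stimulus-on indicator; a motor regressor is built from
    ``|motor_trace|`` when one is supplied (resampled to ``fs`` length).
    """
    if fs <= 0 or kernel_tau <= 0:
        raise ValueError("fs and kernel_tau must be positive")
    if train.n_trials == 0 or not train.onsets_s:
        raise ValueError("empty stimulus train")
    time_s, drive, stim_on = stimulus_drive(train, geom, fs, n_samples)
    kernel = _exp_kernel(kernel_tau, fs)
    n = len(time_s)
    stim = _normalize(np.convolve(drive, kernel)[:n])
    isi = _normalize(np.convolve((~stim_on).astype(float), kernel)[:n])
    motor = None
    if motor_trace is not None:
        m = np.abs(np.asarray(motor_trace, dtype=float))
        if len(m) != n:
            m = np.interp(time_s, np.linspace(0, time_s[-1], len(m)), m)
        motor = _normalize(np.convolve(m, kernel)[:n])
    return RegressorSet(time_s=time_s, stimulus=stim, isi=isi, motor=motor)


# ---------------------------------------------------------------------------
# JSON config round-trip
# ---------------------------------------------------------------------------

def train_to_dict(train: StimulusTrain) -> dict:
    p = train.params
    return {
        "params": {
            "kind": p.kind.value, "l_over_v": p.l_over_v, "theta_init": p.theta_init,
            "theta_final": p.theta_final, "hold_s": p.hold_s, "refresh_hz": p.refresh_hz,
            "eye": p.eye.value,
        },
        "n_trials": train.n_trials, "isi_s": train.isi_s, "start_s": train.start_s,
        "onsets_s": list(train.onsets_s),
    }


def train_from_dict(d: dict) -> StimulusTrain:
    return StimulusTrain(
        params=LoomingParams(**d["params"]), n_trials=d["n_trials"], isi_s=d["isi_s"],
        start_s=d.get("start_s", 0.0), onsets_s=tuple(d.get("onsets_s", ())),
    )


def save_train(train: StimulusTrain, path) -> None:
    with open(path, "w") as fh:
        json.dump(train_to_dict(train), fh, indent=2)


def load_train(path) -> StimulusTrain:
    with open(path) as fh:
        return train_from_dict(json.load(fh))
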