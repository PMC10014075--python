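"""Synthetic behavioral sessions, calcium populations, ROI images and tail videos.

Every generator returns its outputs together with a ground-truth manifest so
that each pipeline stage can be tested end to end without real recordings.
The defaults emulate the statistical structure of the reference study's
data: trial-locked escape events whose probability decays exponentially with
repetition over a background of spontaneous Poisson flicks (first-trial
probability 0.6, spontaneous rate 0.0266 Hz, 76% of escapes directed away
from the stimulated eye, escape lead time 1.3 +/- 0.5 s before collision);
ROI populations with planted 4-bit tuning codes whose per-trial peak
amplitudes follow ``a*exp(t*inv_tau) + c`` plus white Gaussian noise;
hemispheric placement with a configurable contralateral bias; and a
configurable GABA-positive fraction.

All randomness flows from a single ``numpy`` Generator seeded per call:
the same config and seed give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .behavior import TailTrace, response_window
from .stimulus import Eye, LoomingParams, ScreenGeometry, StimulusKind, StimulusTrain
from .tuning import BIT_NAMES, KIND_TO_BIT, RoiTraceSet, decimal_to_bits, regressor_segment

# -- reference stimulus parameter sets --------------------------------------

def behavior_params(eye: str = "left") -> LoomingParams:
    """Behavioral-rig dark loom: l/|v| = 240 ms, 4 -> 140 deg, 2.5 s hold."""
    return LoomingParams(kind=StimulusKind.DARK_LOOM, l_over_v=0.240, theta_init=4.0,
                         theta_final=140.0, hold_s=2.5, refresh_hz=20.0, eye=eye)


def imaging_params(kind: StimulusKind | str, eye: str = "left") -> LoomingParams:
    """Imaging-rig stimulus: l/|v| = 480 ms, 3 -> 80 deg, 10 s hold."""
    return LoomingParams(kind=StimulusKind(kind), l_over_v=0.480, theta_init=3.0,
                         theta_final=80.0, hold_s=10.0, refresh_hz=30.0, eye=eye)


def behavior_train(n_trials: int = 10, isi_s: float = 10.0, eye: str = "left",
                   start_s: float = 30.0) -> StimulusTrain:
    """Default behavioral session: 10 dark looms, with a stimulus-free lead-in."""
    return StimulusTrain(params=behavior_params(eye), n_trials=n_trials, isi_s=isi_s,
                         start_s=start_s)


def dynamics_train(n_trials: int = 10, isi_s: float = 40.0, eye: str = "left",
                   start_s: float = 40.0) -> StimulusTrain:
    """Default imaging habituation session: 10 dark looms at ISI 40 s."""
    return StimulusTrain(params=imaging_params(StimulusKind.DARK_LOOM, eye),
                         n_trials=n_trials, isi_s=isi_s, start_s=start_s)


def four_type_session(n_reps: int = 5, isi_s: float = 40.0, eye: str = "left",
                      start_s: float = 40.0) -> dict:
    """Blocked four-type tuning session: dm, dl, br, cb trains in sequence.

    Returns a dict keyed by tuning-code bit name, all trains on one session
    clock (each block starts one ISI after the previous block's last trial
    ends).
    """
    order = [StimulusKind.DIMMING, StimulusKind.DARK_LOOM,
             StimulusKind.BRIGHTENING, StimulusKind.CHECKER_LOOM]
    trains = {}
    t0 = start_s
    for kind in order:
        p = imaging_params(kind, eye)
        train = StimulusTrain(params=p, n_trials=n_reps, isi_s=isi_s, start_s=t0)
        trains[KIND_TO_BIT[kind.value]] = train
        t0 = train.onsets_s[-1] + p.duration_s + isi_s
    return trains


# ---------------------------------------------------------------------------
# Behavioral sessions
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Study conditions for a simulated behavioral cohort.

    Trial ``k`` (0-based) evokes an escape with probability
    ``p1 * exp(-k*ISI / tau_h)``; evoked flick onsets lead the virtual
    collision by a truncated Gaussian (mean 1.3 s, SD 0.5 s) restricted to
    the validity window, and point away from the stimulated eye with
    probability ``away_prob``.  Spontaneous flicks are a Poisson process at
    ``lambda_spont`` over the whole session.  The tail flick is a half-sine
    bend (optionally followed by a counter-bend) on white tracking noise.
    """

    n_fish: int = 20
    train: StimulusTrain = field(default_factory=behavior_train)
    p1: float = 0.6
    tau_h: float = 60.0
    lambda_spont: float = 0.0266
    away_prob: float = 0.76
    lead_mean_s: float = 1.3
    lead_sd_s: float = 0.5
    flick_amp_mean_mm: float = 1.0
    flick_amp_sd_mm: float = 0.2
    flick_min_amp_mm: float = 0.45
    flick_duration_s: float = 0.3
    counterbend_ratio: float = 0.5
    noise_sd_mm: float = 0.05
    fps: float = 120.0
    tail_s: float = 30.0

    def __post_init__(self) -> None:
        for p in (self.p1, self.away_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.lambda_spont < 0:
            raise ValueError("lambda_spont must be >= 0")
        t_lo, t_hi = response_window(self.train, "main")
        period = self.train.params.duration_s + self.train.isi_s
        if t_hi > period:
            raise ValueError("ISI too short: validity window overlaps the next trial")


def _half_sine(amp: float, duration_s: float, fps: float) -> np.ndarray:
    n = max(2, int(round(duration_s * fps)))
    return amp * np.sin(np.linspace(0.0, np.pi, n))


def _add_waveform(trace: np.ndarray, i0: int, wf: np.ndarray) -> None:
    i0 = max(0, i0)
    seg = wf[: max(0, len(trace) - i0)]
    trace[i0 : i0 + len(seg)] += seg


def simulate_behavior_session(cfg: BehaviorSimConfig, seed: int
                              ) -> tuple[list[TailTrace], dict]:
    """Simulate tail-deflection traces for a cohort of fish.

    Returns one :class:`TailTrace` per fish and a truth manifest listing, for
    every fish, the per-trial escape flags and every generated event
    (onset time, signed amplitude, evoked/spontaneous, trial index).
    """
    rng = np.random.default_rng(seed)
    train = cfg.train
    p = train.params
    t_lo, t_hi = response_window(train, "main")
    session_len = train.onsets_s[-1] + p.duration_s + train.isi_s + cfg.tail_s
    n_samp = int(round(session_len * cfg.fps))
    n_trials = train.n_trials
    p_trial = cfg.p1 * np.exp(-np.arange(n_trials) * train.isi_s / cfg.tau_h)
    # evoked lead-time truncation: lead in [-1 s, collision - window start]
    lead_lo, lead_hi = -1.0, p.collision_s - t_lo
    a_tn = (lead_lo - cfg.lead_mean_s) / cfg.lead_sd_s
    b_tn = (lead_hi - cfg.lead_mean_s) / cfg.lead_sd_s

    traces, fish_truth = [], []
    for _ in range(cfg.n_fish):
        trace = np.zeros(n_samp)
        events = []
        responded = rng.random(n_trials) < p_trial
        for k, onset in enumerate(train.onsets_s):
            if not responded[k]:
                continue
            lead = float(truncnorm.rvs(a_tn, b_tn, loc=cfg.lead_mean_s,
                                       scale=cfg.lead_sd_s, random_state=rng))
            t_ev = onset + p.collision_s - lead
            amp = max(cfg.flick_min_amp_mm,
                      rng.normal(cfg.flick_amp_mean_mm, cfg.flick_amp_sd_mm))
            sign = -1.0 if rng.random() < cfg.away_prob else 1.0
            events.append({"t_s": t_ev, "amp_mm": sign * amp, "kind": "evoked", "trial": k})
        n_spont = rng.poisson(cfg.lambda_spont * session_len)
        for t_ev in np.sort(rng.uniform(0.0, session_len, n_spont)):
            amp = max(cfg.flick_min_amp_mm,
                      rng.normal(cfg.flick_amp_mean_mm, cfg.flick_amp_sd_mm))
            sign = -1.0 if rng.random() < 0.5 else 1.0
            events.append({"t_s": float(t_ev), "amp_mm": sign * amp,
                           "kind": "spontaneous", "trial": None})
        for ev in events:
            wf = _half_sine(ev["amp_mm"], cfg.flick_duration_s, cfg.fps)
            i0 = int(round(ev["t_s"] * cfg.fps))
            _add_waveform(trace, i0, wf)
            if cfg.counterbend_ratio > 0 and ev["kind"] == "evoked":
                cb = _half_sine(-ev["amp_mm"] * cfg.counterbend_ratio,
                                cfg.flick_duration_s / 2.0, cfg.fps)
                _add_waveform(trace, i0 + len(wf), cb)
        if cfg.noise_sd_mm > 0:
            trace += rng.normal(0.0, cfg.noise_sd_mm, n_samp)
        traces.append(TailTrace(deflection_mm=trace, fps=cfg.fps))
        fish_truth.append({"responded": responded.tolist(),
                           "events": sorted(events, key=lambda e: e["t_s"])})
    truth = {
        "responded_matrix": [f["responded"] for f in fish_truth],
        "fish": fish_truth,
        "p_trial": p_trial.tolist(),
        "validity_window_s": [t_lo, t_hi],
        "session_len_s": session_len,
        "config": {k: v for k, v in asdict(cfg).items() if k != "train"},
    }
    return traces, truth


# ---------------------------------------------------------------------------
# Calcium populations
# ---------------------------------------------------------------------------

#: dynamics-class inv_tau distributions (mean, sd), s^-1.  The depressing and
#: near-zero (stable) values follow the reference double-Gaussian components;
#: the potentiating rate is a moderate growth (~6x over a 10-trial ISI-40
#: session).
DYN_CLASS_INV_TAU = {
    "depressing": (-7.5e-3, 1.5e-3),
    "potentiating": (5.0e-3, 1.5e-3),
    "stable": (-3.76e-5, 2.25e-5),
}


@dataclass
class PopulationSpec:
    """One homogeneous simulated cell population.

    ``code`` is the planted tuning code (decimal 0-15); amplitudes follow
    ``a*exp(t*inv_tau) + c`` with per-cell ``a ~ N(a_mean, a_sd)`` (floored at
    a tenth of the mean), ``inv_tau`` drawn from the class distribution (or
    ``inv_tau_range`` uniformly if given) and constant ``c``.  ``p_contra``
    is the probability of placement contralateral to the stimulated eye;
    ``binocular_fraction`` of cells respond to either eye, the rest are
    monocular for the stimulated eye.
    """

    n_cells: int
    code: int
    dyn_class: str = "stable"
    inv_tau_range: tuple | None = None
    a_mean: float = 1.0
    a_sd: float = 0.1
    c: float = 0.1
    p_contra: float = 0.93
    gaba_fraction: float = 0.1
    binocular_fraction: float = 0.0
    name: str = ""


@dataclass
class CalciumSimConfig:
    """Simulated imaging session: populations + acquisition parameters.

    ``snr`` sets the trace noise SD as ``a_ref / snr`` where ``a_ref`` is the
    mean response amplitude over populations; ``trains`` maps tuning-code bit
    names to stimulus trains on one session clock.
    """

    populations: list = field(default_factory=lambda: [
        # DS cells sit in both hemispheres (HI ~ 0); LS cells are strongly
        # contralateral to the stimulated eye (HI ~ -0.86)
        PopulationSpec(n_cells=60, code=12, dyn_class="depressing", p_contra=0.49,
                       name="DS_dep"),
        PopulationSpec(n_cells=30, code=12, dyn_class="potentiating", p_contra=0.49,
                       binocular_fraction=0.33, gaba_fraction=0.25, name="DS_pot"),
        PopulationSpec(n_cells=50, code=5, dyn_class="depressing", p_contra=0.93,
                       name="LS"),
        PopulationSpec(n_cells=30, code=2, dyn_class="stable", p_contra=0.5, name="BR"),
        PopulationSpec(n_cells=30, code=0, p_contra=0.5, name="untuned"),
    ])
    trains: dict = field(default_factory=four_type_session)
    fs: float = 1.0
    kernel_tau: float = 3.5
    snr: float = 5.0
    n_fish: int = 5
    pad_s: float = 40.0

    @property
    def noise_sd(self) -> float:
        a_ref = float(np.mean([p.a_mean for p in self.populations]))
        return a_ref / self.snr


def simulate_calcium_population(cfg: CalciumSimConfig, seed: int
                                ) -> tuple[RoiTraceSet, pd.DataFrame]:
    """Simulate ROI fluorescence traces with known tuning and dynamics.

    Each cell responds to every trial of the stimulus types set in its
    tuning code with per-trial amplitude ``a*exp(t_k*inv_tau) + c`` (``t_k``
    seconds since the first trial of that type's train) scaled onto the
    unit-peak single-trial calcium regressor, plus white Gaussian noise.
    ``t_k`` is measured from the first trial of that stimulus type's own
    train, so each tuned pathway habituates with its own exposure.
    Returns the trace set and a truth table with one row per cell (code,
    dynamics class and parameters, hemisphere, GABA flag, binocularity).
    """
    rng = np.random.default_rng(seed)
    geom = ScreenGeometry(width_px=128, height_px=128, px_per_degree=1.0)
    fs = cfg.fs
    session_end = max(tr.onsets_s[-1] + tr.params.duration_s for tr in cfg.trains.values())
    n_frames = int(round((session_end + cfg.pad_s) * fs))
    # unit-peak single-trial response per stimulus type
    waveforms = {}
    for bit, tr in cfg.trains.items():
        w = int(round((tr.params.duration_s + 5.0 * cfg.kernel_tau) * fs))
        waveforms[bit] = regressor_segment(tr.params, geom, cfg.kernel_tau, fs, w)
    stim_eye = next(iter(cfg.trains.values())).params.eye
    contra = "right" if stim_eye == Eye.LEFT else "left"
    ipsi = "left" if contra == "right" else "right"

    n_total = sum(p.n_cells for p in cfg.populations)
    F = np.zeros((n_total, n_frames))
    rows = []
    i = 0
    for pop in cfg.populations:
        bits = decimal_to_bits(pop.code)
        for _ in range(pop.n_cells):
            a = max(rng.normal(pop.a_mean, pop.a_sd), 0.1 * pop.a_mean)
            if pop.inv_tau_range is not None:
                inv_tau = float(rng.uniform(*pop.inv_tau_range))
            else:
                mu, sd = DYN_CLASS_INV_TAU[pop.dyn_class]
                inv_tau = float(rng.normal(mu, sd))
            for bit in BIT_NAMES:
                if not bits[bit] or bit not in cfg.trains:
                    continue
                tr = cfg.trains[bit]
                wf = waveforms[bit]
                for onset in tr.onsets_s:
                    # habituation clock runs per stimulus type: each pathway
                    # habituates with its own stimulus exposure
                    t_k = onset - tr.onsets_s[0]
                    amp = a * np.exp(inv_tau * t_k) + pop.c
                    _add_waveform(F[i], int(round(onset * fs)), amp * wf)
            hemi = contra if rng.random() < pop.p_contra else ipsi
            binoc = rng.random() < pop.binocular_fraction
            rows.append({"cell": i, "population": pop.name, "code": pop.code,
                         **{f"bit_{b}": bits[b] for b in BIT_NAMES},
                         "dyn_class": pop.dyn_class, "a": a, "inv_tau": inv_tau,
                         "c": pop.c, "hemisphere": hemi,
                         "gaba": bool(rng.random() < pop.gaba_fraction),
                         "binocular": binoc,
                         "eye": "both" if binoc else stim_eye.value})
            i += 1
    if cfg.noise_sd > 0:
        F += rng.normal(0.0, cfg.noise_sd, F.shape)
    truth = pd.DataFrame(rows)
    rois = RoiTraceSet(F=F, fs=fs, roi_ids=np.arange(n_total),
                       fish_ids=rng.integers(0, cfg.n_fish, n_total))
    truth["fish_id"] = rois.fish_ids
    return rois, truth


# ---------------------------------------------------------------------------
# ROI label masks and red-channel images
# ---------------------------------------------------------------------------

@dataclass
class ImageSimConfig:
    """Planted ROI mask + red-channel pair for GABA calling.

    Each ROI is an ellipse on a jittered grid; the red channel covers an
    exact planted fraction of each ROI's pixels (> 0.7 for planted-GABA
    cells, below for the rest).  ``coverages`` overrides the per-ROI planted
    fraction list explicitly.
    """

    height: int = 192
    width: int = 192
    n_rois: int = 24
    radius_px: int = 5
    gaba_fraction: float = 0.3
    coverage_gaba: float = 0.9
    coverage_non: float = 0.4
    coverages: list | None = None
    red_fg: float = 200.0
    red_bg: float = 8.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.height < 128 or self.width < 128:
            raise ValueError("canvas must be at least 128 x 128")


def simulate_roi_images(cfg: ImageSimConfig, seed: int
                        ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a uint16 ROI label mask, a red-channel image and the truth table.

    The red label covers an exact pixel count per ROI, so the planted
    coverage fraction is reproduced by pixel counting to 1/|ROI| resolution.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((cfg.height, cfg.width), dtype=np.uint16)
    red = np.full((cfg.height, cfg.width), cfg.red_bg, dtype=float)
    r = cfg.radius_px
    pitch = 4 * r
    centers = [(y, x)
               for y in range(2 * r + 2, cfg.height - 2 * r - 2, pitch)
               for x in range(2 * r + 2, cfg.width - 2 * r - 2, pitch)]
    if len(centers) < cfg.n_rois:
        raise ValueError("canvas too small to place the requested ROIs")
    order = rng.permutation(len(centers))[: cfg.n_rois]
    if cfg.coverages is not None:
        coverages = list(cfg.coverages)
        if len(coverages) != cfg.n_rois:
            raise ValueError("coverages must have one entry per ROI")
        gaba_planted = [c > 0.7 for c in coverages]
    else:
        gaba_planted = (rng.random(cfg.n_rois) < cfg.gaba_fraction).tolist()
        coverages = [cfg.coverage_gaba if g else cfg.coverage_non for g in gaba_planted]
    rows = []
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for k, ci in enumerate(order):
        cy, cx = centers[ci]
        cy += int(rng.integers(-2, 3))
        cx += int(rng.integers(-2, 3))
        ry, rx = r, max(2, r - 1)
        sel = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        sel &= mask == 0
        mask[sel] = k + 1
        pix = np.argwhere(mask == k + 1)
        n_red = int(round(coverages[k] * len(pix)))
        # rounding to whole pixels must not cross the 70% call boundary
        crit = 0.7 * len(pix)
        if coverages[k] > 0.7:
            n_red = max(n_red, int(np.floor(crit)) + 1)
        else:
            n_red = min(n_red, int(np.floor(crit)))
        for py, px in pix[:n_red]:
            red[py, px] = cfg.red_fg
        actual = n_red / len(pix)
        rows.append({"roi_id": k + 1, "n_pixels": int(len(pix)),
                     "planted_coverage": coverages[k], "actual_coverage": actual,
                     "gaba": actual > 0.7})
    if cfg.noise_sd > 0:
        red += rng.normal(0.0, cfg.noise_sd, red.shape)
    return mask, red, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tail videos
# ---------------------------------------------------------------------------

@dataclass
class VideoSimConfig:
    """Rendered tail video with known deflection and optional fin flicker.

    The tail is a 10-point polyline along x whose lateral offsets follow a
    quadratic profile scaled so that the mean point offset equals the planted
    deflection trace.  Fin patches carry a fixed random texture whose
    intensity ramps as a sawtooth at ``fin_freq_hz`` (one sharp frame-to-frame
    jump per beat).
    """

    width: int = 160
    height: int = 120
    fps: float = 50.0
    duration_s: float = 8.0
    px_per_mm: float = 10.0
    deflection_mm: np.ndarray | None = None
    fin_freq_hz: float = 0.0
    fin_stop_s: float | None = None
    n_points: int = 10

    def __post_init__(self) -> None:
        if self.width > 256 or self.height > 256 or self.duration_s * self.fps > 2000:
            raise ValueError("video too large; keep <= 256 x 256 and <= 2000 frames")


def tail_point_columns(cfg: VideoSimConfig) -> np.ndarray:
    """x pixel positions of the rendered tail points (head to tip)."""
    x0 = 10
    x1 = int(cfg.width * 0.75)
    return np.linspace(x0, x1, cfg.n_points).round().astype(int)


def _offset_weights(n_points: int) -> np.ndarray:
    s = (np.arange(n_points) + 0.5) / n_points
    w = s**2
    return w / w.mean()


def fin_windows(cfg: VideoSimConfig) -> tuple[tuple, tuple]:
    """(y0, y1, x0, x1) windows of the two rendered fin patches."""
    x0 = int(cfg.width * 0.80)
    return ((8, 24, x0, x0 + 16), (cfg.height - 24, cfg.height - 8, x0, x0 + 16))


def simulate_tail_video(cfg: VideoSimConfig, seed: int) -> tuple[np.ndarray, dict]:
    """Render a grayscale uint8 stack of a moving tail (plus fin patches).

    Returns the stack and a truth dict with the planted per-frame mean
    deflection (mm), the true tail-point coordinates, and the fin beat
    frequency.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(cfg.duration_s * cfg.fps))
    defl = (np.zeros(n_frames) if cfg.deflection_mm is None
            else np.asarray(cfg.deflection_mm, dtype=float))
    if len(defl) != n_frames:
        raise ValueError("deflection_mm length must equal duration * fps")
    stack = np.zeros((n_frames, cfg.height, cfg.width), dtype=np.uint8)
    xs = tail_point_columns(cfg)
    w = _offset_weights(cfg.n_points)
    y_mid = cfg.height / 2.0
    pts = np.empty((n_frames, cfg.n_points, 2))
    for f in range(n_frames):
        ys = y_mid + defl[f] * cfg.px_per_mm * w
        pts[f, :, 0] = xs
        pts[f, :, 1] = ys
        for x, y in zip(xs, ys):
            yi = int(round(y))
            stack[f, max(0, yi - 1): yi + 2, max(0, x - 1): x + 2] = 255
    truth = {"deflection_mm": defl, "points_px": pts, "fin_freq_hz": cfg.fin_freq_hz,
             "y_mid_px": y_mid, "px_per_mm": cfg.px_per_mm}
    if cfg.fin_freq_hz > 0:
        t = np.arange(n_frames) / cfg.fps
        ramp = (cfg.fin_freq_hz * t) % 1.0
        if cfg.fin_stop_s is not None:
            ramp[t >= cfg.fin_stop_s] = ramp[np.searchsorted(t, cfg.fin_stop_s)]
        for win in fin_windows(cfg):
            y0, y1, x0, x1 = win
            pattern = rng.integers(0, 120, (y1 - y0, x1 - x0))
            patch = (pattern[None, :, :] * ramp[:, None, None]).astype(np.uint8)
            stack[:, y0:y1, x0:x1] = np.maximum(stack[:, y0:y1, x0:x1], patch)
    return stack, truth


def track_tail_points(stack: np.ndarray, cfg: VideoSimConfig) -> np.ndarray:
    """Recover per-frame tail-point coordinates by intensity centroid.

    For each rendered tail-point column band, the y position is the
    brightness-weighted centroid; returns (n_frames, n_points, 2) (x, y) px.
    """
    xs = tail_point_columns(cfg)
    n_frames = stack.shape[0]
    pts = np.empty((n_frames, len(xs), 2))
    half = 2
    ys_grid = np.arange(stack.shape[1], dtype=float)
    for f in range(n_frames):
        for i, x in enumerate(xs):
            band = stack[f, :, max(0, x - half): x + half + 1].astype(float)
            wsum = band.sum()
            y = float((band.sum(axis=1) * ys_grid).sum() / wsum) if wsum > 0 else np.nan
            pts[f, i] = (x, y)
    return pts
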