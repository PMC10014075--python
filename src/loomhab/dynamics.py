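"""Per-cell habituation dynamics: exponential amplitude fits and classification.

For each cell, the peak calcium response amplitude is extracted for every
trial and the trend across trials is quantified by nonlinear least squares
with the model

    peak(t) = a * exp(t * inv_tau) + c

where ``t`` is the time of each peak in seconds since the first stimulus
onset and ``inv_tau = 1/tau`` (s^-1).  The population histogram of well-fit
``inv_tau`` values shows a large near-zero peak plus a prominent negative
peak; a double-Gaussian fit to it yields classification thresholds at the
near-zero component's mean +/- half its full width at half maximum.  Cells
are then labelled depressing (inv_tau below the negative threshold),
potentiating (above the positive threshold) or stable (between); cells whose
exponential fit is ill-constrained are labelled by the sign of inv_tau only
and never count as stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import kruskal

from .stimulus import StimulusTrain

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PeakSeries:
    """Per-trial response peaks for one cell.

    ``t_s`` is the time of each peak in seconds from the first stimulus
    onset; ``responded`` marks trials whose peak exceeded the response
    criterion (``criterion_sd`` times the pre-onset noise SD).
    """

    t_s: np.ndarray
    peak: np.ndarray
    responded: np.ndarray
    roi_id: object = None

    @property
    def n_responded(self) -> int:
        return int(np.sum(self.responded))


@dataclass
class ExpFit:
    """Exponential amplitude-dynamics fit ``a*exp(t*inv_tau) + c`` for one cell.

    ``well_fit`` is decided at the population level: the 95% CI on
    ``inv_tau`` must be narrower than 10x the population's largest |inv_tau|.
    """

    a: float
    inv_tau: float
    c: float
    ci_inv_tau: tuple
    n_responded: int
    roi_id: object = None
    well_fit: bool | None = None

    @property
    def ci_width(self) -> float:
        return self.ci_inv_tau[1] - self.ci_inv_tau[0]


@dataclass
class RateThresholds:
    """Population thresholds on inv_tau from the double-Gaussian histogram fit.

    ``near_zero`` and ``second`` are (mean, sd, amplitude) of the two
    components, with ``near_zero`` the one whose mean is closest to zero.
    """

    pos_thr: float
    neg_thr: float
    near_zero: tuple = (np.nan, np.nan, np.nan)
    second: tuple = (np.nan, np.nan, np.nan)
    bin_width: float = np.nan

    def __post_init__(self) -> None:
        if not self.neg_thr < self.pos_thr:
            raise ValueError("need neg_thr < pos_thr")


def extract_peak_series(trace: np.ndarray, train: StimulusTrain, fs: float,
                        response_window_s: float | None = None, baseline_s: float = 5.0,
                        criterion_sd: float = 2.0, roi_id=None) -> PeakSeries:
    """Per-trial baseline-subtracted response peaks of a fluorescence trace.

    For each trial the baseline (mean of ``baseline_s`` pre-onset) is
    subtracted and the peak is the maximum in the response window (default:
    stimulus duration + 10 s, truncated at the trial period).  A trial counts
    as responded when its peak exceeds ``criterion_sd`` times the pooled
    pre-onset noise SD.
    """
    trace = np.asarray(trace, dtype=float)
    p = train.params
    period = p.duration_s + train.isi_s
    if response_window_s is None:
        response_window_s = min(p.duration_s + 10.0, period)
    if response_window_s > period + 1e-9:
        raise ValueError("response window longer than the trial period (windows overlap)")
    w = int(round(response_window_s * fs))
    nb = int(round(baseline_s * fs))
    onsets = np.round(np.asarray(train.onsets_s) * fs).astype(int)
    base_segs = [trace[max(0, f0 - nb): f0] for f0 in onsets if f0 > 0]
    noise_sd = float(np.std(np.concatenate(base_segs))) if base_segs else 0.0
    t_s, peaks = [], []
    for f0 in onsets:
        if f0 + w > len(trace):
            raise ValueError("trial window outside the recording")
        base = trace[max(0, f0 - nb): f0]
        seg = trace[f0 : f0 + w] - (base.mean() if len(base) else 0.0)
        i = int(np.argmax(seg))
        peaks.append(float(seg[i]))
        t_s.append((f0 + i) / fs - train.onsets_s[0])
    peaks = np.asarray(peaks)
    responded = peaks > criterion_sd * noise_sd
    return PeakSeries(t_s=np.asarray(t_s), peak=peaks, responded=responded, roi_id=roi_id)


def _model(t, a, inv_tau, c):
    return a * np.exp(np.clip(t * inv_tau, -700, 700)) + c


def fit_exponential(series: PeakSeries, min_responded: int = 3,
                    c_allowance: float = 0.1) -> ExpFit | None:
    """Nonlinear least-squares fit of ``a*exp(t*inv_tau) + c`` to the peaks.

    Requires at least ``min_responded`` responded trials (cells below that are
    excluded from the dynamics analysis: returns None).

    The fit is bounded: ``a >= 0`` (the exponential term is a response
    amplitude), ``|inv_tau| <= 0.5`` and ``c <= min(peak) + c_allowance *
    range(peak)`` — the offset is the non-habituating floor of the series.
    Without the ``c`` ceiling the three-parameter model is weakly identified
    on flat series (``c`` can absorb all but one point, letting ``inv_tau``
    wander to arbitrary values driven by noise curvature).

    Initialization for decreasing series: ``c0`` = last peak, ``a0`` =
    first - last peak, ``inv_tau0`` from a log-linear regression of
    ``peak - c0``; flat or growing series use a floor just below the minimum
    instead.  The 95% CI on ``inv_tau`` comes from the linearized fit
    covariance.
    """
    if series.n_responded < min_responded:
        return None
    t = np.asarray(series.t_s, dtype=float)
    y = np.asarray(series.peak, dtype=float)
    ymax = float(np.max(np.abs(y))) + 1e-12
    ptp = float(np.ptp(y)) + 1e-12
    c_hi = float(np.min(y)) + c_allowance * ptp
    a0 = y[0] - y[-1]
    if a0 > 0:                       # decreasing: the canonical habituation case
        c0 = min(y[-1], c_hi)
        resid = y - c0
        ok = resid > 1e-12 * max(1.0, a0)
        inv_tau0 = -1e-3
        if ok.sum() >= 2:
            slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
            if np.isfinite(slope):
                inv_tau0 = float(np.clip(slope, -0.5, 0.5))
    else:                            # flat or growing: floor below the data
        c0 = float(np.min(y)) - 0.05 * ptp
        resid = np.clip(y - c0, 1e-12, None)
        inv_tau0, log_a0 = np.polyfit(t, np.log(resid), 1)
        inv_tau0 = float(np.clip(inv_tau0, -0.5, 0.5))
        a0 = float(np.exp(log_a0))
    a0 = float(np.clip(a0, 1e-9, 5.0 * ymax))
    try:
        popt, pcov = curve_fit(_model, t, y, p0=[a0, inv_tau0, min(c0, c_hi)],
                               bounds=([0.0, -0.5, -2.0 * ymax], [5.0 * ymax, 0.5, c_hi]),
                               maxfev=20000)
    except RuntimeError:
        return ExpFit(a=np.nan, inv_tau=np.sign(y[-1] - y[0]) * np.inf if y[-1] != y[0] else 0.0,
                      c=np.nan, ci_inv_tau=(-np.inf, np.inf),
                      n_responded=series.n_responded, roi_id=series.roi_id)
    a, inv_tau, c = (float(v) for v in popt)
    sd = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    ci = (inv_tau - 1.96 * sd, inv_tau + 1.96 * sd)
    return ExpFit(a=a, inv_tau=inv_tau, c=c, ci_inv_tau=ci,
                  n_responded=series.n_responded, roi_id=series.roi_id)


def flag_well_fit(fits: list[ExpFit]) -> float:
    """Apply the population ill-fit rule in place; returns the CI-width bound.

    A fit is well constrained when its 95% CI on inv_tau is narrower than
    10x the largest |inv_tau| in the population.
    """
    finite = [f for f in fits if np.isfinite(f.inv_tau)]
    if not finite:
        raise ValueError("no finite fits")
    bound = 10.0 * max(abs(f.inv_tau) for f in finite)
    for f in fits:
        f.well_fit = bool(np.isfinite(f.inv_tau) and np.isfinite(f.ci_width)
                          and f.ci_width < bound)
    return bound


def rate_thresholds(inv_taus: np.ndarray, bins="fd",
                    override: tuple[float, float] | None = None) -> RateThresholds:
    """Classification thresholds from a double-Gaussian fit to the inv_tau histogram.

    The histogram of well-fit ``inv_tau`` values is fit with a sum of
    Gaussians, one per prominent histogram peak (at least the near-zero and
    one more); the component whose mean is closest to zero is the near-zero
    peak and the thresholds are its mean +/- FWHM/2, with the most prominent
    remaining component reported as ``second``.  Histogram edges are
    aligned so that zero sits at a bin center (the near-zero peak can be much
    narrower than one bin; centering keeps it from being split or shifted by
    edge placement).  ``override=(pos, neg)`` bypasses the fit and passes
    externally supplied thresholds through (e.g. published constants).
    """
    if override is not None:
        pos, neg = override
        return RateThresholds(pos_thr=float(pos), neg_thr=float(neg))
    x = np.asarray(inv_taus, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("too few inv_tau values for a histogram fit")
    if isinstance(bins, str):
        h = float(np.histogram_bin_edges(x, bins=bins)[1]
                  - np.histogram_bin_edges(x, bins=bins)[0])
    else:
        h = float(np.ptp(x)) / int(bins)
    k_lo = int(np.floor(x.min() / h + 0.5)) - 1
    k_hi = int(np.ceil(x.max() / h - 0.5)) + 1
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * h   # bin centers at integer multiples of h
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    bw = float(edges[1] - edges[0])
    # One Gaussian per prominent histogram peak (at least two).  Anchoring a
    # component on every peak keeps the near-zero component from migrating or
    # broadening to soak up an extra mode the two-component model would
    # otherwise leave unexplained.
    pk, props = find_peaks(counts, prominence=max(1.0, 0.05 * counts.max()))
    if len(pk) < 2:
        extra = [i for i in np.argsort(counts)[::-1] if i not in set(pk.tolist())]
        pk = np.sort(np.concatenate([pk, extra[: 2 - len(pk)]]).astype(int))
    pk = np.sort(pk[np.argsort(counts[pk])[::-1][:3]])   # at most three components
    span = centers[-1] - centers[0] + bw
    p0, lo, hi = [], [], []
    for i in pk:
        # sigma floor: a component narrower than one bin is unresolvable
        p0 += [counts[i], centers[i], bw]
        lo += [0.0, centers[i] - 2 * bw, bw]
        hi += [2.0 * counts.sum(), centers[i] + 2 * bw, span]
    def model(xx, *params):
        out = np.zeros_like(xx, dtype=float)
        for j in range(0, len(params), 3):
            A, mu, s = params[j : j + 3]
            out += A * np.exp(-0.5 * ((xx - mu) / s) ** 2)
        return out
    try:
        popt, _ = curve_fit(model, centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"Gaussian-mixture histogram fit failed: {err}") from err
    comps = [(float(popt[j + 1]), float(popt[j + 2]), float(popt[j]))
             for j in range(0, len(popt), 3)]
    if any(not np.isfinite(s) or s <= 0 for _, s, _ in comps):
        raise ValueError("degenerate Gaussian fit (component width collapsed)")
    comps.sort(key=lambda c: abs(c[0]))
    near = comps[0]
    second = max(comps[1:], key=lambda c: c[2] * c[1])  # largest remaining area
    mu1, s1, _ = near
    half = FWHM_PER_SIGMA * s1 / 2.0
    return RateThresholds(pos_thr=float(mu1 + half), neg_thr=float(mu1 - half),
                          near_zero=near, second=second, bin_width=bw)


def classify_dynamics(inv_tau: float, thresholds: RateThresholds,
                      well_fit: bool = True) -> str:
    """Label one cell depressing / potentiating / stable.

    Well-fit cells use the thresholds; ill-fit cells are assigned to the
    depressing or potentiating group by the sign of their exponent alone
    (never stable).
    """
    if well_fit:
        if inv_tau < thresholds.neg_thr:
            return "depressing"
        if inv_tau > thresholds.pos_thr:
            return "potentiating"
        return "stable"
    return "depressing" if inv_tau < 0 else "potentiating"


def classify_population(fits: list[ExpFit], thresholds: RateThresholds | None = None,
                        bins="fd") -> tuple[pd.DataFrame, RateThresholds]:
    """Threshold derivation + classification for a population of fits.

    Applies the ill-fit rule, derives thresholds from the well-fit cells'
    inv_tau histogram (unless supplied), and labels every fitted cell.
    """
    fits = [f for f in fits if f is not None]
    flag_well_fit(fits)
    if thresholds is None:
        well = np.array([f.inv_tau for f in fits if f.well_fit])
        thresholds = rate_thresholds(well, bins=bins)
    rows = []
    for f in fits:
        rows.append({"roi_id": f.roi_id, "a": f.a, "inv_tau": f.inv_tau, "c": f.c,
                     "ci_lo": f.ci_inv_tau[0], "ci_hi": f.ci_inv_tau[1],
                     "well_fit": f.well_fit, "n_responded": f.n_responded,
                     "dyn_class": classify_dynamics(f.inv_tau, thresholds, f.well_fit)})
    return pd.DataFrame(rows), thresholds


def covert_depression_contrast(peaks: pd.DataFrame) -> pd.DataFrame:
    """Group statistics for the pre-exposure (covert depression) experiment.

    ``peaks`` has one row per cell x trial with columns ``condition``
    (``dimming`` — intervening dimming stimulation — or ``wait``), ``trial``
    (1, 10 and 11: last pre trial, end of habituation, first test trial) and
    ``peak``.  Returns per-condition/trial medians and SEs plus
    Kruskal-Wallis p-values for the within-condition trial 1 vs 10 contrasts
    and the across-condition trial-11 contrast.  Groups with identical values
    throughout (rank ties only) report p = 1.
    """
    for col in ("condition", "trial", "peak"):
        if col not in peaks.columns:
            raise ValueError(f"missing column {col!r}")
    needed = {1, 10, 11}
    rows = []
    for cond, sub in peaks.groupby("condition"):
        trials = set(sub["trial"].unique())
        if not needed <= trials:
            raise ValueError(f"condition {cond!r} missing trials {needed - trials}")
        for tr in sorted(needed):
            v = sub.loc[sub["trial"] == tr, "peak"].to_numpy(dtype=float)
            rows.append({"condition": cond, "trial": tr, "n": len(v),
                         "median": float(np.median(v)),
                         "se": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                         "contrast": "", "p_value": np.nan})
        g1 = sub.loc[sub["trial"] == 1, "peak"].to_numpy(dtype=float)
        g10 = sub.loc[sub["trial"] == 10, "peak"].to_numpy(dtype=float)
        rows.append({"condition": cond, "trial": -1, "n": len(g1) + len(g10),
                     "median": np.nan, "se": np.nan,
                     "contrast": "trial1_vs_trial10", "p_value": _kw_p(g1, g10)})
    conds = sorted(peaks["condition"].unique())
    if len(conds) == 2:
        a = peaks.loc[(peaks["condition"] == conds[0]) & (peaks["trial"] == 11), "peak"]
        b = peaks.loc[(peaks["condition"] == conds[1]) & (peaks["trial"] == 11), "peak"]
        rows.append({"condition": "+".join(conds), "trial": 11, "n": len(a) + len(b),
                     "median": np.nan, "se": np.nan,
                     "contrast": "trial11_across_conditions",
                     "p_value": _kw_p(a.to_numpy(float), b.to_numpy(float))})
    return pd.DataFrame(rows)


def _kw_p(*groups) -> float:
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 1.0  # all observations tied: no evidence of a difference
    return float(kruskal(*groups).pvalue)
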