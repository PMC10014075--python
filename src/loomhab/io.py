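"""Readers/writers, pipeline configuration and the end-to-end synthetic pipeline.

CSV is the canonical table format (long layout, one row per entity x
observation); stimulus trains and configs are JSON (or YAML), images are
TIFF.  ``run_pipeline`` chains every stage on synthetic data — behavior
detection and habituation curve, tuning codes, amplitude dynamics,
laterality and GABA calling — deterministically for a given seed, and
writes a run report with record counts and summary statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import behavior as bhv
from . import dynamics as dyn
from . import laterality as lat
from . import synthetic as syn
from . import tuning as tun
from .stimulus import StimulusTrain, train_from_dict, train_to_dict


# ---------------------------------------------------------------------------
# Tables, images, configs
# ---------------------------------------------------------------------------

def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking that the required columns are present."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(arr: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr)
    return path


def events_to_table(events: list[bhv.FlickEvent], fish_id=0) -> pd.DataFrame:
    return pd.DataFrame([{
        "fish_id": fish_id, "onset_s": e.onset_s, "peak_s": e.peak_s,
        "peak_amp_mm": e.peak_amp_mm, "counter_peak_amp_mm": e.counter_peak_amp_mm,
        "type_label": e.type_label, "provenance": e.provenance,
    } for e in events])


def events_from_table(df: pd.DataFrame) -> list[bhv.FlickEvent]:
    req = ["onset_s", "peak_s", "peak_amp_mm"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing column(s) {', '.join(missing)}")
    out = []
    for _, r in df.iterrows():
        cp = r.get("counter_peak_amp_mm")
        out.append(bhv.FlickEvent(
            onset_s=float(r["onset_s"]), peak_s=float(r["peak_s"]),
            peak_amp_mm=float(r["peak_amp_mm"]),
            counter_peak_amp_mm=None if pd.isna(cp) else float(cp),
            provenance=str(r.get("provenance", "unassigned"))))
    return out


@dataclass
class PipelineConfig:
    """Parameters of the end-to-end synthetic pipeline.

    Defaults follow the reference protocol: flick thresholds 0.2/0.4 mm,
    correlation thresholds r = 0.2 (tuning code) / 0.3 (stimulus, ISI) / 0.5
    (motor), 70% GABA overlap, >= 3 responded repetitions per fitted cell,
    and region filtering at >= 10 cells from >= 3 fish.
    """

    seed: int = 0
    out_dir: str = "loomhab_out"
    # behavioral cohort
    n_fish: int = 20
    behavior_isi_s: float = 10.0
    behavior_trials: int = 10
    # imaging sessions
    snr: float = 5.0
    dynamics_cells: int = 300
    dynamics_isi_s: float = 40.0
    dynamics_trials: int = 10
    class_mix: tuple = (0.55, 0.18, 0.27)   # depressing, potentiating, stable
    # thresholds
    onset_thresh_mm: float = bhv.ONSET_THRESH_MM
    peak_thresh_mm: float = bhv.PEAK_THRESH_MM
    r_code: float = tun.R_CODE
    r_stim: float = tun.R_STIM
    r_motor: float = tun.R_MOTOR
    gaba_overlap: float = lat.GABA_OVERLAP_THRESH
    min_repetitions: int = 3
    min_cells: int = 10
    min_fish: int = 3
    kmeans_k: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "class_mix" in d:
            d = {**d, "class_mix": tuple(d["class_mix"])}
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from JSON or YAML (schema-checked)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


@dataclass
class RunReport:
    """Per-stage record counts, parameter echo and summary statistics."""

    config: dict
    stages: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_json_default))
        return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage on synthetic data and write all outputs.

    Stages run in dependency order; any failure aborts with the stage name in
    the exception message.  Rerunning with the same config and seed
    reproduces every output byte for byte.
    """
    out = Path(cfg.out_dir)
    report = RunReport(config=dataclasses.asdict(cfg))
    stage = "behavior"
    try:
        _behavior_stage(cfg, out, report)
        stage = "tuning"
        codes, truth_cal = _tuning_stage(cfg, out, report)
        stage = "dynamics"
        _dynamics_stage(cfg, out, report)
        stage = "laterality"
        _laterality_stage(cfg, out, report, codes, truth_cal)
        stage = "gaba"
        _gaba_stage(cfg, out, report)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    report.save(out / "report.json")
    return report


def _behavior_stage(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    train = syn.behavior_train(n_trials=cfg.behavior_trials, isi_s=cfg.behavior_isi_s)
    sim = syn.BehaviorSimConfig(n_fish=cfg.n_fish, train=train)
    traces, truth = syn.simulate_behavior_session(sim, cfg.seed)
    t_lo, t_hi = bhv.response_window(train, "main")
    all_events, trial_tables, rates = [], [], []
    for fid, trace in enumerate(traces):
        ev = bhv.detect_flicks(trace, cfg.peak_thresh_mm, cfg.onset_thresh_mm)
        tt = bhv.assign_responses(ev, train, mode="main")
        ivals = bhv.stimulus_free_intervals(train, trace.duration_s)
        rates.append(bhv.spontaneous_rate(ev, ivals))
        all_events.append(events_to_table(ev, fid))
        tt.insert(0, "fish_id", fid)
        trial_tables.append(tt)
    events_df = pd.concat(all_events, ignore_index=True)
    trials_df = pd.concat(trial_tables, ignore_index=True)
    rate = float(np.mean(rates))
    responded = trials_df.pivot(index="fish_id", columns="trial", values="responded").to_numpy()
    curve = bhv.habituation_curve(responded, train, rate, t_hi - t_lo, seed=cfg.seed)
    curve_df = pd.DataFrame({"trial": np.arange(len(curve.t_s)), "t_s": curve.t_s,
                             "p_obs": curve.p_obs, "p_corr": curve.p_corr,
                             "band_lo": curve.band_lo, "band_hi": curve.band_hi})
    write_table(events_df, out / "events.csv")
    write_table(trials_df, out / "trial_table.csv")
    write_table(curve_df, out / "habituation_curve.csv")
    report.stages["behavior"] = {
        "n_fish": cfg.n_fish, "n_events": len(events_df), "n_trials": len(trials_df),
        "outputs": {"events.csv": len(events_df), "trial_table.csv": len(trials_df),
                    "habituation_curve.csv": len(curve_df)}}
    report.summary["spontaneous_rate_hz"] = rate
    report.summary["habituation_tau_s"] = curve.tau_s
    report.summary["habituation_fit_ok"] = curve.fit_ok
    report.summary["first_trial_p_corr"] = float(curve.p_corr[0])
    report.summary["direction_away_fraction"] = bhv.direction_stats(trials_df)


def _tuning_stage(cfg: PipelineConfig, out: Path, report: RunReport):
    sim = syn.CalciumSimConfig(snr=cfg.snr)
    rois, truth = syn.simulate_calcium_population(sim, cfg.seed + 1)
    geom = syn.ScreenGeometry(width_px=128, height_px=128, px_per_degree=1.0)
    codes = tun.assign_codes(rois, sim.trains, geom, kernel_tau=sim.kernel_tau,
                             r_code=cfg.r_code)
    codes["true_code"] = truth["code"].to_numpy()
    write_table(codes, out / "tuning_codes.csv")
    census = codes["decimal"].value_counts().sort_index()
    report.stages["tuning"] = {
        "n_cells": len(codes),
        "outputs": {"tuning_codes.csv": len(codes)},
        "cluster_census": {int(k): int(v) for k, v in census.items()}}
    acc = float((codes["decimal"] == codes["true_code"]).mean())
    report.summary["code_recovery_fraction"] = acc
    return codes, truth


def _dynamics_stage(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    train = syn.dynamics_train(n_trials=cfg.dynamics_trials, isi_s=cfg.dynamics_isi_s)
    n = cfg.dynamics_cells
    mix = cfg.class_mix
    pops = [
        syn.PopulationSpec(n_cells=int(round(n * mix[0])), code=4, dyn_class="depressing"),
        syn.PopulationSpec(n_cells=int(round(n * mix[1])), code=4, dyn_class="potentiating"),
        syn.PopulationSpec(n_cells=n - int(round(n * mix[0])) - int(round(n * mix[1])),
                           code=4, dyn_class="stable"),
    ]
    sim = syn.CalciumSimConfig(populations=pops, trains={"dl": train}, snr=cfg.snr)
    rois, truth = syn.simulate_calcium_population(sim, cfg.seed + 2)
    fits = []
    for i in range(rois.F.shape[0]):
        series = dyn.extract_peak_series(rois.F[i], train, rois.fs, roi_id=i)
        fits.append(dyn.fit_exponential(series, min_responded=cfg.min_repetitions))
    table, thr = dyn.classify_population(fits)
    table["true_class"] = truth["dyn_class"].to_numpy()[table["roi_id"].to_numpy()]
    write_table(table, out / "dynamics_fits.csv")
    (out / "thresholds.json").write_text(json.dumps({
        "pos_thr": thr.pos_thr, "neg_thr": thr.neg_thr,
        "near_zero": list(thr.near_zero), "second": list(thr.second)}, indent=2))
    frac = table["dyn_class"].value_counts(normalize=True)
    report.stages["dynamics"] = {
        "n_cells": n, "n_fitted": len(table),
        "outputs": {"dynamics_fits.csv": len(table), "thresholds.json": 1}}
    report.summary["dynamics_fractions"] = {k: float(frac.get(k, 0.0))
                                            for k in ("depressing", "potentiating", "stable")}
    report.summary["rate_thresholds"] = {"pos": thr.pos_thr, "neg": thr.neg_thr}


def _laterality_stage(cfg: PipelineConfig, out: Path, report: RunReport,
                      codes: pd.DataFrame, truth: pd.DataFrame) -> None:
    cells = codes.copy()
    cells["hemisphere"] = truth["hemisphere"].to_numpy()
    cells["region"] = truth["population"].to_numpy()
    eye = "left"  # stimulated eye of the default session
    ls = cells[cells["decimal"] == 5]
    ds = cells[cells["decimal"] == 12]
    hi_ls = lat.hi_single_eye(ls, eye) if len(ls) else float("nan")
    hi_ds = lat.hi_single_eye(ds, eye) if len(ds) else float("nan")
    cells["tuning_class"] = np.select(
        [cells["decimal"] == 5, cells["decimal"] == 12], ["LS", "DS"], "other")
    regions = lat.region_summary(cells, label_col="tuning_class",
                                 min_cells=cfg.min_cells, min_fish=cfg.min_fish)
    write_table(cells[["roi_id", "fish_id", "hemisphere", "region", "decimal",
                       "tuning_class"]], out / "cells.csv")
    write_table(regions, out / "region_summary.csv")
    report.stages["laterality"] = {
        "n_cells": len(cells), "n_regions_kept": len(regions),
        "outputs": {"cells.csv": len(cells), "region_summary.csv": len(regions)}}
    report.summary["hi_ls"] = hi_ls
    report.summary["hi_ds"] = hi_ds


def _gaba_stage(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    sim = syn.ImageSimConfig()
    mask, red, truth = syn.simulate_roi_images(sim, cfg.seed + 3)
    calls = lat.gaba_assign(mask, red, overlap_thresh=cfg.gaba_overlap)
    merged = calls.merge(truth[["roi_id", "gaba"]], on="roi_id")
    write_image(mask, out / "roi_mask.tif")
    write_image(red.astype(np.float32), out / "red_channel.tif")
    write_table(calls, out / "gaba_calls.csv")
    report.stages["gaba"] = {
        "n_rois": len(calls),
        "outputs": {"gaba_calls.csv": len(calls), "roi_mask.tif": 1, "red_channel.tif": 1}}
    report.summary["gaba_fraction"] = float(calls["is_gaba"].mean())
    report.summary["gaba_call_accuracy"] = float((merged["is_gaba"] == merged["gaba"]).mean())
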