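"""End-to-end orchestration: simulate -> quantify -> statistics.

``run_pipeline`` executes the full analysis for one experiment from an
:class:`~spineltd.io.ExperimentConfig`, writes per-spine trace tables, the
binned fEPSP time course, summary JSONs and a manifest (inputs, seeds,
config hash, QC decisions with per-trace drift values), and returns the
results in memory. Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ephys import (baseline_drift_qc_ephys, bin_and_normalize,
                    measure_initial_slope, ppf_ratio, quantify_ltd)
from .imaging import quantify_channel, quantify_sep_signal, \
    quantify_structural_plasticity, measure_morphometrics
from .io import (ExperimentConfig, write_json, write_rois, write_sweeps,
                 write_traces_csv, write_zstack_tiff, read_zstack_tiff,
                 read_rois, read_sweeps)
from .simulate import (EphysSimConfig, ImagingSimConfig, make_spine_grid,
                       simulate_fepsp_experiment, simulate_imaging_experiment,
                       simulate_ppf_sweeps)
from .stats import paired_t

log = logging.getLogger("spineltd")

__all__ = ["run_pipeline"]


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                out = fn(*a, **k)
            except Exception as exc:   # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc
            return out
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: ExperimentConfig):
    im_cfg = ImagingSimConfig(seed=cfg.seed, **cfg.sim_imaging)
    spines = make_spine_grid(im_cfg, n_spines=cfg.n_spines,
                             shrinkage=cfg.true_shrinkage,
                             sep_surface_drop=cfg.sep_surface_drop)
    series, rois, im_gt = simulate_imaging_experiment(im_cfg, spines)
    ep_cfg = EphysSimConfig(seed=cfg.seed + 1, **cfg.sim_ephys)
    sweeps, ep_gt = simulate_fepsp_experiment(ep_cfg)
    ppf_sweeps, ppf_gt = simulate_ppf_sweeps(ep_cfg)
    log.info("simulate: %d spines, %d frames, %d sweeps, %d PPF ISIs",
             len(spines), series.n_frames, len(sweeps), len(ppf_gt.ppf_true))
    return series, rois, im_gt, sweeps, ep_gt, ppf_sweeps, ppf_gt


@_stage("quantify-imaging")
def _quantify_imaging(cfg: ExperimentConfig, series, rois):
    res = {}
    res["red"] = quantify_channel(
        series, rois, channel="volume_reporter", collapse=cfg.collapse,
        drift_threshold=cfg.imaging_drift_threshold)
    # an experiment with no QC-passing spines yields no plasticity measure;
    # downstream stats report "no data" instead of failing the run
    res["volume"] = (
        quantify_structural_plasticity(
            res["red"]["traces"], cfg.window, cfg.reference)
        if any(t.qc_passed for t in res["red"]["traces"]) else None)
    if series.green is not None:
        res["green"] = quantify_channel(
            series, rois, channel="sep_reporter", collapse=cfg.collapse,
            drift_threshold=cfg.imaging_drift_threshold)
        res["sep"] = (
            quantify_sep_signal(
                res["green"]["traces"], cfg.window, cfg.reference)
            if any(t.qc_passed for t in res["green"]["traces"]) else None)
    res["morphometrics"] = measure_morphometrics(rois, series.pixel_size_um)
    n_in = len(res["red"]["traces"])
    n_ok = sum(t.qc_passed for t in res["red"]["traces"])
    log.info("quantify-imaging: %d spines in, %d passed QC", n_in, n_ok)
    return res


@_stage("quantify-ephys")
def _quantify_ephys(cfg: ExperimentConfig, sweeps, ppf_sweeps):
    slopes, times = [], []
    for sw in sweeps:
        r = measure_initial_slope(sw)
        slopes.append(r["slope"])
        times.append(sw.sweep_time_min)
    course = bin_and_normalize(np.array(slopes), np.array(times))
    baseline_drift_qc_ephys(course, cfg.ephys_drift_threshold)
    ltd = quantify_ltd(course, cfg.window, cfg.reference) \
        if course.qc_passed else None
    ppf = {}
    if ppf_sweeps is not None:
        template = next((s for s in ppf_sweeps
                         if len(s.stim_times_ms) == 1), None)
        for sw in ppf_sweeps:
            if len(sw.stim_times_ms) == 2:
                isi = sw.stim_times_ms[1] - sw.stim_times_ms[0]
                ppf[isi] = ppf_ratio(sw, template=template)["ratio"]
    log.info("quantify-ephys: %d sweeps binned, QC %s",
             len(sweeps), "pass" if course.qc_passed else "FAIL")
    return {"course": course, "ltd": ltd, "ppf": ppf}


@_stage("stats")
def _stats(imaging, ephys):
    out = {}
    vol = imaging["volume"]
    if vol is None:
        out["volume"] = "no data (all spines excluded by QC)"
    else:
        ref, win = vol.pairs
        if len(ref) >= 2:
            t = paired_t(ref, win,
                         comparison="spine volume: window vs baseline")
            out["volume_paired_t"] = {"t": t.statistic, "df": t.df, "p": t.p,
                                      "defined": t.defined}
        out["volume_window_percent"] = vol.window_mean_percent
        out["volume_reference_percent"] = vol.baseline_reference_percent
    if imaging.get("sep") is not None:
        out["sep_window_percent"] = imaging["sep"].window_mean_percent
    elif "green" in imaging:
        out["sep"] = "no data (all spines excluded by QC)"
    if ephys["ltd"] is not None:
        out["ltd_percent_of_baseline"] = ephys["ltd"]["window_mean_percent"]
    out["ppf_ratios"] = {f"{isi:g}": r for isi, r in ephys["ppf"].items()}
    return out


def run_pipeline(cfg: ExperimentConfig) -> dict:
    """Run simulate (optional) -> quantify-imaging -> quantify-ephys -> stats.

    Writes all outputs under ``cfg.out_dir`` and returns the results bundle.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                  "version": __version__}

    if cfg.simulate:
        series, rois, im_gt, sweeps, ep_gt, ppf_sweeps, ppf_gt = _simulate(cfg)
        sim_dir = out / "simulated"
        paths = write_zstack_tiff(series, sim_dir)
        write_rois(rois, sim_dir / "rois.csv")
        write_sweeps(sweeps, sim_dir / "sweeps.csv")
        write_sweeps(ppf_sweeps, sim_dir / "ppf_sweeps.csv")
        write_json({
            "volume_traces_percent":
                {k: v for k, v in im_gt.volume_traces_percent.items()},
            "gain_series": im_gt.gain_series,
            "drift_offsets": im_gt.drift_offsets,
            "weight_course": ep_gt.weight_course,
            "ppf_true": {f"{k:g}": v for k, v in ppf_gt.ppf_true.items()},
        }, sim_dir / "ground_truth.json")
        provenance["inputs"] = paths
    else:
        missing = [p for p in (cfg.red_tiff, cfg.sidecar, cfg.rois_csv,
                               cfg.sweeps_csv) if p is None]
        if missing:
            raise PipelineError("inputs", ValueError(
                "simulate=false requires red_tiff, sidecar, rois_csv and "
                "sweeps_csv paths"))
        series = read_zstack_tiff(cfg.red_tiff, cfg.sidecar, cfg.green_tiff)
        rois = read_rois(cfg.rois_csv)
        sweeps = read_sweeps(cfg.sweeps_csv)
        ppf_sweeps = None
        provenance["inputs"] = {"red": cfg.red_tiff, "rois": cfg.rois_csv,
                                "sweeps": cfg.sweeps_csv}

    imaging = _quantify_imaging(cfg, series, rois)
    ephys = _quantify_ephys(cfg, sweeps, ppf_sweeps)
    stats_out = _stats(imaging, ephys)

    write_traces_csv(imaging["red"]["traces"], imaging["red"]["raw_traces"],
                     out / "spine_traces.csv")
    course = ephys["course"]
    pd.DataFrame({"minute": course.minutes, "percent": course.percent,
                  "n_sweeps": course.n_sweeps}).to_csv(
        out / "fepsp_course.csv", index=False)
    write_json({**stats_out, **provenance}, out / "summary.json")

    excluded = [
        {"roi_id": tr.roi_id, "drift_percent": tr.drift_percent,
         "reason": "baseline drift"}
        for tr in imaging["red"]["traces"] if not tr.qc_passed
    ]
    manifest = {
        **provenance,
        "qc": {
            "imaging_drift_threshold": cfg.imaging_drift_threshold,
            "ephys_drift_threshold": cfg.ephys_drift_threshold,
            "spines_total": len(imaging["red"]["traces"]),
            "spines_excluded": excluded,
            "ephys_drift_percent": course.drift_percent,
            "ephys_qc_passed": course.qc_passed,
        },
    }
    write_json(manifest, out / "manifest.json")
    return {"imaging": imaging, "ephys": ephys, "stats": stats_out,
            "manifest": manifest,
            "ground_truth": im_gt if cfg.simulate else None,
            "ephys_ground_truth": ep_gt if cfg.simulate else None}
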