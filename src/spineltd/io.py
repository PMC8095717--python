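"""File formats and experiment configuration.

Imaging series are stored as plain multi-page TIFF, one file per channel,
pages ordered T-major then Z, with a JSON sidecar recording shape, timeline
and calibration. ROI sets are CSV (roi_id, role, center_x, center_y,
diameter_px, base_x, base_y), sweeps are long-format CSV (sweep_id,
sweep_time_min, time_ms, voltage_mV, stim_times), ground truth and result
summaries are JSON, and experiment configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ephys import Sweep, SweepSeries
from .imaging import NormalizedTrace, Roi, RoiSet, ZStackSeries

__all__ = [
    "ExperimentConfig",
    "write_zstack_tiff",
    "read_zstack_tiff",
    "write_rois",
    "read_rois",
    "write_sweeps",
    "read_sweeps",
    "write_traces_csv",
    "write_json",
    "read_json",
]


# ---------------------------------------------------------------------------
# TIFF + sidecar
# ---------------------------------------------------------------------------

def write_zstack_tiff(series: ZStackSeries, out_dir: str | Path,
                      dtype: str = "float32") -> dict:
    """Write a Z-stack series as one TIFF per channel plus a JSON sidecar.

    Pages are ordered T-major then Z (frame 0 slice 0, frame 0 slice 1, ...).
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nt, nz, h, w = series.red.shape
    paths = {"red": out / "ch_red.tif", "sidecar": out / "series.json"}
    tifffile.imwrite(paths["red"],
                     series.red.reshape(nt * nz, h, w).astype(dtype))
    channels = {"red": "volume_reporter"}
    if series.green is not None:
        paths["green"] = out / "ch_green.tif"
        tifffile.imwrite(paths["green"],
                         series.green.reshape(nt * nz, h, w).astype(dtype))
        channels["green"] = "sep_reporter"
    sidecar = {
        "frame_count": nt,
        "z_slices": nz,
        "frame_size": [h, w],
        "page_order": "t_major_then_z",
        "timeline_min": [float(t) for t in series.timeline],
        "z_step_um": series.z_step_um,
        "pixel_size_um": series.pixel_size_um,
        "channels": channels,
        "dtype": dtype,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def read_zstack_tiff(red_path: str | Path, sidecar_path: str | Path,
                     green_path: str | Path | None = None) -> ZStackSeries:
    """Load a Z-stack series written by :func:`write_zstack_tiff`.

    The page count of each TIFF must equal frame_count x z_slices declared
    in the sidecar; mismatches are rejected with the expected and actual
    counts.
    """
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    nt, nz = meta["frame_count"], meta["z_slices"]
    h, w = meta["frame_size"]

    def load(path: str | Path) -> np.ndarray:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != nt * nz:
            raise ValueError(
                f"{path}: expected {nt * nz} pages "
                f"({nt} frames x {nz} slices), found {pages.shape[0]}")
        if pages.shape[1:] != (h, w):
            raise ValueError(f"{path}: page shape {pages.shape[1:]} does not "
                             f"match sidecar frame size {(h, w)}")
        return np.asarray(pages, dtype=np.float64).reshape(nt, nz, h, w)

    red = load(red_path)
    green = load(green_path) if green_path is not None else None
    return ZStackSeries(red=red, green=green,
                        timeline=np.array(meta["timeline_min"]),
                        z_step_um=meta["z_step_um"],
                        pixel_size_um=meta["pixel_size_um"])


# ---------------------------------------------------------------------------
# ROI CSV
# ---------------------------------------------------------------------------

def write_rois(rois: RoiSet, path: str | Path) -> None:
    rows = []
    for r in rois.rois:
        rows.append({
            "roi_id": r.roi_id,
            "role": r.role,
            "center_x": r.center[0],
            "center_y": r.center[1],
            "diameter_px": r.diameter_px,
            "base_x": r.base_point[0] if r.base_point else np.nan,
            "base_y": r.base_point[1] if r.base_point else np.nan,
            "dendrite_length_um": rois.dendrite_length_um,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois(path: str | Path, enforce_counts: bool = True) -> RoiSet:
    df = pd.read_csv(path)
    rois = []
    for _, row in df.iterrows():
        base = None
        if np.isfinite(row.get("base_x", np.nan)):
            base = (float(row["base_x"]), float(row["base_y"]))
        rois.append(Roi(str(row["roi_id"]), str(row["role"]),
                        (float(row["center_x"]), float(row["center_y"])),
                        float(row["diameter_px"]), base_point=base))
    length = None
    if "dendrite_length_um" in df and np.isfinite(df["dendrite_length_um"].iloc[0]):
        length = float(df["dendrite_length_um"].iloc[0])
    if enforce_counts:
        return RoiSet(rois, dendrite_length_um=length)
    return RoiSet.unchecked(rois, dendrite_length_um=length)


# ---------------------------------------------------------------------------
# Sweep CSV
# ---------------------------------------------------------------------------

def write_sweeps(series: SweepSeries, path: str | Path) -> None:
    """Long-format sweep table: one row per sample."""
    frames = []
    for sw in series.sweeps:
        frames.append(pd.DataFrame({
            "sweep_id": sw.sweep_id,
            "sweep_time_min": sw.sweep_time_min,
            "time_ms": sw.time_ms,
            "voltage_mV": sw.voltage_mv,
            "stim_times": ";".join(f"{s:g}" for s in sw.stim_times_ms),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sweeps(path: str | Path) -> SweepSeries:
    df = pd.read_csv(path)
    sweeps = []
    for sid, grp in df.groupby("sweep_id", sort=False):
        stim = [float(s) for s in str(grp["stim_times"].iloc[0]).split(";")]
        sweeps.append(Sweep(
            grp["time_ms"].to_numpy(),
            grp["voltage_mV"].to_numpy(),
            stim,
            sweep_time_min=float(grp["sweep_time_min"].iloc[0]),
            sweep_id=str(sid),
        ))
    dt = sweeps[0].dt_ms if sweeps else 0.02
    return SweepSeries(sweeps, sampling_rate_khz=1.0 / dt)


# ---------------------------------------------------------------------------
# Trace tables, JSON helpers
# ---------------------------------------------------------------------------

def write_traces_csv(traces: list[NormalizedTrace],
                     raw: dict | None,
                     path: str | Path) -> None:
    """Per-spine trace table: roi_id, frame, time_min, raw, corrected
    percent, qc_pass."""
    rows = []
    for tr in traces:
        raw_vals = (raw[tr.roi_id].values if raw and tr.roi_id in raw
                    else np.full(len(tr.values), np.nan))
        for k, (t, v) in enumerate(zip(tr.timeline, tr.values)):
            rows.append({
                "roi_id": tr.roi_id,
                "frame": k,
                "time_min": t,
                "raw": raw_vals[k],
                "percent": v,
                "qc_pass": tr.qc_passed,
                "drift_percent": tr.drift_percent,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=True, cls=_NumpyEncoder))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """End-to-end pipeline configuration (YAML-serializable).

    When ``simulate`` is true the pipeline generates its own inputs with the
    configured seed; otherwise the imaging/ephys input paths must exist.
    QC thresholds default to the study criteria (imaging 7%, ephys 5%).
    """

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    # simulation overrides (keys of ImagingSimConfig / EphysSimConfig)
    sim_imaging: dict = field(default_factory=dict)
    sim_ephys: dict = field(default_factory=dict)
    n_spines: int = 5
    true_shrinkage: float = 0.16
    sep_surface_drop: float = 0.0
    # existing inputs (used when simulate is false)
    red_tiff: str | None = None
    green_tiff: str | None = None
    sidecar: str | None = None
    rois_csv: str | None = None
    sweeps_csv: str | None = None
    # analysis parameters
    collapse: str = "max"
    imaging_drift_threshold: float = 7.0
    ephys_drift_threshold: float = 5.0
    window: tuple[float, float] = (50.0, 60.0)
    reference: tuple[float, float] = (-10.0, 0.0)

    def __post_init__(self) -> None:
        if self.imaging_drift_threshold <= 0 or self.ephys_drift_threshold <= 0:
            raise ValueError("QC thresholds must be positive")
        self.window = tuple(self.window)
        self.reference = tuple(self.reference)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        d["reference"] = list(self.reference)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
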