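"""Quantification of spine structural plasticity from two-photon Z-stack series.

The pipeline mirrors standard practice for time-lapse spine imaging:

1. collapse each Z-stack to a single 2D frame (maximum-intensity projection
   by default, sum projection optionally);
2. register the frame series to the first frame (translation only);
3. extract integrated intensity inside constant circular ROIs (diameter
   20 px around each spine head, three background ROIs, five shaft ROIs);
4. subtract background and divide out the global fluorescence fluctuation
   estimated from the shaft ROIs;
5. normalize each trace to its baseline mean (percent of baseline);
6. exclude traces whose baseline drifts by 7% or more (linear-regression
   drift criterion);
7. quantify plasticity as the mean of the 50-60 min post-treatment window
   against the last 10 min of baseline.

Coordinates are 0-based pixel indices with pixel centers at integer + 0.5;
ROI centers are given in the same continuous coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps
from skimage.registration import phase_cross_correlation

__all__ = [
    "Roi",
    "RoiSet",
    "ZStackSeries",
    "NormalizedTrace",
    "PlasticityMeasure",
    "collapse_zstack",
    "register_series",
    "roi_mask",
    "extract_roi_traces",
    "correct_trace",
    "normalize_trace",
    "baseline_drift_qc",
    "apply_experiment_qc",
    "quantify_structural_plasticity",
    "quantify_sep_signal",
    "measure_morphometrics",
    "size_dependence_analysis",
    "quantify_channel",
]

SPINE_ROI_DIAMETER_PX = 20.0
N_BACKGROUND_ROIS = 3
N_SHAFT_ROIS = 5
IMAGING_DRIFT_THRESHOLD = 7.0  # percent; traces pass iff drift < threshold


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """A circular region of interest.

    ``center`` is ``(x, y)`` in continuous pixel coordinates. ``role`` is one
    of ``spine``, ``background`` or ``shaft``. Spine ROIs may carry a
    ``base_point`` (x, y) marking where the spine neck meets the dendrite,
    used for spine-length morphometrics.
    """

    roi_id: str
    role: str
    center: tuple[float, float]
    diameter_px: float = SPINE_ROI_DIAMETER_PX
    base_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("spine", "background", "shaft"):
            raise ValueError(f"unknown ROI role {self.role!r}")
        if self.diameter_px <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass
class RoiSet:
    """Spine, background and shaft ROIs for one imaged dendritic segment."""

    rois: list[Roi]
    dendrite_length_um: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, enforce_counts: bool = True) -> None:
        if enforce_counts:
            nb, ns = len(self.backgrounds), len(self.shafts)
            if nb != N_BACKGROUND_ROIS:
                raise ValueError(
                    f"expected {N_BACKGROUND_ROIS} background ROIs, got {nb} "
                    "(construct with RoiSet.unchecked to override)"
                )
            if ns != N_SHAFT_ROIS:
                raise ValueError(
                    f"expected {N_SHAFT_ROIS} shaft ROIs, got {ns} "
                    "(construct with RoiSet.unchecked to override)"
                )

    @classmethod
    def unchecked(cls, rois: list[Roi],
                  dendrite_length_um: float | None = None) -> "RoiSet":
        """Build a RoiSet without enforcing the 3-background/5-shaft counts."""
        obj = cls.__new__(cls)
        obj.rois = rois
        obj.dendrite_length_um = dendrite_length_um
        return obj

    def _by_role(self, role: str) -> list[Roi]:
        return [r for r in self.rois if r.role == role]

    @property
    def spines(self) -> list[Roi]:
        return self._by_role("spine")

    @property
    def backgrounds(self) -> list[Roi]:
        return self._by_role("background")

    @property
    def shafts(self) -> list[Roi]:
        return self._by_role("shaft")


@dataclass
class ZStackSeries:
    """Time series of two-channel Z-stacks with its acquisition timeline.

    ``red`` holds the volume-reporter channel (T, Z, Y, X); ``green``
    optionally holds the SEP (surface-receptor) channel with the same shape.
    ``timeline`` gives each frame's midpoint time in minutes relative to
    treatment onset (negative during baseline).
    """

    red: np.ndarray
    timeline: np.ndarray
    green: np.ndarray | None = None
    z_step_um: float = 1.0
    pixel_size_um: float = 0.066

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.timeline = np.asarray(self.timeline, dtype=float)
        if self.red.ndim != 4:
            raise ValueError("red channel must be a T x Z x Y x X array")
        if len(self.timeline) != self.red.shape[0]:
            raise ValueError("timeline length must match frame count")
        if np.any(np.diff(self.timeline) <= 0):
            raise ValueError("timeline must be strictly increasing")
        if int(np.sum(self.timeline < 0)) < 2:
            raise ValueError("need at least 2 baseline frames (t < 0)")
        if self.green is not None:
            self.green = np.asarray(self.green)
            if self.green.shape != self.red.shape:
                raise ValueError("green channel shape must match red channel")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.timeline < 0


@dataclass
class NormalizedTrace:
    """Per-ROI percent-of-baseline time course with its QC status."""

    roi_id: str
    values: np.ndarray            # percent of baseline, one per frame
    timeline: np.ndarray          # minutes relative to treatment
    baseline_mean: float          # raw (corrected) units
    channel: str = "volume_reporter"
    drift_percent: float = np.nan
    qc_passed: bool = True
    valid: np.ndarray | None = None   # per-frame validity mask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timeline = np.asarray(self.timeline, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)


@dataclass
class PlasticityMeasure:
    """Windowed plasticity quantification for one experiment.

    ``window_mean_percent`` is the mean percent-of-baseline over the 50-60 min
    post-treatment window; ``baseline_reference_percent`` the mean over the
    last 10 min of baseline. ``pairs`` holds the per-spine (reference, window)
    values feeding a paired t-test downstream.
    """

    window_mean_percent: float
    baseline_reference_percent: float
    n_spines: int
    delta_percent: float = field(init=False)
    per_spine_window: np.ndarray | None = None
    per_spine_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_percent = (self.window_mean_percent
                              - self.baseline_reference_percent)

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.per_spine_reference, self.per_spine_window


# ---------------------------------------------------------------------------
# Z-collapse and registration
# ---------------------------------------------------------------------------

def collapse_zstack(zstack: np.ndarray, method: str = "max") -> np.ndarray:
    """Collapse one Z x Y x X stack to a 2D frame.

    ``method='max'`` gives the maximum-intensity projection (default);
    ``method='sum'`` the sum projection.
    """
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] == 0:
        raise ValueError("zstack must be a non-empty Z x Y x X array")
    if method == "max":
        return zstack.max(axis=0)
    if method == "sum":
        return zstack.sum(axis=0)
    raise ValueError(f"unknown collapse method {method!r}")


def register_series(
    frames: np.ndarray,
    upsample_factor: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align a T x Y x X frame series to frame 0 by translation.

    Shifts are estimated by phase cross-correlation with subpixel (upsampled
    DFT) refinement and applied by spline interpolation with constant edge
    padding. Returns ``(aligned, shifts, flags)`` where ``shifts[t]`` is the
    estimated (dy, dx) displacement of frame t relative to frame 0 and
    ``flags[t]`` is True when the shift was undefined (featureless frame) and
    (0, 0) was substituted.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a T x Y x X series with at least 2 frames")
    ref = frames[0]
    aligned = np.empty_like(frames)
    aligned[0] = ref
    shifts = np.zeros((frames.shape[0], 2))
    flags = np.zeros(frames.shape[0], dtype=bool)
    ref_featureless = np.ptp(ref) == 0
    for t in range(1, frames.shape[0]):
        frm = frames[t]
        if ref_featureless or np.ptp(frm) == 0:
            warnings.warn(f"frame {t}: featureless image, shift undefined; "
                          "using (0, 0)", stacklevel=2)
            flags[t] = True
            aligned[t] = frm
            continue
        # phase_cross_correlation returns the shift that maps frm onto ref
        shift, _, _ = phase_cross_correlation(
            ref, frm, upsample_factor=upsample_factor, normalization=None)
        shifts[t] = -shift  # displacement of frame t relative to frame 0
        aligned[t] = ndimage.shift(frm, shift, order=3, mode="nearest")
    return aligned, shifts, flags


# ---------------------------------------------------------------------------
# ROI trace extraction and correction
# ---------------------------------------------------------------------------

def roi_mask(roi: Roi, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie strictly within the ROI.

    Pixel (ix, iy) has its center at (ix + 0.5, iy + 0.5); it belongs to the
    mask iff its center-to-ROI-center distance is < diameter/2.
    """
    h, w = shape
    cx, cy = roi.center
    ys = np.arange(h)[:, None] + 0.5
    xs = np.arange(w)[None, :] + 0.5
    r2 = (xs - cx) ** 2 + (ys - cy) ** 2
    return r2 < (roi.diameter_px / 2.0) ** 2


@dataclass
class RoiTrace:
    """Raw integrated-intensity trace for one ROI."""

    roi_id: str
    role: str
    values: np.ndarray        # per-frame integrated intensity
    pixel_count: int
    valid: np.ndarray         # per-frame validity (ROI fully inside frame)


def extract_roi_traces(frames: np.ndarray, rois: RoiSet) -> dict[str, RoiTrace]:
    """Integrate intensity inside each ROI over a registered T x Y x X series."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be T x Y x X")
    nt, h, w = frames.shape
    out: dict[str, RoiTrace] = {}
    for roi in rois.rois:
        mask = roi_mask(roi, (h, w))
        npx = int(mask.sum())
        cx, cy = roi.center
        rad = roi.diameter_px / 2.0
        inside = (cx - rad >= 0 and cx + rad <= w
                  and cy - rad >= 0 and cy + rad <= h)
        vals = frames[:, mask].sum(axis=1) if npx else np.zeros(nt)
        valid = np.full(nt, inside, dtype=bool)
        if not inside:
            warnings.warn(f"ROI {roi.roi_id} extends outside the frame; "
                          "trace marked invalid", stacklevel=2)
        out[roi.roi_id] = RoiTrace(roi.roi_id, roi.role, vals, npx, valid)
    return out


def correct_trace(
    spine: RoiTrace,
    backgrounds: list[RoiTrace],
    shafts: list[RoiTrace],
    baseline_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract and fluctuation-correct one spine trace.

    Per frame t the background estimate is the mean per-pixel intensity of
    the background ROIs scaled to the spine mask area,
    ``B(t) = mean_b[bg_b(t) / npx_b] * npx_spine``; the corrected spine
    signal is ``spine(t) - B(t)``. The global gain is the mean over shaft
    ROIs of each shaft's background-subtracted signal divided by its own
    baseline mean (so the gain averages 1 over baseline), and the output is
    the background-subtracted spine signal divided by that gain.

    Returns ``(corrected, valid)`` where ``valid`` flags frames with a
    positive gain and valid input traces.
    """
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    nt = len(spine.values)
    if any(len(tr.values) != nt for tr in backgrounds + shafts):
        raise ValueError("all traces must have the same length")
    if not baseline_mask.any():
        raise ValueError("baseline is empty")

    bg_per_px = np.mean(
        [tr.values / tr.pixel_count for tr in backgrounds], axis=0)
    s_corr = spine.values - bg_per_px * spine.pixel_count

    rel = []
    for tr in shafts:
        sub = tr.values - bg_per_px * tr.pixel_count
        base = sub[baseline_mask].mean()
        if base <= 0:
            raise ValueError(
                f"shaft ROI {tr.roi_id} has non-positive baseline mean")
        rel.append(sub / base)
    gain = np.mean(rel, axis=0)

    valid = spine.valid.copy()
    for tr in backgrounds + shafts:
        valid &= tr.valid
    pos = gain > 0
    valid &= pos
    corrected = np.full(nt, np.nan)
    corrected[pos] = s_corr[pos] / gain[pos]
    return corrected, valid


def normalize_trace(
    corrected: np.ndarray,
    timeline: np.ndarray,
    roi_id: str = "",
    channel: str = "volume_reporter",
    valid: np.ndarray | None = None,
) -> NormalizedTrace:
    """Express a corrected trace as percent of its baseline (t < 0) mean."""
    corrected = np.asarray(corrected, dtype=float)
    timeline = np.asarray(timeline, dtype=float)
    if valid is None:
        valid = np.isfinite(corrected)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(corrected)
    bl = (timeline < 0) & valid
    if int(bl.sum()) < 2:
        raise ValueError("need at least 2 valid baseline frames")
    base = corrected[bl].mean()
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return NormalizedTrace(
        roi_id=roi_id,
        values=100.0 * corrected / base,
        timeline=timeline,
        baseline_mean=float(base),
        channel=channel,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# QC and windowed quantification
# ---------------------------------------------------------------------------

def baseline_drift_qc(
    trace: NormalizedTrace,
    threshold_percent: float = IMAGING_DRIFT_THRESHOLD,
) -> NormalizedTrace:
    """Apply the baseline-drift inclusion criterion to a normalized trace.

    An ordinary-least-squares line is fit to the baseline values against
    time; the drift is |slope| x (baseline time span) / (baseline mean),
    as a percentage. The trace passes iff drift < threshold (strict), i.e. a
    trace drifting by exactly the threshold is excluded.
    """
    bl = (trace.timeline < 0) & trace.valid
    if int(bl.sum()) < 3:
        trace.drift_percent = np.nan
        trace.qc_passed = False
        return trace
    t, v = trace.timeline[bl], trace.values[bl]
    slope = sps.linregress(t, v).slope
    span = t.max() - t.min()
    drift = abs(slope) * span / v.mean() * 100.0
    trace.drift_percent = float(drift)
    trace.qc_passed = bool(drift < threshold_percent)
    return trace


def apply_experiment_qc(traces: list[NormalizedTrace],
                        policy: str = "per_trace") -> bool:
    """Experiment-level drift-QC policy over per-trace decisions.

    ``per_trace``: keep individual decisions; experiment passes if any trace
    passed. ``all``: the experiment is excluded (every trace marked failed)
    unless all traces passed. Returns whether the experiment passes.
    """
    if policy not in ("per_trace", "all"):
        raise ValueError(f"unknown QC policy {policy!r}")
    if policy == "all" and not all(tr.qc_passed for tr in traces):
        for tr in traces:
            tr.qc_passed = False
        return False
    return any(tr.qc_passed for tr in traces)


def _window_means(trace: NormalizedTrace,
                  window: tuple[float, float] = (50.0, 60.0),
                  reference: tuple[float, float] = (-10.0, 0.0),
                  ) -> tuple[float, float]:
    # post window closed [50, 60], baseline reference half-open [-10, 0)
    t = trace.timeline
    win = (t >= window[0]) & (t <= window[1]) & trace.valid
    ref = (t >= reference[0]) & (t < reference[1]) & trace.valid
    if not win.any():
        raise ValueError("no frames in the post-treatment window")
    if not ref.any():
        raise ValueError("no frames in the baseline reference window")
    return float(trace.values[ref].mean()), float(trace.values[win].mean())


def quantify_structural_plasticity(
    traces: list[NormalizedTrace],
    window: tuple[float, float] = (50.0, 60.0),
    reference: tuple[float, float] = (-10.0, 0.0),
) -> PlasticityMeasure:
    """Windowed plasticity over QC-passing spine traces.

    Per trace, the mean percent over the post-treatment window (50-60 min by
    default) and over the last 10 min of baseline; the experiment value is
    the mean across included spines.
    """
    included = [tr for tr in traces if tr.qc_passed]
    if not included:
        raise ValueError("no QC-passing traces to quantify")
    refs, wins = zip(*(_window_means(tr, window, reference)
                       for tr in included))
    refs, wins = np.array(refs), np.array(wins)
    return PlasticityMeasure(
        window_mean_percent=float(wins.mean()),
        baseline_reference_percent=float(refs.mean()),
        n_spines=len(included),
        per_spine_window=wins,
        per_spine_reference=refs,
    )


def quantify_sep_signal(
    traces: list[NormalizedTrace],
    window: tuple[float, float] = (50.0, 60.0),
    reference: tuple[float, float] = (-10.0, 0.0),
) -> PlasticityMeasure:
    """Windowed surface-receptor (SEP channel) signal; same pipeline as the
    volume channel, reported as percent-of-baseline surface fluorescence."""
    return quantify_structural_plasticity(traces, window, reference)


# ---------------------------------------------------------------------------
# Morphometrics and size stratification
# ---------------------------------------------------------------------------

def measure_morphometrics(rois: RoiSet, pixel_size_um: float) -> dict:
    """Spine density (spines / 10 um of dendrite) and spine lengths (um).

    Length is the Euclidean base-to-head-center distance; spines without a
    base point get NaN length.
    """
    if rois.dendrite_length_um is None or rois.dendrite_length_um <= 0:
        raise ValueError("dendrite segment length must be positive")
    spines = rois.spines
    lengths = {}
    for r in spines:
        if r.base_point is None:
            lengths[r.roi_id] = np.nan
        else:
            d = np.hypot(r.center[0] - r.base_point[0],
                         r.center[1] - r.base_point[1])
            lengths[r.roi_id] = float(d * pixel_size_um)
    density = 10.0 * len(spines) / rois.dendrite_length_um
    return {"density_per_10um": density, "lengths_um": lengths}


def size_dependence_analysis(
    traces: list[NormalizedTrace],
    baseline_intensities: dict[str, float],
    split_quantile: float = 0.5,
    window: tuple[float, float] = (50.0, 60.0),
    reference: tuple[float, float] = (-10.0, 0.0),
) -> dict:
    """Plasticity stratified by initial spine size.

    Spines are split at the given quantile (median by default) of their
    baseline corrected intensity into small and large classes; the per-class
    mean window percent is returned together with the regression slope of
    the per-spine plasticity change against initial size.
    """
    included = [tr for tr in traces if tr.qc_passed]
    if len(included) < 2:
        raise ValueError("need at least 2 QC-passing spines")
    sizes = np.array([baseline_intensities[tr.roi_id] for tr in included])
    vals = np.array([_window_means(tr, window, reference)
                     for tr in included])
    deltas = vals[:, 1] - vals[:, 0]
    wins = vals[:, 1]

    cut = np.quantile(sizes, split_quantile)
    small = sizes <= cut
    large = ~small
    if np.ptp(sizes) == 0:
        small_mean = large_mean = float("nan")
    else:
        small_mean = float(wins[small].mean()) if small.any() else float("nan")
        large_mean = float(wins[large].mean()) if large.any() else float("nan")
    if np.ptp(sizes) == 0:
        slope = 0.0
    else:
        slope = float(sps.linregress(sizes, deltas).slope)
    return {
        "small_mean_percent": small_mean,
        "large_mean_percent": large_mean,
        "slope_delta_vs_size": slope,
        "split_intensity": float(cut),
    }


# ---------------------------------------------------------------------------
# End-to-end channel pipeline
# ---------------------------------------------------------------------------

def quantify_channel(
    series: ZStackSeries,
    rois: RoiSet,
    channel: str = "volume_reporter",
    collapse: str = "max",
    drift_threshold: float = IMAGING_DRIFT_THRESHOLD,
    register: bool = True,
) -> dict:
    """Run the full per-channel pipeline on a Z-stack series.

    Returns a dict with the collapsed/aligned frames, estimated shifts, raw
    traces, normalized per-spine traces (QC applied) and baseline raw
    intensities (for size stratification).
    """
    data = series.red if channel == "volume_reporter" else series.green
    if data is None:
        raise ValueError(f"series has no {channel} channel")
    frames = np.stack([collapse_zstack(data[t], collapse)
                       for t in range(series.n_frames)])
    if register:
        aligned, shifts, flags = register_series(frames)
    else:
        aligned = frames
        shifts = np.zeros((series.n_frames, 2))
        flags = np.zeros(series.n_frames, dtype=bool)
    raw = extract_roi_traces(aligned, rois)
    bgs = [raw[r.roi_id] for r in rois.backgrounds]
    shafts = [raw[r.roi_id] for r in rois.shafts]
    bl = series.baseline_mask
    traces: list[NormalizedTrace] = []
    baseline_raw: dict[str, float] = {}
    for r in rois.spines:
        corrected, valid = correct_trace(raw[r.roi_id], bgs, shafts, bl)
        tr = normalize_trace(corrected, series.timeline, roi_id=r.roi_id,
                             channel=channel, valid=valid)
        baseline_drift_qc(tr, drift_threshold)
        traces.append(tr)
        baseline_raw[r.roi_id] = tr.baseline_mean
    return {
        "frames": aligned,
        "shifts": shifts,
        "registration_flags": flags,
        "raw_traces": raw,
        "traces": traces,
        "baseline_intensity": baseline_raw,
    }
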