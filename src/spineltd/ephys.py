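"""Functional plasticity from extracellular field-potential sweeps.

Implements fEPSP initial-slope measurement, per-minute binning with baseline
normalization, the baseline-drift exclusion criterion, windowed LTD
quantification, and paired-pulse facilitation (PPF) ratios.

Sweeps are stimulus-locked voltage traces (mV) on a uniform time grid (ms).
The fEPSP is negative-going; slopes are signed, with magnitudes used for
ratios and normalization so that results are invariant to recording polarity
conventions and DC offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "Sweep",
    "SweepSeries",
    "SlopeParams",
    "BinnedTimeCourse",
    "measure_initial_slope",
    "bin_and_normalize",
    "baseline_drift_qc_ephys",
    "quantify_ltd",
    "ppf_ratio",
]

EPHYS_DRIFT_THRESHOLD = 5.0  # percent; experiments excluded iff drift > threshold


@dataclass
class Sweep:
    """One stimulus-locked voltage sweep."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    stim_times_ms: list[float]
    sweep_time_min: float = 0.0     # relative to treatment onset
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.time_ms.shape != self.voltage_mv.shape:
            raise ValueError("time and voltage must have the same shape")
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("sweep must be uniformly sampled")
        for s in self.stim_times_ms:
            if not (self.time_ms[0] <= s <= self.time_ms[-1]):
                raise ValueError("stimulus time outside sweep")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class SweepSeries:
    """An ordered collection of sweeps sharing a sampling grid."""

    sweeps: list[Sweep]
    sampling_rate_khz: float = 50.0

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


@dataclass
class SlopeParams:
    """Parameters of the initial-slope measurement.

    ``artifact_blank_ms`` samples after each stimulus are ignored;
    ``onset_threshold`` is the fraction of peak deflection defining response
    onset; the slope is an OLS fit over the rising-phase segment between
    ``fit_lo`` and ``fit_hi`` fractions of the peak (20-80% by default).
    """

    artifact_blank_ms: float = 1.0
    onset_threshold: float = 0.10
    fit_lo: float = 0.20
    fit_hi: float = 0.80
    min_peak_mv: float = 0.05   # deflections below this are noise
    smooth_ms: float = 0.6      # detection-filter width (fit uses raw samples)


@dataclass
class BinnedTimeCourse:
    """Per-minute normalized fEPSP slope time course."""

    minutes: np.ndarray            # bin start, minutes relative to treatment
    percent: np.ndarray            # mean normalized slope, % of baseline
    n_sweeps: np.ndarray
    drift_percent: float = np.nan
    qc_passed: bool = True


# ---------------------------------------------------------------------------
# Initial slope
# ---------------------------------------------------------------------------

def measure_initial_slope(
    sweep: Sweep,
    params: SlopeParams | None = None,
    stim_index: int = -1,
    search_end_ms: float | None = None,
) -> dict:
    """Measure the initial slope of the fEPSP following a stimulus.

    The pre-stimulus mean is subtracted (DC-offset invariance), the peak
    deflection after the artifact-blanking window is located, and the slope
    is the OLS slope of voltage against time over the segment between the
    20% and 80% peak crossings immediately preceding the peak. The segment is
    found by walking backwards from the peak, which keeps the fiber volley
    out of the fit. Peak and crossings are detected on a lightly smoothed
    copy (``smooth_ms`` boxcar) so single noisy samples do not truncate the
    fit window; the OLS fit itself uses the raw samples.

    Returns ``{"slope": mV/ms (signed), "onset_ms", "peak_ms", "ok"}``;
    ``ok`` is False (slope NaN) when no deflection exceeds the noise floor.
    """
    if params is None:
        params = SlopeParams()
    stim = sweep.stim_times_ms[stim_index]
    t, v = sweep.time_ms, sweep.voltage_mv

    pre = t < stim
    base = v[pre].mean() if pre.any() else v[0]
    dv = v - base
    width = max(1, int(round(params.smooth_ms / sweep.dt_ms)))
    sm = (ndimage.uniform_filter1d(dv, width) if width > 1 else dv)

    lo = stim + params.artifact_blank_ms
    hi = search_end_ms if search_end_ms is not None else t[-1]
    seg = (t >= lo) & (t <= hi)
    if not seg.any():
        return {"slope": np.nan, "onset_ms": np.nan, "peak_ms": np.nan,
                "ok": False}
    idx = np.flatnonzero(seg)
    # fEPSP is negative-going: find the most negative deflection
    pk_local = int(np.argmin(sm[idx]))
    peak_val = sm[idx][pk_local]
    if -peak_val < params.min_peak_mv:
        return {"slope": np.nan, "onset_ms": np.nan, "peak_ms": np.nan,
                "ok": False}
    pk = idx[pk_local]

    def cross_back(frac: float) -> int:
        """Last sample before the peak where the smoothed deflection is
        still beyond frac * peak."""
        thr = frac * peak_val  # negative
        i = pk
        while i > idx[0] and sm[i - 1] <= thr:
            i -= 1
        return i

    i_hi = cross_back(params.fit_hi)
    i_lo = cross_back(params.fit_lo)
    i_on = cross_back(params.onset_threshold)
    if i_hi <= i_lo:
        i_hi = min(i_lo + 1, pk)
    if i_hi <= i_lo:
        return {"slope": np.nan, "onset_ms": np.nan, "peak_ms": np.nan,
                "ok": False}
    fit = sps.linregress(t[i_lo:i_hi + 1], dv[i_lo:i_hi + 1])
    return {
        "slope": float(fit.slope),
        "onset_ms": float(t[i_on]),
        "peak_ms": float(t[pk]),
        "ok": True,
    }


# ---------------------------------------------------------------------------
# Binning, normalization, QC
# ---------------------------------------------------------------------------

def bin_and_normalize(
    slopes: np.ndarray,
    sweep_times_min: np.ndarray,
    min_baseline_min: float = 10.0,
) -> BinnedTimeCourse:
    """Bin slope magnitudes per minute and normalize to the baseline mean.

    Sweeps are grouped by ``floor(sweep_time)``; each bin is the mean slope
    magnitude of its sweeps; the course is scaled so the mean of all
    baseline bins (bin start < 0) is 100. Empty minutes are reported as NaN
    bins with ``n_sweeps`` 0.
    """
    slopes = np.abs(np.asarray(slopes, dtype=float))
    times = np.asarray(sweep_times_min, dtype=float)
    ok = np.isfinite(slopes)
    slopes, times = slopes[ok], times[ok]
    if len(slopes) == 0:
        raise ValueError("no valid slopes to bin")
    bins = np.floor(times).astype(int)
    lo, hi = bins.min(), bins.max()
    minutes = np.arange(lo, hi + 1)
    mean = np.full(len(minutes), np.nan)
    count = np.zeros(len(minutes), dtype=int)
    for i, m in enumerate(minutes):
        sel = bins == m
        count[i] = int(sel.sum())
        if count[i]:
            mean[i] = slopes[sel].mean()
    bl = (minutes < 0) & np.isfinite(mean)
    if minutes[bl].size and (0 - minutes[bl].min()) < min_baseline_min:
        raise ValueError(
            f"need at least {min_baseline_min:g} baseline minutes")
    if not bl.any():
        raise ValueError("no baseline bins (t < 0)")
    base = mean[bl].mean()
    if base <= 0:
        raise ValueError("baseline mean slope must be positive")
    return BinnedTimeCourse(minutes=minutes, percent=100.0 * mean / base,
                            n_sweeps=count)


def baseline_drift_qc_ephys(
    course: BinnedTimeCourse,
    threshold_percent: float = EPHYS_DRIFT_THRESHOLD,
) -> BinnedTimeCourse:
    """Baseline-drift exclusion for a binned fEPSP time course.

    Same OLS drift metric as the imaging QC, but the exclusion convention is
    reversed: experiments are excluded iff drift > threshold, so a course
    drifting by exactly the threshold is retained.
    """
    bl = (course.minutes < 0) & np.isfinite(course.percent)
    if int(bl.sum()) < 3:
        course.drift_percent = np.nan
        course.qc_passed = False
        return course
    t = course.minutes[bl].astype(float)
    v = course.percent[bl]
    slope = sps.linregress(t, v).slope
    span = t.max() - t.min()
    drift = abs(slope) * span / v.mean() * 100.0
    course.drift_percent = float(drift)
    course.qc_passed = not (drift > threshold_percent)
    return course


def quantify_ltd(
    course: BinnedTimeCourse,
    window: tuple[float, float] = (50.0, 60.0),
    reference: tuple[float, float] = (-10.0, 0.0),
) -> dict:
    """Windowed LTD magnitude from a QC-passing binned time course.

    Bins belong to a window when their centre (bin start + 0.5 min) falls in
    the half-open interval; with the default windows this selects post bins
    50..59 and the last 10 baseline bins -10..-1.
    """
    if not course.qc_passed:
        raise ValueError("course failed baseline-drift QC")
    centers = course.minutes + 0.5
    win = (centers > window[0]) & (centers <= window[1])
    ref = (centers > reference[0]) & (centers <= reference[1])
    win &= np.isfinite(course.percent)
    ref &= np.isfinite(course.percent)
    if not win.any():
        raise ValueError("no bins in the post-treatment window")
    if not ref.any():
        raise ValueError("no bins in the baseline reference window")
    return {
        "window_mean_percent": float(course.percent[win].mean()),
        "baseline_reference_percent": float(course.percent[ref].mean()),
    }


# ---------------------------------------------------------------------------
# Paired-pulse facilitation
# ---------------------------------------------------------------------------

def ppf_ratio(
    paired: Sweep,
    template: Sweep | None = None,
    params: SlopeParams | None = None,
) -> dict:
    """Paired-pulse facilitation ratio slope2 / slope1.

    The second response rides on the decaying tail of the first; it is
    isolated by template subtraction: a single-pulse sweep (same stimulus
    strength, one stimulus at the time of the paired sweep's first stimulus)
    is subtracted sample-wise, leaving only the second response. If no
    template is given, the paired sweep itself truncated before stimulus 2
    is extrapolated by its last pre-stimulus-2 fitted exponential decay —
    only adequate at long inter-stimulus intervals; providing a template is
    recommended.

    Returns ``{"ratio", "slope1", "slope2", "ok"}``.
    """
    if len(paired.stim_times_ms) != 2:
        raise ValueError("paired sweep must contain exactly two stimuli")
    if params is None:
        params = SlopeParams()
    s1_t, s2_t = paired.stim_times_ms
    r1 = measure_initial_slope(paired, params, stim_index=0,
                               search_end_ms=s2_t)
    if not r1["ok"]:
        return {"ratio": np.nan, "slope1": np.nan, "slope2": np.nan,
                "ok": False}

    if template is not None:
        resid = paired.voltage_mv - template.voltage_mv
    else:
        resid = paired.voltage_mv - _exp_tail_extrapolation(paired, s2_t)
    iso = Sweep(paired.time_ms, resid, [s2_t],
                sweep_time_min=paired.sweep_time_min,
                sweep_id=paired.sweep_id + ":resp2")
    r2 = measure_initial_slope(iso, params, stim_index=0)
    if not r2["ok"]:
        return {"ratio": np.nan, "slope1": r1["slope"], "slope2": np.nan,
                "ok": False}
    return {
        "ratio": abs(r2["slope"]) / abs(r1["slope"]),
        "slope1": r1["slope"],
        "slope2": r2["slope"],
        "ok": True,
    }


def _exp_tail_extrapolation(sweep: Sweep, stim2_ms: float) -> np.ndarray:
    """Extrapolate the first response's decay past stimulus 2.

    Fits log|v| over the last quarter of the inter-stimulus window and
    extends the fitted exponential; before stimulus 2 the sweep itself is
    returned unchanged.
    """
    t, v = sweep.time_ms, sweep.voltage_mv
    pre = t < sweep.stim_times_ms[0]
    base = v[pre].mean() if pre.any() else v[0]
    dv = v - base
    s1 = sweep.stim_times_ms[0]
    fit_lo = s1 + 0.75 * (stim2_ms - s1)
    sel = (t >= fit_lo) & (t < stim2_ms) & (dv < 0)
    out = np.where(t < stim2_ms, v, base)
    if sel.sum() >= 3:
        coef = np.polyfit(t[sel], np.log(-dv[sel]), 1)
        tail = t >= stim2_ms
        out[tail] = base - np.exp(np.polyval(coef, t[tail]))
    return out
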