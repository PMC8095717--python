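"""Ground-truthed synthetic data for the imaging and electrophysiology pipelines.

Three generators emulate the study conditions of a simultaneous two-photon /
field-recording LTD experiment in acute hippocampal slices:

* :func:`simulate_imaging_experiment` renders a two-channel Z-stack time
  series (volume reporter + SEP surface-receptor reporter): 512 x 512 px
  frames, 20 slices at 1 um, 24 frames 4 min apart (30 min baseline, 1 h
  post-treatment), with spines as 3D Gaussian blobs on a constant-intensity
  dendrite band, treatment-locked shrinkage, SEP quenching on
  internalization, per-channel photobleaching, a global per-frame lognormal
  gain, random-walk lateral drift, and Poisson + Gaussian read noise.
* :func:`simulate_fepsp_experiment` produces stimulus-locked fEPSP sweeps at
  one per 30 s whose initial slope follows an exponential-approach synaptic
  weight model ``w(t) = 1 - M (1 - exp(-t/tau))`` after treatment.
* :func:`simulate_ppf_sweeps` produces paired-pulse sweeps whose second
  response is scaled by ``f(ISI) = 1 + ppf_max exp(-ISI/ppf_tau)`` and built
  by exact linear summation of two single-pulse waveforms.

Every generator stores its full ground truth alongside the data and is
bit-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import Roi, RoiSet, ZStackSeries, SPINE_ROI_DIAMETER_PX
from .ephys import Sweep, SweepSeries

__all__ = [
    "ImagingSimConfig",
    "SpineSpec",
    "EphysSimConfig",
    "GroundTruth",
    "CellSpec",
    "simulate_imaging_experiment",
    "make_spine_grid",
    "simulate_fepsp_experiment",
    "simulate_ppf_sweeps",
    "simulate_group_summary",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ImagingSimConfig:
    """Acquisition and nuisance parameters of the imaging simulator.

    Defaults reproduce the experimental cadence: 24 frames of 20 x 512 x 512
    voxels at 4-min intervals, 30 min of baseline, 1-um z-step and a 60x
    objective with x5.65 digital zoom (0.066 um/px, configurable; the field
    of view in um is not pinned down by the protocol).
    """

    frame_count: int = 24
    frame_interval: float = 4.0          # min
    baseline_duration: float = 30.0      # min
    z_slices: int = 20
    z_step: float = 1.0                  # um
    frame_size: tuple[int, int] = (512, 512)   # (Y, X) px
    pixel_size: float = 0.066            # um/px
    psf_sigma: float = 2.0               # px, lateral
    psf_sigma_z: float = 1.5             # slices, axial
    background_level: float = 50.0       # photons/px
    bleach_rate_per_frame: float = 0.005     # fraction lost per frame, both channels
    fluctuation_sigma: float = 0.05      # lognormal sigma of per-frame gain
    drift_step_sigma: float = 0.5        # px/frame random-walk step
    read_noise_sigma: float = 3.0        # photons
    shot_noise: bool = True
    sep_channel: bool = True
    dendrite_y: float | None = None      # px; default: 1/4 of frame height
    dendrite_halfwidth: float = 3.0      # px
    dendrite_z_halfwidth: int = 1        # slices around the central slice
    dendrite_intensity: float = 30.0     # photons/px/voxel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1 or self.z_slices < 1:
            raise ValueError("frame_count and z_slices must be positive")
        if self.frame_interval <= 0 or self.baseline_duration <= 0:
            raise ValueError("frame_interval and baseline_duration must be "
                             "positive")
        # first frame at -baseline_duration; need >= 2 frames before t = 0
        if self.baseline_duration < 2 * self.frame_interval:
            raise ValueError("baseline must span at least two frames")
        for name in ("psf_sigma", "psf_sigma_z", "background_level",
                     "bleach_rate_per_frame", "fluctuation_sigma",
                     "drift_step_sigma", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.bleach_rate_per_frame < 1:
            raise ValueError("bleach_rate_per_frame must be in [0, 1)")

    @property
    def timeline(self) -> np.ndarray:
        """Frame times in minutes relative to treatment onset."""
        return (-self.baseline_duration
                + self.frame_interval * np.arange(self.frame_count))


@dataclass
class SpineSpec:
    """Ground-truth description of one simulated spine.

    ``shrinkage_fraction`` is the fractional volume loss after
    ``onset_time`` (minutes relative to treatment). ``recovery`` is either
    ``None`` (persistent step shrinkage) or a time constant in minutes for
    exponential recovery of the volume back toward baseline.
    ``sep_surface_fraction_course`` gives the per-frame fraction of
    receptors on the surface (green channel); ``None`` means all-surface.
    """

    spine_id: str
    center: tuple[float, float]               # (x, y) px at t = 0
    z_center: float = 10.0                    # slice index
    base_point: tuple[float, float] | None = None
    baseline_volume: float = 2.0e4            # integrated photons
    shrinkage_fraction: float = 0.0
    onset_time: float = 0.0                   # min relative to treatment
    recovery: float | None = None             # min, exponential; None = persistent
    sep_surface_fraction_course: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrinkage_fraction <= 1.0:
            raise ValueError("shrinkage_fraction must be in [0, 1]")
        if self.baseline_volume < 0:
            raise ValueError("baseline_volume must be >= 0")
        if self.sep_surface_fraction_course is not None:
            c = np.asarray(self.sep_surface_fraction_course, dtype=float)
            if np.any((c < 0) | (c > 1)):
                raise ValueError("surface fractions must lie in [0, 1]")
            self.sep_surface_fraction_course = c

    def volume_course(self, timeline: np.ndarray) -> np.ndarray:
        """Relative volume (1 = baseline) at each frame time."""
        t = np.asarray(timeline, dtype=float)
        v = np.ones_like(t)
        post = t >= self.onset_time
        if self.recovery is None:
            v[post] = 1.0 - self.shrinkage_fraction
        else:
            u = t[post] - self.onset_time
            v[post] = 1.0 - self.shrinkage_fraction * np.exp(-u / self.recovery)
        return v


@dataclass
class EphysSimConfig:
    """Parameters of the field-potential simulator.

    Defaults follow the recording protocol (stimulation at one pulse per
    30 s, 50-kHz digitization, 30 min baseline + 60 min post) with an LTD
    magnitude matching a strong chemically induced depression (weight
    settling at 32% of baseline).
    """

    sweep_rate: float = 1.0 / 30.0        # Hz (one sweep per 30 s)
    sweep_duration: float = 100.0         # ms
    sampling_rate: float = 50.0           # kHz
    baseline_duration: float = 30.0       # min
    post_duration: float = 60.0           # min
    ltd_magnitude: float = 0.68           # fractional slope loss
    ltd_tau: float = 5.0                  # min
    fiber_volley_amplitude: float = 0.1   # mV
    epsp_amplitude: float = 1.0           # mV
    epsp_rise_tau: float = 2.0            # ms
    epsp_decay_tau: float = 15.0          # ms
    epsp_latency: float = 2.0             # ms after stimulus
    stim_time: float = 10.0               # ms into the sweep
    artifact_amplitude: float = 2.0       # mV
    noise_sigma: float = 0.02             # mV
    ppf_isis: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0)  # ms
    ppf_max: float = 0.5
    ppf_tau: float = 100.0                # ms
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.sampling_rate * self.sweep_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate x sweep_duration must be an "
                             "integer sample count")
        if not 0.0 <= self.ltd_magnitude <= 1.0:
            raise ValueError("ltd_magnitude must be in [0, 1]")
        for name in ("ltd_tau", "epsp_rise_tau", "epsp_decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsp_rise_tau >= self.epsp_decay_tau:
            raise ValueError("epsp_rise_tau must be shorter than "
                             "epsp_decay_tau")

    def weight(self, t_min: np.ndarray | float) -> np.ndarray | float:
        """Synaptic weight course: 1 over baseline, exponential approach to
        ``1 - ltd_magnitude`` after treatment at t = 0."""
        t = np.asarray(t_min, dtype=float)
        w = np.where(
            t < 0, 1.0,
            1.0 - self.ltd_magnitude * (1.0 - np.exp(-np.maximum(t, 0)
                                                     / self.ltd_tau)))
        return w if w.ndim else float(w)

    def ppf_factor(self, isi_ms: float) -> float:
        """True facilitation f(ISI) = 1 + ppf_max exp(-ISI/ppf_tau)."""
        return 1.0 + self.ppf_max * math.exp(-isi_ms / self.ppf_tau)


@dataclass
class GroundTruth:
    """Everything the simulators injected, for downstream validation."""

    # imaging
    volume_traces_au: dict[str, np.ndarray] = field(default_factory=dict)
    volume_traces_percent: dict[str, np.ndarray] = field(default_factory=dict)
    sep_surface_traces: dict[str, np.ndarray] = field(default_factory=dict)
    sep_traces_percent: dict[str, np.ndarray] = field(default_factory=dict)
    drift_offsets: np.ndarray | None = None       # (T, 2) as (dx, dy)
    gain_series: np.ndarray | None = None
    bleach_curves: dict[str, np.ndarray] = field(default_factory=dict)
    spine_overlap_flags: dict[str, bool] = field(default_factory=dict)
    # electrophysiology
    weight_course: np.ndarray | None = None       # per-sweep true weight
    sweep_times_min: np.ndarray | None = None
    true_slope_per_sweep: np.ndarray | None = None
    ppf_true: dict[float, float] = field(default_factory=dict)
    ppf_merged: dict[float, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Imaging simulator
# ---------------------------------------------------------------------------

def _gauss1d(coords: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((coords - center) / sigma) ** 2) / (
        sigma * math.sqrt(2.0 * math.pi))


def _band_coverage(n: int, center: float, halfwidth: float) -> np.ndarray:
    """Fractional coverage of each unit pixel row by the band
    [center - halfwidth, center + halfwidth]."""
    edges_lo = np.arange(n, dtype=float)
    lo = np.maximum(edges_lo, center - halfwidth)
    hi = np.minimum(edges_lo + 1.0, center + halfwidth)
    return np.clip(hi - lo, 0.0, 1.0)


def _place_rois(config: ImagingSimConfig, spines: list[SpineSpec],
                dend_y: float, rng: np.random.Generator) -> RoiSet:
    h, w = config.frame_size
    roi_r = SPINE_ROI_DIAMETER_PX / 2.0
    rois = [Roi(sp.spine_id, "spine", sp.center, SPINE_ROI_DIAMETER_PX,
                base_point=sp.base_point if sp.base_point is not None
                else (sp.center[0], dend_y))
            for sp in spines]

    # five shaft ROIs spread along the dendrite, clear of spine heads
    # (no ROI overlap, no blob tail inside the shaft mask)
    shaft_d = 6.0
    clearance = max(roi_r + shaft_d / 2 + 0.5,
                    shaft_d / 2 + 6.0 * config.psf_sigma)
    cand = np.linspace(shaft_d / 2 + 1, w - shaft_d / 2 - 1, 200)
    if spines:
        centers = np.array([sp.center for sp in spines])
        d = np.hypot(cand[:, None] - centers[None, :, 0],
                     dend_y - centers[None, :, 1])
        cand = cand[np.min(d, axis=1) >= clearance]
    if len(cand) < 5:
        raise ValueError("frame too crowded to place 5 shaft ROIs")
    for i, j in enumerate(np.linspace(0, len(cand) - 1, 5).round().astype(int)):
        rois.append(Roi(f"shaft_{i}", "shaft", (float(cand[j]), dend_y),
                        shaft_d))

    # three background ROIs by rejection sampling in signal-free regions
    margin = roi_r + 1
    keepout_dend = config.dendrite_halfwidth + roi_r + 3.0
    keepout_spine = roi_r + SPINE_ROI_DIAMETER_PX / 2.0 + 4.0 * config.psf_sigma
    placed: list[tuple[float, float]] = []
    for i in range(3):
        for attempt in range(20000):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if abs(cy - dend_y) <= keepout_dend:
                continue
            if any(np.hypot(cx - sp.center[0], cy - sp.center[1])
                   <= keepout_spine for sp in spines):
                continue
            if any(np.hypot(cx - px, cy - py) <= SPINE_ROI_DIAMETER_PX
                   for px, py in placed):
                continue
            placed.append((cx, cy))
            rois.append(Roi(f"background_{i}", "background",
                            (cx, cy), SPINE_ROI_DIAMETER_PX))
            break
        else:
            raise ValueError(
                "could not place background ROIs in a signal-free region; "
                "frame too small or too crowded")
    return RoiSet(rois, dendrite_length_um=w * config.pixel_size)


def simulate_imaging_experiment(
    config: ImagingSimConfig,
    spines: list[SpineSpec],
    allow_overlap: bool = False,
) -> tuple[ZStackSeries, RoiSet, GroundTruth]:
    """Render a ground-truthed two-channel Z-stack time series.

    Red-channel spine blobs have an integrated intensity of
    ``baseline_volume x volume_course(t) x bleach(t) x gain(t)`` before
    noise; the green (SEP) channel additionally scales with the per-frame
    surface fraction. Spines must sit fully inside the frame with an
    ROI-radius margin and their ROIs must not overlap (unless
    ``allow_overlap``, in which case overlaps are flagged in the ground
    truth). Identical seeds give bit-identical output.
    """
    h, w = config.frame_size
    roi_r = SPINE_ROI_DIAMETER_PX / 2.0
    dend_y = config.dendrite_y if config.dendrite_y is not None else h / 4.0

    for sp in spines:
        cx, cy = sp.center
        if not (roi_r <= cx <= w - roi_r and roi_r <= cy <= h - roi_r):
            raise ValueError(
                f"spine {sp.spine_id} at {sp.center} lies within {roi_r} px "
                f"of the frame edge ({w}x{h})")
        if not 0 <= sp.z_center <= config.z_slices - 1:
            raise ValueError(f"spine {sp.spine_id} z_center outside stack")
        if abs(cy - dend_y) < roi_r + config.dendrite_halfwidth + 1:
            raise ValueError(
                f"spine {sp.spine_id} ROI would overlap the dendrite band; "
                "move the head further from the dendrite")
    overlap_flags = {sp.spine_id: False for sp in spines}
    for i, a in enumerate(spines):
        for b in spines[i + 1:]:
            d = math.hypot(a.center[0] - b.center[0],
                           a.center[1] - b.center[1])
            if d < SPINE_ROI_DIAMETER_PX:
                if not allow_overlap:
                    raise ValueError(
                        f"spine ROIs {a.spine_id} and {b.spine_id} overlap "
                        f"(center distance {d:.1f} px < "
                        f"{SPINE_ROI_DIAMETER_PX:g} px)")
                overlap_flags[a.spine_id] = overlap_flags[b.spine_id] = True

    rng = np.random.default_rng(config.seed)
    timeline = config.timeline
    nt, nz = config.frame_count, config.z_slices

    # nuisance series
    steps = (rng.normal(0.0, config.drift_step_sigma, size=(nt - 1, 2))
             if config.drift_step_sigma > 0 else np.zeros((nt - 1, 2)))
    drift = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])  # (dx, dy)
    gain = (np.exp(rng.normal(0.0, config.fluctuation_sigma, size=nt))
            if config.fluctuation_sigma > 0 else np.ones(nt))
    bleach = (1.0 - config.bleach_rate_per_frame) ** np.arange(nt)
    bleach_curves = {"red": bleach.copy(), "green": bleach.copy()}

    # ground-truth traces
    gt = GroundTruth(drift_offsets=drift, gain_series=gain,
                     bleach_curves=bleach_curves,
                     spine_overlap_flags=overlap_flags)
    baseline_mask = timeline < 0
    for sp in spines:
        v = sp.baseline_volume * sp.volume_course(timeline)
        gt.volume_traces_au[sp.spine_id] = v
        gt.volume_traces_percent[sp.spine_id] = \
            100.0 * v / v[baseline_mask].mean()
        surf = (np.ones(nt) if sp.sep_surface_fraction_course is None
                else np.asarray(sp.sep_surface_fraction_course, dtype=float))
        if len(surf) != nt:
            raise ValueError(
                f"spine {sp.spine_id}: surface-fraction course length "
                f"{len(surf)} != frame count {nt}")
        gt.sep_surface_traces[sp.spine_id] = surf
        sep = v * surf
        denom = sep[baseline_mask].mean()
        gt.sep_traces_percent[sp.spine_id] = (
            100.0 * sep / denom if denom > 0 else np.full(nt, np.nan))

    # rendering
    zc_dend = (nz - 1) / 2.0
    z_lo = int(round(zc_dend)) - config.dendrite_z_halfwidth
    z_hi = int(round(zc_dend)) + config.dendrite_z_halfwidth
    zs = np.arange(nz, dtype=float)

    red = np.zeros((nt, nz, h, w), dtype=np.float64)
    green = (np.zeros((nt, nz, h, w), dtype=np.float64)
             if config.sep_channel else None)
    half_ext = int(math.ceil(6.0 * config.psf_sigma)) + 1

    for t in range(nt):
        dx, dy = drift[t]
        g = gain[t]
        # dendrite: hard-edged constant band with subpixel edge coverage
        cov = _band_coverage(h, dend_y + dy, config.dendrite_halfwidth)
        dend_amp = config.dendrite_intensity * bleach[t] * g
        for z in range(max(z_lo, 0), min(z_hi, nz - 1) + 1):
            red[t, z] += dend_amp * cov[:, None]
            if green is not None:
                green[t, z] += dend_amp * cov[:, None]
        # spine blobs: separable 3D Gaussians with unit integral
        for sp in spines:
            cx, cy = sp.center[0] + dx, sp.center[1] + dy
            x0 = max(int(cx) - half_ext, 0)
            x1 = min(int(cx) + half_ext + 1, w)
            y0 = max(int(cy) - half_ext, 0)
            y1 = min(int(cy) + half_ext + 1, h)
            gx = _gauss1d(np.arange(x0, x1) + 0.5, cx, config.psf_sigma)
            gy = _gauss1d(np.arange(y0, y1) + 0.5, cy, config.psf_sigma)
            gz = _gauss1d(zs, sp.z_center, config.psf_sigma_z)
            blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            amp_r = gt.volume_traces_au[sp.spine_id][t] * bleach[t] * g
            red[t, :, y0:y1, x0:x1] += amp_r * blob
            if green is not None:
                amp_g = (gt.volume_traces_au[sp.spine_id][t]
                         * gt.sep_surface_traces[sp.spine_id][t]
                         * bleach[t] * g)
                green[t, :, y0:y1, x0:x1] += amp_g * blob

    red += config.background_level
    if green is not None:
        green += config.background_level
    if config.shot_noise:
        red = rng.poisson(red).astype(np.float64)
        if green is not None:
            green = rng.poisson(green).astype(np.float64)
    if config.read_noise_sigma > 0:
        red = red + rng.normal(0.0, config.read_noise_sigma, size=red.shape)
        if green is not None:
            green = green + rng.normal(0.0, config.read_noise_sigma,
                                       size=green.shape)

    series = ZStackSeries(red=red, green=green, timeline=timeline,
                          z_step_um=config.z_step,
                          pixel_size_um=config.pixel_size)
    rois = _place_rois(config, spines, dend_y, rng)
    return series, rois, gt


# ---------------------------------------------------------------------------
# Electrophysiology simulators
# ---------------------------------------------------------------------------

def _epsp_shape(u_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials EPSP shape, peak-normalized to 1."""
    u = np.maximum(u_ms, 0.0)
    s = np.where(u_ms >= 0, np.exp(-u / decay) - np.exp(-u / rise), 0.0)
    u_pk = math.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    s_pk = math.exp(-u_pk / decay) - math.exp(-u_pk / rise)
    return s / s_pk


def _single_response(t_ms: np.ndarray, stim_ms: float,
                     config: EphysSimConfig, weight: float) -> np.ndarray:
    """Noise-free voltage of one stimulus + fiber volley + EPSP."""
    v = np.zeros_like(t_ms)
    u = t_ms - stim_ms
    # biphasic stimulus artifact (blanked by analysis)
    v += np.where((u >= 0) & (u < 0.2), config.artifact_amplitude, 0.0)
    v += np.where((u >= 0.2) & (u < 0.4), -config.artifact_amplitude, 0.0)
    # fiber volley: brief negative gaussian, amplitude independent of LTD;
    # gated causally so no tail precedes the stimulus
    v -= np.where(u >= 0,
                  config.fiber_volley_amplitude * np.exp(
                      -0.5 * ((u - 1.0) / 0.25) ** 2),
                  0.0)
    # negative-going EPSP scaled by the synaptic weight
    v -= (config.epsp_amplitude * weight
          * _epsp_shape(u - config.epsp_latency,
                        config.epsp_rise_tau, config.epsp_decay_tau))
    return v


def _epsp_true_slope(config: EphysSimConfig, weight: float = 1.0) -> float:
    """Maximal rising-phase derivative of the noise-free EPSP (mV/ms),
    by dense numerical differentiation of the closed-form waveform."""
    u = np.linspace(0.0, 5.0 * config.epsp_rise_tau, 20001)
    s = _epsp_shape(u, config.epsp_rise_tau, config.epsp_decay_tau)
    return float(weight * config.epsp_amplitude * np.max(np.gradient(s, u)))


def simulate_fepsp_experiment(
    config: EphysSimConfig,
) -> tuple[SweepSeries, GroundTruth]:
    """Simulate a chemical-LTD field-recording experiment.

    One sweep per stimulation interval (30 s at the default rate) from
    ``-baseline_duration`` to ``+post_duration`` minutes; each sweep carries
    a stimulus artifact, a fiber volley and an EPSP whose amplitude (and
    hence initial slope) is proportional to the synaptic weight ``w(t)``.
    """
    rng = np.random.default_rng(config.seed)
    n_samp = int(round(config.sampling_rate * config.sweep_duration))
    t_ms = np.arange(n_samp) / config.sampling_rate
    interval_min = 1.0 / config.sweep_rate / 60.0
    n_sweeps = int(round((config.baseline_duration + config.post_duration)
                         / interval_min))
    times = -config.baseline_duration + interval_min * np.arange(n_sweeps)
    weights = np.asarray(config.weight(times))

    sweeps = []
    for k in range(n_sweeps):
        v = _single_response(t_ms, config.stim_time, config, weights[k])
        if config.noise_sigma > 0:
            v = v + rng.normal(0.0, config.noise_sigma, size=n_samp)
        sweeps.append(Sweep(t_ms, v, [config.stim_time],
                            sweep_time_min=float(times[k]),
                            sweep_id=f"sweep_{k:04d}"))
    gt = GroundTruth(weight_course=weights, sweep_times_min=times,
                     true_slope_per_sweep=np.array(
                         [_epsp_true_slope(config, wk) for wk in weights]))
    return SweepSeries(sweeps, sampling_rate_khz=config.sampling_rate), gt


def simulate_ppf_sweeps(
    config: EphysSimConfig,
    isis: list[float] | None = None,
) -> tuple[SweepSeries, GroundTruth]:
    """Simulate paired-pulse sweeps plus a single-pulse template sweep.

    The series starts with one single-pulse sweep (``sweep_id='single'``,
    the subtraction template), followed by one paired sweep per
    inter-stimulus interval. The paired waveform is the exact sample-wise
    sum of the first response and a second response scaled by
    ``f(ISI) = 1 + ppf_max exp(-ISI/ppf_tau)``. ISIs short enough that the
    second stimulus precedes the first EPSP's peak are flagged as merged in
    the ground truth.
    """
    if isis is None:
        isis = list(config.ppf_isis)
    if any(isi <= 0 for isi in isis):
        raise ValueError("inter-stimulus intervals must be positive")
    rng = np.random.default_rng(config.seed)
    tail_ms = 90.0
    duration = max(config.sweep_duration,
                   math.ceil(config.stim_time + max(isis) + tail_ms))
    if any(isi >= duration for isi in isis):
        raise ValueError("ISI must be shorter than the sweep duration")
    n_samp = int(round(config.sampling_rate * duration))
    t_ms = np.arange(n_samp) / config.sampling_rate

    u_pk = (math.log(config.epsp_decay_tau / config.epsp_rise_tau)
            / (1.0 / config.epsp_rise_tau - 1.0 / config.epsp_decay_tau))
    merge_isi = config.epsp_latency + u_pk

    first = _single_response(t_ms, config.stim_time, config, 1.0)
    sweeps = [Sweep(t_ms, first + (rng.normal(0, config.noise_sigma, n_samp)
                                   if config.noise_sigma > 0 else 0.0),
                    [config.stim_time], sweep_id="single")]
    gt = GroundTruth()
    for isi in isis:
        f = config.ppf_factor(isi)
        second = _single_response(t_ms, config.stim_time + isi, config, f)
        v = first + second
        if config.noise_sigma > 0:
            v = v + rng.normal(0.0, config.noise_sigma, size=n_samp)
        sweeps.append(Sweep(t_ms, v,
                            [config.stim_time, config.stim_time + isi],
                            sweep_id=f"ppf_{isi:g}ms"))
        gt.ppf_true[isi] = f
        gt.ppf_merged[isi] = bool(isi < merge_isi)
    return SweepSeries(sweeps, sampling_rate_khz=config.sampling_rate), gt


def make_spine_grid(
    config: ImagingSimConfig,
    n_spines: int = 5,
    shrinkage: float = 0.16,
    onset_time: float = 0.0,
    head_offset: float = 32.0,
    baseline_volume: float = 2.0e4,
    sep_surface_drop: float = 0.0,
    volume_jitter: float = 0.0,
    seed: int | None = None,
) -> list[SpineSpec]:
    """Lay out spines evenly along the dendrite with a common effect.

    Heads sit ``head_offset`` px from the dendrite centerline (far enough
    that spine ROIs never touch the dendrite band); bases sit on the
    centerline below each head. ``sep_surface_drop`` reduces the SEP surface
    fraction from 1 to ``1 - drop`` at treatment onset. ``volume_jitter``
    draws per-spine baseline volumes from a lognormal spread (requires
    ``seed``), giving a size distribution for stratified analyses.
    """
    h, w = config.frame_size
    dend_y = config.dendrite_y if config.dendrite_y is not None else h / 4.0
    cy = dend_y + head_offset
    if not SPINE_ROI_DIAMETER_PX / 2 <= cy <= h - SPINE_ROI_DIAMETER_PX / 2:
        raise ValueError("head_offset places spines outside the frame")
    xs = np.linspace(0.15 * w, 0.85 * w, n_spines)
    if n_spines > 1 and np.diff(xs)[0] < SPINE_ROI_DIAMETER_PX:
        raise ValueError("frame too narrow for this many spines")
    timeline = config.timeline
    surf = None
    if sep_surface_drop > 0:
        surf = np.where(timeline < onset_time, 1.0, 1.0 - sep_surface_drop)
    vols = np.full(n_spines, baseline_volume)
    if volume_jitter > 0:
        rng = np.random.default_rng(seed if seed is not None else config.seed)
        vols = baseline_volume * np.exp(
            rng.normal(0.0, volume_jitter, size=n_spines))
    return [
        SpineSpec(
            spine_id=f"spine_{i}",
            center=(float(x), float(cy)),
            z_center=(config.z_slices - 1) / 2.0,
            base_point=(float(x), float(dend_y)),
            baseline_volume=float(vols[i]),
            shrinkage_fraction=shrinkage,
            onset_time=onset_time,
            sep_surface_fraction_course=surf,
        )
        for i, x in enumerate(xs)
    ]


# ---------------------------------------------------------------------------
# Group-summary fixture generator
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """True mean, SD and sample size for one cell of a factorial design."""

    true_mean: float
    true_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each cell needs n >= 2")
        if self.true_sd < 0:
            raise ValueError("true_sd must be >= 0")


def simulate_group_summary(
    design: dict[str, CellSpec],
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, dict]]:
    """Draw per-animal Gaussian values for each design cell.

    Returns ``(raw, summaries)`` where ``raw[label]`` holds the n draws and
    ``summaries[label]`` their ``{"mean", "sem", "n"}`` (SEM with the n-1
    denominator).
    """
    rng = np.random.default_rng(seed)
    raw: dict[str, np.ndarray] = {}
    summaries: dict[str, dict] = {}
    for label, cell in design.items():
        vals = rng.normal(cell.true_mean, cell.true_sd, size=cell.n)
        raw[label] = vals
        sem = vals.std(ddof=1) / math.sqrt(cell.n) if cell.n > 1 else 0.0
        summaries[label] = {"mean": float(vals.mean()), "sem": float(sem),
                            "n": cell.n}
    return raw, summaries
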