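# Methods

Quantitative models, parameter defaults and numerical choices of the
`spineltd` package. All assertions about accuracy here are the ones
computed by the test suite and `scripts/acceptance.py`; nothing else is
claimed.

## 1. Imaging simulator (`spineltd.simulate`)

### Acquisition model

A two-channel Z-stack time series of a dendritic segment:

- **Timeline** — `frame_count = 24` frames at `frame_interval = 4` min,
  starting at `-baseline_duration = -30` min, so frames lie at
  −30, −26, …, 62 min relative to treatment onset (8 baseline frames).
- **Geometry** — `z_slices = 20` at `z_step = 1` µm; frames of
  `frame_size = 512×512` px at `pixel_size = 0.066` µm/px (a 60×
  objective with digital zoom; the physical field of view is configurable
  because it is not uniquely determined by the acquisition protocol).
- **Dendrite** — a hard-edged constant-intensity band (half-width 3 px,
  ±1 slice around the central slice, 30 photons/voxel) with exact subpixel
  row coverage. The hard edge guarantees that a spine ROI placed ≥ ROI
  radius + half-width + 1 px from the centerline receives exactly zero
  dendrite signal, which makes ground-truth comparisons exact; a diffraction
  -blurred dendrite would only add a deterministic offset handled by the
  background/shaft corrections.
- **Spines** — separable 3D Gaussian blobs (lateral σ = `psf_sigma = 2` px,
  axial σ = `psf_sigma_z = 1.5` slices) whose *integral* equals
  `baseline_volume × volume_course(t) × bleach(t) × gain(t)`. Volume is
  therefore encoded as integrated intensity, matching the integrated-ROI
  readout. `volume_course` is 1 during baseline and steps to
  `1 − shrinkage_fraction` at `onset_time` (optionally relaxing back with
  an exponential `recovery` time constant).
- **SEP channel** — the green channel scales the same blob by a per-frame
  surface fraction in [0, 1], modelling receptor internalization
  (quenching) on top of the volume change.

### Nuisance processes

- **Photobleaching** — `(1 − bleach_rate_per_frame)^t`, default 0.005/frame,
  both channels.
- **Global gain** — per-frame lognormal factor,
  `exp(N(0, fluctuation_sigma))`, default σ = 0.05, shared by all
  structures in a frame (laser/detection fluctuation).
- **Lateral drift** — 2D Gaussian random walk, step σ = 0.5 px/frame,
  frame 0 at (0, 0).
- **Noise** — Poisson shot noise on (signal + `background_level = 50`)
  photons plus Gaussian read noise (σ = 3).

Identical seeds give bit-identical output. The full injected state (volume
and surface-fraction courses in a.u. and percent, drift, gain, bleach,
overlap flags) is returned as `GroundTruth`.

### What the simulator does *not* emulate

Dendrite/spine morphological diversity (necks, irregular heads), axial
drift and focus loss, depth-dependent scattering, detector saturation,
spectral bleed-through between channels, activity-dependent transients, and
spatially varying background. These either do not affect the pipeline
quantities being validated or are covered conservatively by the QC path
(e.g. large drift → baseline-drift exclusion).

## 2. Imaging quantification (`spineltd.imaging`)

1. **Z-collapse** — maximum-intensity projection (default) or sum
   projection per frame.
2. **Registration** — translation-only, phase cross-correlation with
   20× upsampled-DFT subpixel refinement (`normalization=None`, which is
   markedly more accurate on low-contrast fluorescence frames), applied by
   cubic-spline interpolation with edge replication. Featureless frames
   are flagged and left unshifted. Accuracy (asserted): integer circular
   shifts recovered exactly; a pure half-pixel shift within 0.25 px.
3. **ROI traces** — integrated intensity inside constant circular ROIs;
   spine ROIs are 20 px diameter, plus 3 background and 5 shaft ROIs.
   Pixel centers sit at integer + 0.5; a pixel belongs to a mask iff its
   center is strictly within the radius. ROIs extending past the frame are
   marked invalid.
4. **Correction** — per frame: background estimate = mean per-pixel
   intensity of the background ROIs × spine mask area, subtracted; global
   gain = mean over shaft ROIs of each shaft's background-subtracted signal
   divided by its own baseline mean (so the gain is 1 on average during
   baseline), divided out. Because bleaching and the lognormal gain are
   shared between spines and shafts, both cancel *exactly*: the acceptance
   suite asserts a worst-case relative error < 1e−9 against ground truth
   (measured ~1e−14).
5. **Normalization** — percent of the trace's own baseline (t < 0) mean.
6. **Drift QC** — OLS line over baseline values vs time;
   `drift = |slope| × span / mean × 100`. A trace passes iff
   drift < 7 (strict: exactly 7% is excluded). An optional experiment-level
   policy (`apply_experiment_qc`) can demand that all traces pass.
7. **Windowed quantification** — per spine, mean percent over the
   post-treatment window [50, 60] min (closed; frames 50, 54, 58) against
   the reference window [−10, 0) (frames −10, −6, −2); the experiment value
   is the mean over QC-passing spines, and the per-spine (reference,
   window) pairs feed a paired t-test.
8. **Morphometrics** — spine density per 10 µm of dendrite and
   base-to-head-center spine length; size-stratified plasticity via a
   median split on baseline corrected intensity plus an OLS slope of the
   per-spine change against initial size.

## 3. Electrophysiology (`spineltd.ephys` + simulator)

### fEPSP model

Sweeps every 30 s (−30 to +60 min), 50 kHz, 100 ms. Each sweep contains a
biphasic ±2 mV stimulus artifact (0–0.4 ms post-stimulus), a fiber volley
(−0.1 mV Gaussian at 1 ms, σ = 0.25 ms, causally gated, amplitude
independent of LTD), and a negative-going EPSP: a peak-normalized
difference of exponentials (rise τ = 2 ms, decay τ = 15 ms, latency 2 ms)
scaled by `epsp_amplitude = 1 mV` × synaptic weight
`w(t) = 1 − M(1 − e^{−t/τ})` (defaults M = 0.68, τ = 5 min: weight settles
at 32% of baseline), plus Gaussian noise (σ = 0.02 mV).

### Initial slope

Pre-stimulus mean subtracted (DC invariance); 1 ms after the stimulus is
blanked; the peak negative deflection and its 20%/80% crossings are
detected on a lightly smoothed copy (0.6 ms boxcar) by walking back from
the peak — which keeps the fiber volley out of the fit and prevents single
noisy samples from truncating the window — while the OLS slope itself is
fit on the raw samples between the crossings. The smoothing width was set
by a bias analysis (ratio-of-ratios vs the noiseless value across widths),
not against any acceptance target. The 20–80% fit is a multiplicatively
biased estimate of the peak derivative; tests assert it matches the
closed-form 20–80% chord within 15% and, critically, that slope *ratios*
across sweeps are exact to 0.1% noiselessly, since every downstream
quantity is a ratio.

### Binning, QC, LTD window

Slope magnitudes are grouped by `floor(minute)`, averaged per bin and
scaled so the mean of baseline bins is 100 (≥10 baseline minutes
required; empty minutes are NaN). Baseline-drift QC uses the same OLS
metric as imaging but the reversed convention: excluded iff drift > 5
(exactly 5% is retained). LTD is the mean over bins whose centre
(start + 0.5) lies in (50, 60] — bins 50…59 — against bins −10…−1.
Acceptance: across 100 noisy simulated experiments the mean recovered
window is within 2 points of the injected weight-course mean (measured
31.4 vs 32.0).

### Paired-pulse facilitation

The simulator builds paired sweeps by exact linear summation of two
single-pulse responses, the second scaled by
`f(ISI) = 1 + ppf_max·e^{−ISI/ppf_tau}` (defaults 0.5, 100 ms; ISIs 25,
50, 100, 200, 400 ms), and prepends a single-pulse template sweep.
Analysis isolates the second response by template subtraction (preferred)
or, lacking a template, by extrapolating the first response's fitted
exponential tail — adequate only at long ISIs. Noiseless ratios match the
injected facilitation to 1% (template) / 5% (extrapolation); ISIs shorter
than latency + time-to-peak are flagged as merged and not quantified.

## 4. Statistics (`spineltd.stats`)

The experimental unit is the animal. SEM uses the n−1 denominator.
Unpaired comparisons use the pooled-variance Student t; raw input is
summarized first so the raw and printed-summary forms share one formula
path (asserted identical to 1e−12). The 2×2 between-subjects ANOVA
computes each effect from a single-df cell-mean contrast,
`SS = L² / Σ(1/n_ij)` against the pooled within-cell MSE with df = N − 4 —
the Type-III sum of squares, exact for 2×2 layouts balanced or not
(asserted against a statsmodels extra-sum-of-squares oracle to 1e−9).
Bonferroni post-hocs multiply each pairwise-cell p by the family size
(default: the four simple effects), capped at 1. Degenerate zero-variance
inputs return "undefined" results rather than infinities. Under the null,
both the t-test and the interaction F reject at 4.8–5.0% over 10,000
simulations (asserted within 4–6%).

Recomputing published figure-legend statistics from their printed
mean/SEM/n reproduces the reported values: p = 0.0286 (reported 0.0285),
0.00060 (0.00059), 0.00743 (0.0073), < 1e−4 (reported < 0.0001);
interaction F = 6.399 (reported 6.406) and 4.511 (4.52). The residual ~2%
discrepancies are what rounding of the printed means/SEMs propagates to.

## 5. Numerical and design choices

- **Windows** — post [50, 60] closed vs reference [−10, 0) for frames;
  bin-centre membership for minute bins. Chosen so the default frame/bin
  grids select exactly the intended frames/bins.
- **Strict-< vs strict-> QC** — imaging excludes at exactly 7%, ephys
  retains at exactly 5%; both boundary behaviours are pinned by tests.
- **Whether the drift criterion applies per spine or per experiment** is
  ambiguous in common usage; the package applies it per trace and exposes
  `apply_experiment_qc(..., policy="all")` for the stricter reading.
- **Scaled-down validation sizes** — recovery studies use 128×128 frames,
  5 slices and 4 spines (vs the full 512×512×20×5) so 100 seeded
  experiments run in about a minute; cadence, ROI sizes, analysis
  parameters and the noise model are unchanged.
- **Determinism** — all stochastic stages take explicit seeds
  (`numpy.random.default_rng`); pipeline reruns are byte-identical, and
  outputs carry a config hash, seed and per-trace QC decisions in a
  manifest.

## 6. Limitations

- The simulator validates the analysis, not biology: effect time courses
  are idealized steps/exponentials.
- Registration is translation-only; rotation or non-rigid tissue movement
  is out of scope (and would surface as drift-QC exclusion).
- The tail-extrapolation PPF fallback is unreliable at short ISIs and in
  noise; template subtraction is the supported path.
- At the default imaging SNR the 7% drift criterion excludes an
  appreciable fraction of individual spine traces; exclusions are
  uncorrelated with the plasticity effect (recovery stays unbiased), but
  per-experiment spine counts shrink accordingly.
- The 2×2 ANOVA assumes homoscedastic Gaussian cells (as does the
  pooled-variance t); a Welch option exists for two-group comparisons
  only.
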