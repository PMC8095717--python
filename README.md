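# spineltd

Dual-modality quantification of long-term synaptic depression (LTD):
structural plasticity of dendritic spines from two-photon time-lapse
imaging, functional depression from extracellular field recordings, the
factorial statistics used to compare genotypes and treatments, and a fully
ground-truthed synthetic-data generator for validating every stage.

## Scientific background

Group-I mGluR activation (e.g. by DHPG) and NMDAR activation both induce
LTD of hippocampal CA3→CA1 synapses, but they engage different structural
programs: NMDAR-LTD shrinks dendritic spines, and protein-synthesis- or
mTOR-dependent signalling can dissociate the functional depression from the
structural change — spine shrinkage can be blocked (rapamycin,
cycloheximide) while electrophysiological LTD persists, and the coupling
differs between wild-type and *Fmr1* knockout mice. Testing such
dissociations requires measuring, in the same preparation:

1. **spine volume over time** — two-photon Z-stacks of a dendritic segment
   every 4 minutes (30 min baseline, 1 h after treatment), spine volume
   read out as integrated fluorescence of a cell-filling reporter inside a
   fixed circular ROI, corrected for background and for global fluorescence
   fluctuations, normalized to baseline;
2. **surface AMPA receptors** — a pH-sensitive (SEP) reporter in a second
   channel, quantified through the identical pipeline;
3. **fEPSP initial slope** — stimulus-locked sweeps every 30 s, slope of
   the EPSP rising phase binned per minute and normalized to baseline;
4. **paired-pulse facilitation** — the ratio of the second to the first
   fEPSP slope at varying inter-stimulus intervals (a presynaptic marker);
5. **group statistics** — mean ± SEM per animal, paired/unpaired t-tests,
   and 2×2 (treatment × genotype) between-subjects ANOVA with Bonferroni
   post-hoc tests, computable from raw values *or* from printed
   figure-legend summaries.

`spineltd` implements all five, plus simulators that render synthetic
Z-stack series and sweep series with known ground truth (shrinkage
magnitude, synaptic-weight course, drift, gain, bleaching, facilitation),
so the accuracy of the whole analysis chain can be measured instead of
assumed.

## Worked example

```python
import numpy as np
from spineltd import (ImagingSimConfig, EphysSimConfig, make_spine_grid,
                      simulate_imaging_experiment, simulate_fepsp_experiment,
                      quantify_channel, quantify_structural_plasticity,
                      measure_initial_slope, bin_and_normalize,
                      baseline_drift_qc_ephys, quantify_ltd,
                      unpaired_t_summary, anova2x2)

# --- imaging: 16% spine shrinkage under realistic noise -------------------
cfg = ImagingSimConfig(frame_size=(128, 128), z_slices=5, seed=1)
spines = make_spine_grid(cfg, n_spines=4, shrinkage=0.16, volume_jitter=0.4,
                         seed=1)
series, rois, gt = simulate_imaging_experiment(cfg, spines)
res = quantify_channel(series, rois)
m = quantify_structural_plasticity(res["traces"])
print(f"spine volume 50-60 min: {m.window_mean_percent:.1f}% of baseline "
      f"({m.n_spines} spines passed QC; injected 84.0%)")

# --- electrophysiology: chemically induced LTD ----------------------------
ecfg = EphysSimConfig(seed=1)
sweeps, egt = simulate_fepsp_experiment(ecfg)
slopes = np.array([measure_initial_slope(sw)["slope"] for sw in sweeps])
course = bin_and_normalize(slopes, egt.sweep_times_min)
baseline_drift_qc_ephys(course)
ltd = quantify_ltd(course)
print(f"fEPSP slope 50-60 min:  {ltd['window_mean_percent']:.1f}% of "
      f"baseline (injected 32.0%)")

# --- statistics from published group summaries ----------------------------
t = unpaired_t_summary(65.29, 3.35, 16, 51.25, 5.44, 11)
print(f"WT vs KO LTD:           t({t.df}) = {t.statistic:.3f}, p = {t.p:.4f}")
a = anova2x2([{"mean": 84.89, "sem": 2.45, "n": 10},
              {"mean": 96.01, "sem": 1.44, "n": 12},
              {"mean": 88.19, "sem": 3.12, "n": 10},
              {"mean": 86.92, "sem": 2.65, "n": 12}])
ia = a.interaction
print(f"treatment x genotype:   F(1,{a.df_error}) = {ia.statistic:.3f}, "
      f"p = {ia.p:.4f}")
```

Output:

```
spine volume 50-60 min: 79.4% of baseline (3 spines passed QC; injected 84.0%)
fEPSP slope 50-60 min:  31.2% of baseline (injected 32.0%)
WT vs KO LTD:           t(25) = 2.324, p = 0.0286
treatment x genotype:   F(1,40) = 6.399, p = 0.0155
```

A single experiment is noisy (one seed recovered 79.4% here; across 100
seeds the mean is 83.7% against the injected 84%); the acceptance script
below quantifies that recovery systematically.

## Command-line interface

```
spineltd simulate imaging --seed 1 --out data/
spineltd simulate ephys   --seed 1 --out data/
spineltd quantify-imaging --images data/ch_red.tif --rois data/rois.csv \
                          --timeline data/series.json --out out/
spineltd quantify-ephys   --sweeps data/sweeps.csv --out out/
spineltd stats ttest --summary groups.csv      # CSV: group, mean, sem, n
spineltd run-all --config cfg.yaml
```

`run-all` executes simulate → quantify (both modalities) → stats and writes
per-spine trace tables, the binned fEPSP course, a summary JSON and a
manifest recording the config hash, seed and every QC decision. Reruns with
the same configuration are byte-identical.

## Package layout

| module | contents |
|---|---|
| `spineltd.simulate` | ground-truthed imaging / fEPSP / PPF / group-summary generators |
| `spineltd.imaging` | Z-collapse, registration, ROI traces, corrections, drift QC, windowed plasticity, morphometrics |
| `spineltd.ephys` | initial slope, per-minute binning, drift QC, LTD windows, PPF ratios |
| `spineltd.stats` | SEM, paired/unpaired t (raw or summary form), 2×2 ANOVA, Bonferroni, correlation |
| `spineltd.io` | TIFF+sidecar, ROI/sweep CSV, JSON, YAML experiment configs |
| `spineltd.pipeline` | end-to-end orchestration with stage-named errors and manifests |
| `spineltd.cli` | `spineltd` command-line entry point |

See `docs/methods.md` for the quantitative models, parameter defaults and
their rationale, and known limitations.
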