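"""Spine-imaging quantification: projections, registration, ROI traces,
corrections, normalization, drift QC, windowed plasticity, morphometrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from spineltd import (NormalizedTrace, Roi, RoiSet, apply_experiment_qc,
                      baseline_drift_qc, collapse_zstack, correct_trace,
                      extract_roi_traces, measure_morphometrics,
                      normalize_trace, quantify_channel, quantify_sep_signal,
                      quantify_structural_plasticity, register_series,
                      size_dependence_analysis, simulate_imaging_experiment,
                      make_spine_grid)
from spineltd.imaging import RoiTrace, roi_mask

from conftest import clean_imaging_config

TIMELINE = -30.0 + 4.0 * np.arange(24)


def make_trace(values, roi_id="s", timeline=TIMELINE):
    return NormalizedTrace(roi_id=roi_id, values=np.asarray(values, float),
                           timeline=np.asarray(timeline, float),
                           baseline_mean=1.0)


# ---------------------------------------------------------------------------
# Z-collapse
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_zero_stack_collapses_to_zero(self):
        assert np.all(collapse_zstack(np.zeros((4, 8, 8))) == 0)

    def test_single_slice_is_identity(self, rng):
        sl = rng.normal(size=(1, 6, 7))
        assert np.array_equal(collapse_zstack(sl), sl[0])

    def test_max_projection_matches_bruteforce(self, rng):
        stack = rng.normal(size=(5, 8, 9))
        proj = collapse_zstack(stack, "max")
        for y in range(8):
            for x in range(9):
                best = stack[0, y, x]
                for z in range(1, 5):
                    best = max(best, stack[z, y, x])
                assert proj[y, x] == best

    def test_sum_projection_matches_bruteforce(self, rng):
        stack = rng.normal(size=(4, 5, 6))
        assert np.allclose(collapse_zstack(stack, "sum"),
                           sum(stack[z] for z in range(4)))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            collapse_zstack(np.zeros((0, 4, 4)))
        with pytest.raises(ValueError):
            collapse_zstack(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            collapse_zstack(np.zeros((2, 4, 4)), "median")


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

class TestRegistration:
    @staticmethod
    def scene(rng, n=64):
        img = np.zeros((n, n))
        for _ in range(6):
            y, x = rng.integers(12, n - 12, size=2)
            yy, xx = np.mgrid[0:n, 0:n]
            img += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / 8.0)
        return img

    def test_identical_frames_give_zero_shift(self, rng):
        img = self.scene(rng)
        _, shifts, flags = register_series(np.stack([img, img, img]))
        assert np.allclose(shifts, 0.0, atol=1e-6)
        assert not flags.any()

    def test_integer_shift_recovered_exactly(self, rng):
        img = self.scene(rng)
        moved = np.roll(img, (3, -2), axis=(0, 1))
        aligned, shifts, _ = register_series(np.stack([img, moved]))
        assert np.allclose(shifts[1], [3.0, -2.0], atol=1e-6)
        # interior pixels restored to the reference
        assert np.allclose(aligned[1][8:-8, 8:-8], img[8:-8, 8:-8], atol=1e-6)

    def test_half_pixel_shift_recovered(self, rng):
        img = self.scene(rng)
        # oracle displacement by exactly (0.5, 0.5) px via Fourier shift
        moved = np.fft.ifftn(
            ndimage.fourier_shift(np.fft.fftn(img), (0.5, 0.5))).real
        _, shifts, _ = register_series(np.stack([img, moved]))
        assert np.allclose(shifts[1], [0.5, 0.5], atol=0.25)

    def test_featureless_frame_flagged(self, rng):
        img = self.scene(rng)
        flat = np.full_like(img, 3.0)
        with pytest.warns(UserWarning, match="featureless"):
            _, shifts, flags = register_series(np.stack([img, flat]))
        assert flags[1]
        assert np.array_equal(shifts[1], [0.0, 0.0])

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            register_series(np.zeros((1, 8, 8)))


# ---------------------------------------------------------------------------
# ROI masks and trace extraction
# ---------------------------------------------------------------------------

class TestRoiExtraction:
    def test_mask_matches_bruteforce_enumeration(self):
        roi = Roi("r", "spine", (20.3, 15.7), 20.0)
        mask = roi_mask(roi, (40, 40))
        for y in range(40):
            for x in range(40):
                d2 = (x + 0.5 - 20.3) ** 2 + (y + 0.5 - 15.7) ** 2
                assert mask[y, x] == (d2 < 100.0)

    def test_uniform_frame_trace_is_area_times_level(self):
        roi = Roi("r", "spine", (20.0, 20.0), 20.0)
        frames = np.full((3, 40, 40), 2.5)
        rs = RoiSet.unchecked([roi])
        tr = extract_roi_traces(frames, rs)["r"]
        assert np.allclose(tr.values, 2.5 * tr.pixel_count)
        npx = int(roi_mask(roi, (40, 40)).sum())
        assert tr.pixel_count == npx

    def test_zero_frames_give_zero_trace(self):
        roi = Roi("r", "spine", (15.0, 15.0), 10.0)
        tr = extract_roi_traces(np.zeros((2, 30, 30)),
                                RoiSet.unchecked([roi]))["r"]
        assert np.all(tr.values == 0.0)

    def test_blob_fully_inside_roi_is_fully_captured(self):
        frame = np.zeros((50, 50))
        frame[24:27, 24:27] = 7.0   # 3x3 block well inside the ROI
        roi = Roi("r", "spine", (25.5, 25.5), 20.0)
        tr = extract_roi_traces(frame[None], RoiSet.unchecked([roi]))["r"]
        assert tr.values[0] == pytest.approx(frame.sum())

    def test_roi_touching_edge_marked_invalid(self):
        roi = Roi("r", "spine", (5.0, 15.0), 20.0)
        with pytest.warns(UserWarning, match="outside the frame"):
            tr = extract_roi_traces(np.ones((2, 30, 30)),
                                    RoiSet.unchecked([roi]))["r"]
        assert not tr.valid.any()

    def test_roiset_count_enforcement(self):
        spine = Roi("s", "spine", (30.0, 30.0))
        with pytest.raises(ValueError, match="background"):
            RoiSet([spine])
        assert RoiSet.unchecked([spine]).spines == [spine]


# ---------------------------------------------------------------------------
# Correction and normalization
# ---------------------------------------------------------------------------

def _aux(values, roi_id, npx=100):
    values = np.asarray(values, float)
    return RoiTrace(roi_id, "shaft", values, npx,
                    np.ones(len(values), dtype=bool))


class TestCorrection:
    def test_zero_background_unit_gain_is_identity(self):
        nt = 24
        spine = _aux(np.linspace(100, 200, nt), "s")
        bgs = [_aux(np.zeros(nt), f"b{i}") for i in range(3)]
        shafts = [_aux(np.full(nt, 50.0), f"sh{i}") for i in range(5)]
        corr, valid = correct_trace(spine, bgs, shafts, TIMELINE < 0)
        assert np.allclose(corr, spine.values)
        assert valid.all()

    def test_additive_offset_and_multiplicative_gain_cancel(self, rng):
        # nuisance invariance: per-frame gain g(t) with baseline mean 1 and
        # a constant per-pixel offset must cancel exactly
        nt = 24
        true = np.where(TIMELINE < 0, 1000.0, 840.0)
        g = np.exp(rng.normal(0, 0.05, nt))
        g /= g[TIMELINE < 0].mean()
        offset = 30.0  # photons per pixel
        spine = _aux(true * g + offset * 100, "s", npx=100)
        bgs = [_aux(np.full(nt, offset * 80), f"b{i}", npx=80)
               for i in range(3)]
        shafts = [_aux(500.0 * g + offset * 60, f"sh{i}", npx=60)
                  for i in range(5)]
        corr, _ = correct_trace(spine, bgs, shafts, TIMELINE < 0)
        assert np.allclose(corr, true, rtol=1e-12)

    def test_nonpositive_shaft_baseline_rejected(self):
        nt = 24
        spine = _aux(np.ones(nt), "s")
        bgs = [_aux(np.zeros(nt), f"b{i}") for i in range(3)]
        shafts = [_aux(np.zeros(nt), f"sh{i}") for i in range(5)]
        with pytest.raises(ValueError, match="non-positive baseline"):
            correct_trace(spine, bgs, shafts, TIMELINE < 0)


class TestNormalization:
    def test_constant_trace_normalizes_to_100(self):
        tr = normalize_trace(np.full(24, 5.0), TIMELINE)
        assert np.allclose(tr.values, 100.0)
        assert tr.baseline_mean == pytest.approx(5.0)

    def test_doubling_after_onset_gives_200(self):
        vals = np.where(TIMELINE < 0, 3.0, 6.0)
        tr = normalize_trace(vals, TIMELINE)
        assert np.allclose(tr.values[TIMELINE < 0], 100.0)
        assert np.allclose(tr.values[TIMELINE >= 0], 200.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1.0, 1e4), min_size=24, max_size=24))
    def test_baseline_mean_is_always_100(self, vals):
        tr = normalize_trace(np.array(vals), TIMELINE)
        assert tr.values[TIMELINE < 0].mean() == pytest.approx(100.0,
                                                               rel=1e-9)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_trace(np.full(24, -1.0), TIMELINE)


# ---------------------------------------------------------------------------
# Drift QC and windowed quantification
# ---------------------------------------------------------------------------

class TestDriftQc:
    def test_flat_baseline_has_zero_drift_and_passes(self):
        tr = baseline_drift_qc(make_trace(np.full(24, 100.0)))
        assert tr.drift_percent == pytest.approx(0.0, abs=1e-9)
        assert tr.qc_passed

    def test_linear_ramp_drift_matches_closed_form(self):
        # baseline frames at -30..-2; a perfectly linear ramp has OLS slope
        # equal to its true slope, so drift = |b| * 28 / mean * 100
        b = 0.2
        vals = 100.0 + b * TIMELINE
        tr = baseline_drift_qc(make_trace(vals))
        t_bl = TIMELINE[TIMELINE < 0]
        expect = b * (t_bl.max() - t_bl.min()) / vals[TIMELINE < 0].mean() * 100
        assert tr.drift_percent == pytest.approx(expect, rel=1e-9)
        assert tr.qc_passed     # ~5.8% < 7%

    def test_ten_percent_ramp_fails(self):
        vals = 100.0 + 0.4 * TIMELINE    # ~11.6% drift over baseline
        tr = baseline_drift_qc(make_trace(vals))
        assert tr.drift_percent > 7.0
        assert not tr.qc_passed

    def test_drift_scales_linearly_with_ramp_amplitude(self):
        # ramps centered on the baseline midpoint (t = -16) keep the
        # baseline mean at 100, so drift is exactly proportional to b
        d = [baseline_drift_qc(
                make_trace(100.0 + b * (TIMELINE + 16.0))).drift_percent
             for b in (0.05, 0.10, 0.20)]
        assert d[1] == pytest.approx(2 * d[0], rel=1e-6)
        assert d[2] == pytest.approx(4 * d[0], rel=1e-6)

    def test_post_treatment_change_does_not_affect_drift(self):
        flat = make_trace(np.where(TIMELINE < 0, 100.0, 40.0))
        tr = baseline_drift_qc(flat)
        assert tr.drift_percent == pytest.approx(0.0, abs=1e-9)
        assert tr.qc_passed

    def test_experiment_policy_all_vs_per_trace(self):
        good = baseline_drift_qc(make_trace(np.full(24, 100.0)))
        bad = baseline_drift_qc(make_trace(100.0 + 0.5 * TIMELINE))
        assert apply_experiment_qc([good, bad], policy="per_trace")
        assert good.qc_passed and not bad.qc_passed
        good2 = baseline_drift_qc(make_trace(np.full(24, 100.0)))
        bad2 = baseline_drift_qc(make_trace(100.0 + 0.5 * TIMELINE))
        assert not apply_experiment_qc([good2, bad2], policy="all")
        assert not good2.qc_passed
        with pytest.raises(ValueError):
            apply_experiment_qc([good], policy="any")


class TestWindowedQuantification:
    def test_step_to_84_quantifies_as_84(self):
        vals = np.where(TIMELINE < 0, 100.0, 84.0)
        m = quantify_structural_plasticity([make_trace(vals)])
        assert m.window_mean_percent == pytest.approx(84.0)
        assert m.baseline_reference_percent == pytest.approx(100.0)
        assert m.delta_percent == pytest.approx(-16.0)

    def test_no_change_quantifies_as_100(self):
        m = quantify_structural_plasticity([make_trace(np.full(24, 100.0))])
        assert m.window_mean_percent == pytest.approx(100.0)

    def test_windows_select_expected_frames(self):
        # post window [50, 60] closed -> frames at 50, 54, 58;
        # reference [-10, 0) half-open -> frames at -10, -6, -2
        vals = np.zeros(24)
        vals[np.isin(TIMELINE, [50.0, 54.0, 58.0])] = 60.0
        vals[np.isin(TIMELINE, [-10.0, -6.0, -2.0])] = 30.0
        m = quantify_structural_plasticity([make_trace(vals)])
        assert m.window_mean_percent == pytest.approx(60.0)
        assert m.baseline_reference_percent == pytest.approx(30.0)

    def test_failed_traces_are_excluded_from_the_mean(self):
        ok = make_trace(np.where(TIMELINE < 0, 100.0, 80.0))
        bad = make_trace(np.where(TIMELINE < 0, 100.0, 20.0))
        bad.qc_passed = False
        m = quantify_structural_plasticity([ok, bad])
        assert m.n_spines == 1
        assert m.window_mean_percent == pytest.approx(80.0)
        with pytest.raises(ValueError, match="no QC-passing"):
            quantify_structural_plasticity([bad])

    def test_pairs_feed_paired_comparison(self):
        traces = [make_trace(np.where(TIMELINE < 0, 100.0, p))
                  for p in (70.0, 80.0, 90.0)]
        m = quantify_structural_plasticity(traces)
        ref, win = m.pairs
        assert np.allclose(ref, 100.0)
        assert np.allclose(sorted(win), [70.0, 80.0, 90.0])


# ---------------------------------------------------------------------------
# Morphometrics and size dependence
# ---------------------------------------------------------------------------

class TestMorphometrics:
    def test_density_and_345_triangle_length(self):
        spines = [Roi(f"s{i}", "spine", (30.0 + 25 * i, 60.0),
                      base_point=(30.0 + 25 * i, 60.0)) for i in range(11)]
        spines[0] = Roi("s0", "spine", (30.0, 60.0), base_point=(33.0, 64.0))
        rs = RoiSet.unchecked(spines, dendrite_length_um=20.0)
        m = measure_morphometrics(rs, pixel_size_um=0.5)
        assert m["density_per_10um"] == pytest.approx(5.5)
        # base offset (3, 4) px -> 5 px -> 2.5 um
        assert m["lengths_um"]["s0"] == pytest.approx(2.5)
        assert m["lengths_um"]["s1"] == pytest.approx(0.0)

    def test_missing_base_point_gives_nan_length(self):
        rs = RoiSet.unchecked([Roi("s", "spine", (10.0, 10.0))],
                              dendrite_length_um=10.0)
        m = measure_morphometrics(rs, 0.1)
        assert np.isnan(m["lengths_um"]["s"])

    def test_nonpositive_segment_length_rejected(self):
        rs = RoiSet.unchecked([Roi("s", "spine", (10.0, 10.0))])
        with pytest.raises(ValueError):
            measure_morphometrics(rs, 0.1)


class TestSizeDependence:
    def test_uniform_shrinkage_has_zero_size_slope(self):
        vals = np.where(TIMELINE < 0, 100.0, 84.0)
        traces = [make_trace(vals, roi_id=f"s{i}") for i in range(6)]
        sizes = {f"s{i}": 100.0 * (1.5 ** i) for i in range(6)}
        out = size_dependence_analysis(traces, sizes)
        assert out["small_mean_percent"] == pytest.approx(84.0)
        assert out["large_mean_percent"] == pytest.approx(84.0)
        assert out["slope_delta_vs_size"] == pytest.approx(0.0, abs=1e-9)

    def test_large_only_shrinkage_separates_classes(self):
        traces, sizes = [], {}
        for i in range(6):
            big = i >= 3
            post = 70.0 if big else 100.0
            traces.append(make_trace(np.where(TIMELINE < 0, 100.0, post),
                                     roi_id=f"s{i}"))
            sizes[f"s{i}"] = 500.0 if big else 100.0
        out = size_dependence_analysis(traces, sizes)
        assert out["small_mean_percent"] == pytest.approx(100.0)
        assert out["large_mean_percent"] == pytest.approx(70.0)
        assert out["slope_delta_vs_size"] < 0


# ---------------------------------------------------------------------------
# End-to-end channel pipeline on simulated data
# ---------------------------------------------------------------------------

class TestEndToEnd:
    def test_noiseless_pipeline_recovers_ground_truth_exactly(self, clean_sim):
        cfg, spines, series, rois, gt = clean_sim
        res = quantify_channel(series, rois, register=False)
        assert all(tr.qc_passed for tr in res["traces"])
        for tr in res["traces"]:
            assert np.allclose(tr.values, gt.volume_traces_percent[tr.roi_id],
                               rtol=1e-9)
        m = quantify_structural_plasticity(res["traces"])
        assert m.window_mean_percent == pytest.approx(84.0, abs=1e-6)

    def test_sep_channel_combines_volume_and_surface_fraction(self, clean_sim):
        cfg, spines, series, rois, gt = clean_sim
        res = quantify_channel(series, rois, channel="sep_reporter",
                               register=False)
        m = quantify_sep_signal(res["traces"])
        # 16% volume loss x 25% surface drop -> 0.84 * 0.75 = 63%
        assert m.window_mean_percent == pytest.approx(63.0, abs=1e-6)

    def test_gain_and_bleach_cancel_in_percent_traces(self):
        cfg = clean_imaging_config(fluctuation_sigma=0.08,
                                   bleach_rate_per_frame=0.004, seed=21)
        spines = make_spine_grid(cfg, n_spines=3, shrinkage=0.16)
        series, rois, gt = simulate_imaging_experiment(cfg, spines)
        res = quantify_channel(series, rois, register=False)
        for tr in res["traces"]:
            # bleach is shared with the shaft gain estimate and divides out
            assert np.allclose(tr.values, gt.volume_traces_percent[tr.roi_id],
                               rtol=1e-6)

    def test_registration_restores_drifting_series(self):
        cfg = clean_imaging_config(frame_size=(128, 128), z_slices=5,
                                   drift_step_sigma=1.0, seed=4)
        spines = make_spine_grid(cfg, n_spines=4, shrinkage=0.16)
        series, rois, gt = simulate_imaging_experiment(cfg, spines)
        res = quantify_channel(series, rois, register=True)
        est = res["shifts"]                        # (dy, dx)
        true = gt.drift_offsets[:, ::-1]           # (dx, dy) -> (dy, dx)
        assert np.abs(est - true).max() < 0.3
        m = quantify_structural_plasticity(res["traces"])
        assert m.window_mean_percent == pytest.approx(84.0, abs=0.5)
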