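"""Polarization quantitation: stretch, background, box mean, profiles, peaks."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epiactin.core import CellROI, LineProfile, TimeLapseStack
from epiactin.polarization import (
    assign_halves,
    cell_mean,
    contrast_stretch,
    detect_peaks,
    enrichment_offset,
    estimate_background,
    extract_vd_profile,
    leading_edge_roi_mean,
    vd_ratio_over_window,
)
from epiactin.simulate import MovieSpec, generate_movie


def brute_force_peak_count(values, background, threshold=10.0):
    """Independent run-scanner: count maximal supra-threshold runs."""
    count = 0
    in_run = False
    for v in values:
        above = v >= background + threshold
        if above and not in_run:
            count += 1
        in_run = above
    return count


def _rect_roi(top, bottom, left, right, cell_id="c", role="leading-cell"):
    cx = (left + right) / 2
    return CellROI(
        cell_id=cell_id,
        role=role,
        polygon=np.array([[top, left], [top, right], [bottom, right], [bottom, left]]),
        axis=np.array([[bottom, cx], [top, cx]]),
        leading_edge=np.array([[bottom, left], [bottom, right]]),
    )


class TestContrastStretch:
    def test_full_range_unchanged(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, (3, 20, 20)).astype(np.uint8)
        frames[0, 0, 0], frames[0, 0, 1] = 0, 255
        out = contrast_stretch(TimeLapseStack(frames), 0, 100)
        assert np.max(np.abs(out.frames.astype(int) - frames.astype(int))) <= 1

    def test_constant_stack_warns_identity(self):
        frames = np.full((2, 10, 10), 40, dtype=np.uint8)
        with pytest.warns(UserWarning):
            out = contrast_stretch(TimeLapseStack(frames))
        assert np.array_equal(out.frames, frames)

    def test_monotone(self):
        rng = np.random.default_rng(1)
        frames = rng.integers(10, 200, (2, 15, 15)).astype(np.uint8)
        out = contrast_stretch(TimeLapseStack(frames))
        a = frames.ravel().astype(int)
        b = out.frames.ravel().astype(int)
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= 0)


class TestEstimateBackground:
    def test_constant(self):
        assert estimate_background(np.full((10, 10), 20.0)) == 20.0

    def test_mode_ignores_bright_minority(self):
        frame = np.full((10, 10), 20.0)
        frame[:1, :] = 200.0
        assert estimate_background(frame) == 20.0

    def test_generator_background(self, wt_preset):
        spec = MovieSpec(preset=wt_preset, noise_sigma=0.0, seed=0)
        stack, _, _ = generate_movie(spec)
        assert estimate_background(stack.frames[0]) == spec.background_level


class TestLeadingEdgeRoiMean:
    def test_constant_frame(self):
        frame = np.full((100, 100), 7.0)
        roi = _rect_roi(10, 90, 20, 80)
        assert leading_edge_roi_mean(frame, roi) == 7.0

    def test_checkerboard(self):
        frame = np.indices((100, 100)).sum(axis=0) % 2 * 10.0
        roi = _rect_roi(10, 90, 20, 80)
        assert leading_edge_roi_mean(frame, roi) == pytest.approx(5.0)

    def test_additive_shift_equivariance(self):
        rng = np.random.default_rng(2)
        frame = rng.uniform(0, 50, (100, 100))
        roi = _rect_roi(10, 90, 20, 80)
        base = leading_edge_roi_mean(frame, roi)
        assert leading_edge_roi_mean(frame + 11.5, roi) == pytest.approx(base + 11.5)

    def test_out_of_bounds_names_cell(self):
        frame = np.zeros((30, 30))
        roi = _rect_roi(2, 28, 2, 28, cell_id="LC-9")
        with pytest.raises(ValueError, match="LC-9"):
            leading_edge_roi_mean(frame, roi)

    def test_enriched_frame_exceeds_cell_mean(self, wt_noiseless, leading_roi):
        """At enrichment onset the leading-edge box outshines the whole cell."""
        stack, gt, _ = wt_noiseless
        f = stack.frame_at_or_after(gt.event_times["t_lc_enrichment"])
        frame = stack.frames[f]
        assert leading_edge_roi_mean(frame, leading_roi) > cell_mean(frame, leading_roi)


class TestExtractVdProfile:
    def test_vertical_column(self):
        frame = np.zeros((10, 5))
        frame[5:8, 2] = [10, 9, 8]
        roi = _rect_roi(5, 7, 1, 3)
        prof = extract_vd_profile(frame, roi)
        assert list(prof.intensities) == [8, 9, 10]

    def test_length_matches_axis(self, wt_noiseless, leading_roi):
        stack, _, _ = wt_noiseless
        prof = extract_vd_profile(stack.frames[0], leading_roi)
        axis_len = np.hypot(*(leading_roi.axis[1] - leading_roi.axis[0]))
        assert abs(len(prof) - (axis_len + 1)) <= 1

    def test_oblique_axis_matches_closed_form(self):
        """Sampling an analytic intensity field along a 30-degree axis matches
        the closed form within bilinear-interpolation tolerance."""
        r0, c0 = 60.0, 60.0

        def field(r, c):
            return 100.0 * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / 800.0)

        rr, cc = np.mgrid[0:120, 0:120]
        frame = field(rr, cc)
        theta = np.deg2rad(30)
        length = 50.0
        ventral = np.array([r0 + length / 2 * np.cos(theta), c0 + length / 2 * np.sin(theta)])
        dorsal = np.array([r0 - length / 2 * np.cos(theta), c0 - length / 2 * np.sin(theta)])
        roi = CellROI(
            cell_id="c",
            role="leading-cell",
            polygon=np.array([[10, 10], [10, 110], [110, 110], [110, 10]]),
            axis=np.array([ventral, dorsal]),
            leading_edge=np.array([[110, 10], [110, 110]]),
        )
        prof = extract_vd_profile(frame, roi)
        t = np.linspace(0, 1, len(prof))
        pts = ventral[None, :] + t[:, None] * (dorsal - ventral)[None, :]
        exact = field(pts[:, 0], pts[:, 1])
        assert np.max(np.abs(prof.intensities - exact)) <= 2.0

    def test_short_axis_rejected(self):
        frame = np.zeros((10, 10))
        roi = _rect_roi(5, 5, 2, 8)
        roi.axis = np.array([[5.0, 5.0], [5.0, 5.0]])
        with pytest.raises(ValueError):
            extract_vd_profile(frame, roi)


class TestDetectPeaks:
    def test_two_runs(self):
        prof = LineProfile([5, 5, 20, 5, 16, 5])
        peaks = detect_peaks(prof, background=5)
        assert [p.apex_index for p in peaks] == [2, 4]

    def test_inclusive_boundary(self):
        prof = LineProfile([5, 14, 5])
        assert detect_peaks(prof, background=5) == []
        prof = LineProfile([5, 15, 5])
        assert len(detect_peaks(prof, background=5)) == 1

    def test_run_with_internal_wiggle_is_one_peak(self):
        prof = LineProfile([0, 20, 18, 25, 0])
        peaks = detect_peaks(prof, background=0)
        assert len(peaks) == 1
        assert peaks[0].apex_index == 3

    def test_leftmost_apex_on_ties(self):
        prof = LineProfile([0, 20, 20, 0])
        assert detect_peaks(prof, background=0)[0].apex_index == 1

    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=60),
        st.integers(min_value=0, max_value=10),
    )
    def test_equals_brute_force_scanner(self, values, background):
        prof = LineProfile(values)
        assert len(detect_peaks(prof, background)) == brute_force_peak_count(
            values, background
        )


class TestAssignHalves:
    def test_one_each_half(self):
        prof = LineProfile(np.zeros(101))
        prof.intensities[20] = 30
        prof.intensities[80] = 30
        peaks = detect_peaks(prof, 0)
        assert assign_halves(peaks, prof) == (1, 1)

    def test_midpoint_is_ventral(self):
        prof = LineProfile(np.zeros(101))
        prof.intensities[50] = 30
        peaks = detect_peaks(prof, 0)
        assert assign_halves(peaks, prof) == (1, 0)

    def test_all_ventral_generator(self, wt_preset):
        """With ventral_peak_fraction=1 every measured peak lands ventrally."""
        allv = dataclasses.replace(
            wt_preset,
            ventral_peak_fraction=1.0,
            t_lc_enrichment=None,
            t_lc_protrusion=None,
            t_lc_meeting=None,
        )
        stack, gt, rois = generate_movie(MovieSpec(preset=allv, noise_sigma=0.0, seed=4))
        lead = next(r for r in rois if r.role == "leading-cell")
        res = vd_ratio_over_window(stack, lead, 0, stack.n_frames)
        placed_v, placed_d = gt.vd_counts(0, stack.n_frames, cell_ids=[lead.cell_id])
        assert placed_d == 0
        assert (res.ventral_count, res.dorsal_count) == (placed_v, 0)
        assert placed_v > 0


class TestVdRatioWindow:
    def test_counts_and_ratio(self, wt_preset):
        stack, gt, rois = generate_movie(
            MovieSpec(preset=wt_preset, noise_sigma=0.0, seed=5)
        )
        lead = next(r for r in rois if r.role == "leading-cell")
        res = vd_ratio_over_window(stack, lead, 0, 10)
        gv, gd = gt.vd_counts(0, 10, cell_ids=[lead.cell_id], include_ridge=True)
        assert (res.ventral_count, res.dorsal_count) == (gv, gd)
        if res.defined:
            assert res.ratio == pytest.approx(gv / gd)

    def test_undefined_flag(self):
        from epiactin.core import VDRatioResult

        res = VDRatioResult(n_frames=20, ventral_count=5, dorsal_count=0)
        assert not res.defined and res.ratio is None
        res = VDRatioResult(n_frames=20, ventral_count=12, dorsal_count=4)
        assert res.ratio == 3.0

    def test_window_out_of_range(self, wt_noiseless, leading_roi):
        stack, _, _ = wt_noiseless
        with pytest.raises(ValueError):
            vd_ratio_over_window(stack, leading_roi, stack.n_frames - 5, 20)

    def test_frame_order_invariance(self, wt_preset):
        """Pooled window counts do not depend on the order of the frames."""
        stack, _, rois = generate_movie(
            MovieSpec(preset=wt_preset, noise_sigma=0.0, seed=6)
        )
        lead = next(r for r in rois if r.role == "leading-cell")
        res = vd_ratio_over_window(stack, lead, 0, 12)
        shuffled = TimeLapseStack(
            stack.frames[:12][::-1].copy(),
            frame_interval=stack.frame_interval,
            t_start=stack.t_start,
            pixel_size=stack.pixel_size,
        )
        res2 = vd_ratio_over_window(shuffled, lead, 0, 12)
        assert (res.ventral_count, res.dorsal_count) == (
            res2.ventral_count,
            res2.dorsal_count,
        )


class TestEnrichmentOffset:
    def test_wild_type_preset_recovers_offset(self, wt_noiseless, leading_roi):
        stack, gt, _ = wt_noiseless
        f = stack.frame_at_or_after(gt.event_times["t_lc_enrichment"])
        off = enrichment_offset(stack.frames[f], leading_roi, pixel_size=0.15)
        assert off == pytest.approx(2.0, abs=0.15)

    def test_ridge_at_front_gives_zero(self):
        frame = np.full((60, 60), 5.0)
        frame[40, 10:50] = 100.0  # single bright row: both front and apex
        roi = _rect_roi(10, 40, 10, 49)
        assert enrichment_offset(frame, roi, pixel_size=1.0) == 0.0

    def test_uniform_scaling_invariance(self, wt_noiseless, leading_roi):
        stack, gt, _ = wt_noiseless
        f = stack.frame_at_or_after(gt.event_times["t_lc_enrichment"])
        frame = stack.frames[f].astype(float)
        base = enrichment_offset(frame, leading_roi, pixel_size=0.15)
        scaled = enrichment_offset(frame * 2.0, leading_roi, pixel_size=0.15)
        assert scaled == pytest.approx(base)

    def test_no_signal_errors(self):
        frame = np.zeros((60, 60))
        roi = _rect_roi(10, 40, 10, 49)
        with pytest.raises(ValueError):
            enrichment_offset(frame, roi)
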