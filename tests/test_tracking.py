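import numpy as np
import pytest

import cinestrain as cs
from cinestrain.tracking import TrackingParams


def circle_contour(centre, radius, n=60, topology="closed"):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return cs.Contour(
        points=np.stack([centre[0] + radius * np.cos(theta),
                         centre[1] + radius * np.sin(theta)], axis=1),
        topology=topology,
    )


class TestTrackingParams:
    def test_search_radius_bounded_by_template(self):
        with pytest.raises(ValueError, match="search_radius"):
            TrackingParams(template_half_width_px=3, search_radius_px=9)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_smoothing_window_must_be_odd(self, window):
        with pytest.raises(ValueError, match="odd"):
            TrackingParams(smoothing_window_points=window)


class TestTrackContour:
    def test_static_sequence_does_not_drift(self, ring_phantom):
        # repeat one textured phantom frame: no motion, so no drift
        frame = ring_phantom.sequence.frames[0]
        seq = cs.CineSequence(frames=np.stack([frame] * 10), pixel_spacing_mm=1.0,
                              frame_interval_ms=40.0)
        init = ring_phantom.truth_track.contours[0]
        track = cs.track_contour(seq, init)
        for contour in track.contours:
            drift = np.hypot(*(contour.points - init.points).T)
            assert drift.max() < 0.5

    def test_pure_translation_recovered(self, textured_image):
        frames = np.stack([np.roll(textured_image, 3 * t, axis=1) for t in range(6)])
        seq = cs.CineSequence(frames=frames, pixel_spacing_mm=1.0,
                              frame_interval_ms=40.0)
        init = circle_contour((20, 40), 8)
        track = cs.track_contour(
            seq, init,
            TrackingParams(drift_compensation=False, normal_refinement=False,
                           temporal_smoothing=False),
        )
        for t in range(1, 6):
            step = track.contours[t].points - track.contours[t - 1].points
            assert step[:, 0].mean() == pytest.approx(3.0, abs=0.5)
            assert np.abs(step[:, 1].mean()) < 0.5

    def test_tracks_ring_phantom_border_length(self, ring_phantom):
        track = cs.track_contour(ring_phantom.sequence,
                                 ring_phantom.truth_track.contours[0])
        truth = ring_phantom.truth_track.border_lengths()
        tracked = track.border_lengths()
        systole = int(np.argmin(truth))
        assert tracked[systole] == pytest.approx(truth[systole], rel=0.02)

    def test_deterministic(self, ring_phantom):
        a = cs.track_contour(ring_phantom.sequence, ring_phantom.truth_track.contours[0])
        b = cs.track_contour(ring_phantom.sequence, ring_phantom.truth_track.contours[0])
        for ca, cb in zip(a.contours, b.contours):
            np.testing.assert_array_equal(ca.points, cb.points)

    def test_frame0_is_initial_contour(self, ring_phantom):
        init = ring_phantom.truth_track.contours[0]
        track = cs.track_contour(ring_phantom.sequence, init)
        np.testing.assert_array_equal(track.contours[0].points, init.points)

    def test_contour_near_border_rejected(self, textured_image):
        seq = cs.CineSequence(frames=np.stack([textured_image] * 3),
                              pixel_spacing_mm=1.0, frame_interval_ms=40.0)
        with pytest.raises(ValueError, match="margin"):
            cs.track_contour(seq, circle_contour((40, 40), 36))

    def test_flat_image_falls_back_without_moving(self):
        # zero-variance templates everywhere: every point keeps its position
        seq = cs.CineSequence(frames=np.ones((4, 60, 60)), pixel_spacing_mm=1.0,
                              frame_interval_ms=40.0)
        init = circle_contour((30, 30), 12)
        track = cs.track_contour(
            seq, init, TrackingParams(normal_refinement=False)
        )
        for contour in track.contours:
            np.testing.assert_allclose(contour.points, init.points, atol=1e-9)


class TestGlobalStrain:
    def test_truth_track_circumferential(self, ring_phantom):
        curve = cs.ft_global_strain(ring_phantom.truth_track, "circumferential")
        assert curve.peak_global_strain_percent == pytest.approx(20.0, abs=0.1)

    def test_truth_track_radial_matches_circumferential(self, ring_phantom):
        # for a circle the radius scales with the circumference
        curve = cs.ft_global_strain(ring_phantom.truth_track, "radial")
        assert curve.peak_global_strain_percent == pytest.approx(20.0, abs=0.1)
        assert curve.values_percent[curve.reference_frame] == 0.0

    def test_truth_track_longitudinal(self, u_phantom):
        curve = cs.ft_global_strain(u_phantom.truth_track, "longitudinal")
        assert curve.peak_global_strain_percent == pytest.approx(20.0, abs=0.1)

    def test_static_track_is_zero(self):
        contours = [circle_contour((30, 30), 10) for _ in range(4)]
        for t, contour in enumerate(contours):
            contour.frame_index = t
        track = cs.ContourTrack(contours=contours, params=None, source="ground_truth")
        for direction in ("circumferential", "radial"):
            assert cs.ft_global_strain(track, direction).peak_global_strain_percent == 0.0

    @pytest.mark.parametrize("direction,topology", [
        ("longitudinal", "closed"), ("circumferential", "open"), ("radial", "open"),
    ])
    def test_direction_topology_mismatch_rejected(self, direction, topology, ring_phantom, u_phantom):
        track = ring_phantom.truth_track if topology == "closed" else u_phantom.truth_track
        with pytest.raises(ValueError):
            cs.ft_global_strain(track, direction)


class TestSegmentalStrain:
    def test_homogeneous_truth_segments_all_equal(self, ring_phantom):
        result = cs.ft_segmental_strain(ring_phantom.truth_track, 6)
        np.testing.assert_allclose(result.per_segment_peak_percent, 20.0, atol=0.1)

    def test_segment_boundaries_partition_equally(self, ring_phantom):
        result = cs.ft_segmental_strain(ring_phantom.truth_track, 6)
        widths = np.diff(result.segment_boundaries)
        np.testing.assert_allclose(widths, 1.0 / 6.0, atol=0.02)

    def test_length_weighted_mean_matches_global(self, ring_phantom):
        track = cs.track_contour(ring_phantom.sequence,
                                 ring_phantom.truth_track.contours[0])
        global_curve = cs.ft_global_strain(track, "circumferential")
        seg = cs.ft_segmental_strain(track, 6)
        weights = seg.segment_reference_lengths_mm
        peak_frame = global_curve.peak_frame
        weighted = np.sum(seg.per_segment_values_percent[:, peak_frame] * weights)
        weighted /= weights.sum()
        assert weighted == pytest.approx(global_curve.values_percent[peak_frame],
                                         abs=0.2)

    def test_too_few_points_rejected(self, ring_phantom):
        with pytest.raises(ValueError, match="segments"):
            cs.ft_segmental_strain(ring_phantom.truth_track, 40)
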