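import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cinestrain as cs
from cinestrain.ebd import DEFAULT_N_OUT


def circle_anchors(n, radius=10.0, centre=(20.0, 20.0)):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack([centre[0] + radius * np.cos(theta),
                     centre[1] + radius * np.sin(theta)], axis=1)


class TestInterpolateBorder:
    def test_reproduces_collinear_anchors(self):
        contour = cs.interpolate_border([(0, 0), (1, 0), (2, 0)], "open", 9)
        np.testing.assert_allclose(contour.points[:, 1], 0.0, atol=1e-12)
        assert cs.border_length(contour) == pytest.approx(2.0, abs=1e-9)

    def test_circle_circumference_recovered(self):
        contour = cs.interpolate_border(circle_anchors(12), "closed", 360)
        assert cs.border_length(contour) == pytest.approx(2.0 * np.pi * 10.0, rel=0.005)

    def test_anchors_returned_when_n_out_equals_anchor_count(self):
        anchors = np.array([(0.0, 0.0), (1.0, 0.5), (3.0, 0.0)])
        contour = cs.interpolate_border(anchors, "open", 3)
        np.testing.assert_array_equal(contour.points, anchors)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError, match="coincident|distinct"):
            cs.interpolate_border([(0, 0), (0, 0), (1, 0)], "open", 5)

    def test_densification_converges(self, ring_phantom):
        """Doubling the number of densified points barely changes strain."""
        def peak(n_out):
            dense = [
                cs.interpolate_border(c.points[::10], c.topology, n_out, c.frame_index)
                for c in ring_phantom.truth_track.contours
            ]
            return cs.ebd_strain(dense).peak_global_strain_percent

        assert abs(peak(2 * DEFAULT_N_OUT) - peak(DEFAULT_N_OUT)) < 0.05


class TestBorderLength:
    def test_open_polyline(self):
        contour = cs.Contour(points=[(0, 0), (3, 0), (3, 4)], topology="open")
        assert cs.border_length(contour) == pytest.approx(7.0)

    def test_closed_triangle_perimeter(self):
        contour = cs.Contour(points=[(0, 0), (3, 0), (0, 4)], topology="closed")
        assert cs.border_length(contour) == pytest.approx(12.0)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0.0, 30.0, size=(12, 2))
        contour = cs.Contour(points=pts, topology="closed")
        base = cs.border_length(contour)
        for _ in range(100):
            angle = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            shift = rng.uniform(-50.0, 50.0, 2)
            moved = cs.Contour(points=pts @ rot.T + shift, topology="closed")
            assert cs.border_length(moved) == pytest.approx(base, rel=1e-9)


class TestEbdStrain:
    @staticmethod
    def contours_with_lengths(lengths):
        return [
            cs.Contour(points=[(0.0, 0.0), (length / 2.0, 0.0), (length, 0.0)],
                       topology="open", frame_index=t)
            for t, length in enumerate(lengths)
        ]

    def test_strain_formula_on_known_lengths(self):
        curve = cs.ebd_strain(self.contours_with_lengths([100, 90, 80, 90, 100]))
        assert curve.reference_frame == 0
        assert curve.peak_global_strain_percent == pytest.approx(20.0)
        np.testing.assert_allclose(curve.values_percent, [0, -10, -20, -10, 0])

    def test_constant_lengths_give_zero_curve(self):
        curve = cs.ebd_strain(self.contours_with_lengths([50, 50, 50]))
        np.testing.assert_array_equal(curve.values_percent, 0.0)
        assert curve.peak_global_strain_percent == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_invariant_under_uniform_rescaling(self, scale):
        lengths = [100.0, 85.0, 92.0]
        base = cs.ebd_strain(self.contours_with_lengths(lengths))
        scaled = cs.ebd_strain(
            self.contours_with_lengths([scale * length for length in lengths])
        )
        np.testing.assert_allclose(scaled.values_percent, base.values_percent,
                                   atol=1e-9)

    @pytest.mark.parametrize("geometry", ["short_axis_ring", "four_chamber_u"])
    @pytest.mark.parametrize("strain", [10.0, 25.0])
    def test_recovers_phantom_truth(self, geometry, strain):
        out = cs.make_phantom(
            cs.PhantomSpec(geometry=geometry, true_peak_strain_percent=strain,
                           noise_sd=0.0, seed=2)
        )
        recovered = cs.ebd_strain(out.truth_track.contours).peak_global_strain_percent
        assert recovered == pytest.approx(strain, abs=0.1)

    def test_mixed_topology_rejected(self):
        contours = self.contours_with_lengths([100, 90])
        contours[1] = cs.Contour(points=[(0, 0), (3, 0), (0, 4)], topology="closed",
                                 frame_index=1)
        with pytest.raises(ValueError, match="topolog"):
            cs.ebd_strain(contours)
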