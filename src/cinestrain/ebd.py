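"""Endocardial border delineation (EBD) strain.

The EBD method measures global myocardial strain from the length of the
endocardial border alone: sparse manually placed border points are densified
by shape-preserving piecewise cubic Hermite interpolation, the border length
is the sum of Euclidean distances between consecutive points, and global
Lagrangian strain follows

    epsilon(t) = 100% * (L_t - L0) / L0

with L0 the maximal border length over the cycle (end-diastole) so that the
curve is zero at the reference phase and most negative at end-systole.  Peak
global strain is reported as an absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io import Contour

__all__ = ["StrainCurve", "interpolate_border", "border_length", "ebd_strain"]

#: default number of densified border points; keeps polyline length error
#: well below 0.1% for anatomical curvature at 1 mm in-plane resolution
DEFAULT_N_OUT = 200


@dataclass
class StrainCurve:
    """Per-frame Lagrangian strain (%) relative to a reference frame.

    ``values_percent`` keeps the sign (negative = shortening); the reported
    ``peak_global_strain_percent`` is the absolute value at the extreme.
    ``lengths_mm`` holds the per-frame border lengths the strain was derived
    from (for radial strain it holds the mean endocardial radius instead).
    """

    values_percent: np.ndarray
    lengths_mm: np.ndarray
    reference_frame: int

    def __post_init__(self) -> None:
        self.values_percent = np.asarray(self.values_percent, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        if self.values_percent.shape != self.lengths_mm.shape:
            raise ValueError("values and lengths must have one entry per frame")
        if self.values_percent[self.reference_frame] != 0.0:
            raise ValueError("strain at the reference frame must be exactly 0")

    @property
    def peak_global_strain_percent(self) -> float:
        """Absolute strain at the extreme phase (non-negative)."""
        return float(np.max(np.abs(self.values_percent)))

    @property
    def peak_frame(self) -> int:
        return int(np.argmax(np.abs(self.values_percent)))

    def summary(self) -> dict:
        return {
            "peak_global_strain_percent": self.peak_global_strain_percent,
            "peak_frame": self.peak_frame,
            "reference_frame": int(self.reference_frame),
            "n_frames": int(len(self.values_percent)),
        }


def interpolate_border(anchor_points, topology: str, n_out: int, frame_index: int = 0) -> Contour:
    """Densify sparse border anchors by monotone piecewise cubic Hermite
    interpolation of x and y against cumulative chord length.

    Open borders interpolate between the first and last anchor; closed
    borders use a periodic parameterisation that includes the closing span.
    Output points are uniformly spaced in the chord-length parameter.  When
    ``n_out`` equals the anchor count the anchors are returned unchanged
    (the interpolant passes through its nodes).
    """
    anchors = np.atleast_2d(np.asarray(anchor_points, dtype=float))
    n_anchor = len(anchors)
    if n_anchor < 3:
        raise ValueError("need at least 3 anchor points")
    if n_out < n_anchor:
        raise ValueError(f"n_out={n_out} must be >= number of anchors ({n_anchor})")
    if topology not in ("open", "closed"):
        raise ValueError(f"topology must be 'open' or 'closed', got {topology!r}")

    closed = topology == "closed"
    if closed and np.all(anchors[0] == anchors[-1]):
        raise ValueError("closed anchors must not repeat the first point")
    seg = np.diff(anchors, axis=0)
    chord = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(chord == 0.0):
        raise ValueError("coincident consecutive anchor points")

    if n_out == n_anchor:
        return Contour(points=anchors.copy(), topology=topology, frame_index=frame_index)

    if closed:
        closing = float(np.hypot(*(anchors[0] - anchors[-1])))
        if closing == 0.0:
            raise ValueError("coincident consecutive anchor points")
        # periodic parameterisation: wrap a few anchors around each end so
        # the shape-preserving tangents see the closing span
        total = float(chord.sum()) + closing
        s = np.concatenate([[0.0], np.cumsum(chord)])
        wrap = min(3, n_anchor)
        s_ext = np.concatenate([s[-wrap:] - total, s, s[:wrap] + total])
        pts_ext = np.concatenate([anchors[-wrap:], anchors, anchors[:wrap]])
        interp = PchipInterpolator(s_ext, pts_ext, axis=0)
        s_out = np.linspace(0.0, total, n_out, endpoint=False)
    else:
        s = np.concatenate([[0.0], np.cumsum(chord)])
        interp = PchipInterpolator(s, anchors, axis=0)
        s_out = np.linspace(0.0, s[-1], n_out)

    return Contour(points=interp(s_out), topology=topology, frame_index=frame_index)


def border_length(contour: Contour) -> float:
    """Border length as the sum of Euclidean distances between consecutive
    points, plus the closing segment for closed contours."""
    pts = contour.points
    seg = np.diff(pts, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if contour.topology == "closed":
        length += float(np.hypot(*(pts[0] - pts[-1])))
    return length


def ebd_strain(per_frame_contours) -> StrainCurve:
    """Global Lagrangian strain from per-frame border lengths.

    The reference length L0 is the maximal border length over the cycle so
    the curve reads as systolic shortening regardless of which phase the
    acquisition was triggered on.  Constant lengths yield a valid all-zero
    curve.
    """
    contours = list(per_frame_contours)
    if len(contours) < 2:
        raise ValueError("need contours for at least 2 frames")
    topologies = {c.topology for c in contours}
    if len(topologies) > 1:
        raise ValueError(f"mixed topologies across frames: {sorted(topologies)}")

    lengths = np.array([border_length(c) for c in contours])
    reference = int(np.argmax(lengths))
    l0 = lengths[reference]
    values = 100.0 * (lengths - l0) / l0
    values[reference] = 0.0  # exact zero at the reference phase
    return StrainCurve(values_percent=values, lengths_mm=lengths, reference_frame=reference)
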