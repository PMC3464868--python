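"""Feature tracking of an endocardial contour through a cine cycle.

The tracker follows the classic cine feature-tracking recipe: an operator
supplies the border on one frame only, and each point is then carried from
frame to frame by

(a) 2-D template matching — a square intensity patch around the point's
    previous position is matched in the next frame by maximising normalised
    cross-correlation (the maximum-likelihood matcher under Gaussian
    intensity noise), with sub-pixel localisation by parabolic fit of the
    correlation peak;
(b) 1-D border refinement — the matched position is nudged along the local
    contour normal onto the strongest intensity-gradient within +/-2 px,
    locking the point back onto the blood-myocardium edge;
(c) spatial smoothing — displacements are moving-averaged over adjacent
    contour points (periodic for closed contours) for spatial coherence;
(d) optional drift compensation — the cardiac cycle is periodic, so the
    residual between the tracked end-of-cycle position and the starting
    position is removed by linear redistribution across frames.

Global strain in the longitudinal and circumferential directions is the
border-length Lagrangian strain of the tracked contour; radial strain uses
the mean relative displacement of border points toward the cavity centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, median_filter, uniform_filter1d
from skimage.feature import match_template

from .ebd import StrainCurve, border_length, ebd_strain
from .io import CineSequence, Contour

__all__ = [
    "TrackingParams",
    "ContourTrack",
    "SegmentalStrainResult",
    "track_contour",
    "ft_global_strain",
    "ft_segmental_strain",
]

_DIRECTIONS = ("longitudinal", "circumferential", "radial")


@dataclass
class TrackingParams:
    """Tunable parameters of the tracker.

    Defaults assume ~1 mm/px cine with 30-40 ms frames, where inter-frame
    tissue motion is a few pixels at most.
    """

    template_half_width_px: int = 5
    search_radius_px: int = 5
    smoothing_window_points: int = 5
    drift_compensation: bool = True
    normal_refinement: bool = True
    temporal_smoothing: bool = True

    def __post_init__(self) -> None:
        if self.template_half_width_px < 3:
            raise ValueError("template_half_width_px must be >= 3")
        if self.search_radius_px < 1:
            raise ValueError("search_radius_px must be >= 1")
        if self.search_radius_px > self.template_half_width_px + 5:
            raise ValueError("search_radius_px must be <= template_half_width_px + 5")
        if self.smoothing_window_points < 1 or self.smoothing_window_points % 2 == 0:
            raise ValueError("smoothing_window_points must be an odd integer >= 1")


@dataclass
class ContourTrack:
    """Materially corresponding contours across all frames.

    Point ``i`` denotes the same tissue point in every frame; the frame-0
    contour is the supplied initial contour (tracked) or the analytic truth
    (ground_truth).
    """

    contours: list
    params: TrackingParams | None
    source: str = "tracked"

    def __post_init__(self) -> None:
        if self.source not in ("tracked", "ground_truth"):
            raise ValueError(f"source must be 'tracked' or 'ground_truth', got {self.source!r}")
        if len(self.contours) < 2:
            raise ValueError("a track needs at least 2 frames")
        n = len(self.contours[0])
        topo = self.contours[0].topology
        for c in self.contours:
            if len(c) != n or c.topology != topo:
                raise ValueError("all frames must share point count and topology")

    @property
    def topology(self) -> str:
        return self.contours[0].topology

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def n_points(self) -> int:
        return len(self.contours[0])

    def border_lengths(self) -> np.ndarray:
        return np.array([border_length(c) for c in self.contours])


@dataclass
class SegmentalStrainResult:
    """Peak strain per equal-arc-length segment of the reference contour."""

    n_segments: int
    per_segment_peak_percent: np.ndarray
    segment_boundaries: np.ndarray  # arc-length fractions on the reference contour
    segment_reference_lengths_mm: np.ndarray
    per_segment_values_percent: np.ndarray  # (n_segments, n_frames), signed
    reference_frame: int


# ---------------------------------------------------------------------------
# core tracking
# ---------------------------------------------------------------------------

def _contour_normals(pts: np.ndarray, closed: bool) -> np.ndarray:
    # tangents from a lightly smoothed polygon so local tracking jitter
    # does not rotate the normals
    smooth = _smooth_field(pts, 5, closed)
    if closed:
        tangent = np.roll(smooth, -1, axis=0) - np.roll(smooth, 1, axis=0)
    else:
        tangent = np.gradient(smooth, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0.0] = 1.0
    tangent = tangent / norm[:, None]
    return np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= -1e-12:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def _match_displacements(ref_img, ref_pts, img, pts, params, frame_no, closed=True):
    """NCC update per point: the template is cut from the reference frame at
    the point's material (frame-0) position and matched in the current frame
    within the search radius around the point's predicted position (its
    tracked position on the previous frame).

    Matching against the reference template rather than the previous frame
    keeps tracking errors from accumulating and prevents the matcher from
    locking onto frame-to-frame correlated noise when the tissue is still.
    Flat templates are flagged invalid.
    """
    h_base = params.template_half_width_px
    r = params.search_radius_px
    height, width = img.shape
    disp = np.zeros_like(pts)
    valid = np.ones(len(pts), dtype=bool)
    for i, (x, y) in enumerate(pts):
        # open-border end points (annulus corners) anchor all tangential
        # motion on straight walls: give them a larger template so the
        # corner structure outweighs the featureless blood-pool channel
        h = h_base + 1 if (not closed and i in (0, len(pts) - 1)) else h_base
        c0x, c0y = int(round(ref_pts[i, 0])), int(round(ref_pts[i, 1]))
        # window centre: predicted position of the template-centre material point
        wcx = int(round(c0x + x - ref_pts[i, 0]))
        wcy = int(round(c0y + y - ref_pts[i, 1]))
        if not (h + r <= wcx < width - h - r and h + r <= wcy < height - h - r):
            raise ValueError(f"point {i} left image bounds at frame {frame_no}")
        template = ref_img[c0y - h : c0y + h + 1, c0x - h : c0x + h + 1]
        if template.std() < 1e-9:
            valid[i] = False
            continue
        window = img[wcy - h - r : wcy + h + r + 1, wcx - h - r : wcx + h + r + 1]
        cc = match_template(window, template)  # (2r+1, 2r+1) NCC map
        iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
        dx, dy = float(ix - r), float(iy - r)
        if 0 < ix < cc.shape[1] - 1:
            dx += _parabolic_offset(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
        else:
            dx = 0.0  # peak on the window rim is not a localised match
        if 0 < iy < cc.shape[0] - 1:
            dy += _parabolic_offset(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
        else:
            dy = 0.0
        # matched template centre, carried back to the point itself
        new_x = wcx + dx + ref_pts[i, 0] - c0x
        new_y = wcy + dy + ref_pts[i, 1] - c0y
        step_x, step_y = new_x - x, new_y - y
        if not closed and i in (0, len(pts) - 1):
            # physical bound on per-frame landmark motion
            step = np.hypot(step_x, step_y)
            if step > 3.0:
                step_x, step_y = step_x * 3.0 / step, step_y * 3.0 / step
        disp[i] = (step_x, step_y)
    return disp, valid


def _smooth_field(field: np.ndarray, window: int, closed: bool) -> np.ndarray:
    if window <= 1:
        return field
    mode = "wrap" if closed else "nearest"
    return uniform_filter1d(field, size=window, axis=0, mode=mode)


def _fill_invalid(disp, valid, window, closed):
    """Replace flat-template displacements by the local average of valid
    neighbours (the smoothed-neighbour fallback)."""
    if valid.all():
        return disp
    w = max(window, 3)
    weights = valid.astype(float)[:, None]
    num = _smooth_field(disp * weights, w, closed)
    den = _smooth_field(np.broadcast_to(weights, disp.shape).copy(), w, closed)
    fallback = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = disp.copy()
    out[~valid] = fallback[~valid]
    return out


def _edge_polarity(img, pts, closed) -> float:
    """+1 if the blood pool (bright) lies on the -normal side of the border,
    -1 otherwise; estimated once from the operator-drawn initial contour."""
    normals = _contour_normals(pts, closed)
    inner = pts - 2.0 * normals
    outer = pts + 2.0 * normals
    sample = np.concatenate([inner, outer])
    vals = map_coordinates(img, [sample[:, 1], sample[:, 0]], order=1)
    n = len(pts)
    return 1.0 if vals[:n].mean() >= vals[n:].mean() else -1.0


def _refine_along_normal(img, pts, closed, polarity):
    """Move each point along its contour normal onto the endocardial edge:
    the steepest bright-to-dark transition (cavity into wall) within +/-2 px,
    sub-pixel by parabolic fit of the directional-derivative profile."""
    gy, gx = np.gradient(img)
    normals = _contour_normals(pts, closed)
    offsets = np.linspace(-2.0, 2.0, 17)
    sample = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    gxs = map_coordinates(gx, [sample[..., 1].ravel(), sample[..., 0].ravel()], order=1)
    gys = map_coordinates(gy, [sample[..., 1].ravel(), sample[..., 0].ravel()], order=1)
    # signed intensity slope along the cavity-to-wall direction
    dirn = polarity * normals
    prof = -(
        gxs.reshape(len(pts), -1) * dirn[:, None, 0]
        + gys.reshape(len(pts), -1) * dirn[:, None, 1]
    )
    # prior centred on the template-matched position: the edge is expected
    # nearby, so a marginally steeper slope far out (texture, neighbouring
    # structures) must not win over the adjacent border
    prof = prof * np.exp(-(offsets**2) / 2.0)[None, :]
    best = np.argmax(prof, axis=1)
    step = offsets[1] - offsets[0]
    shift = offsets[best]
    interior = (best > 0) & (best < len(offsets) - 1)
    for i in np.flatnonzero(interior):
        k = best[i]
        shift[i] += step * _parabolic_offset(-prof[i, k - 1], -prof[i, k], -prof[i, k + 1])
    # refine only where a convincing edge is in reach; points that lost the
    # edge (weak profile peak) stay at their template-matched position
    peak = prof[np.arange(len(pts)), best]
    weak = peak < np.maximum(0.3 * np.median(peak), 1e-3)
    shift[weak] = 0.0
    return pts + shift[:, None] * normals


_ARC_REGULARIZATION = 0.3  # per-frame pull toward reference arc-length fractions
_ARC_DEVIATION_CAP_PX = 2.0  # hard bound on deviation from the arc target


def _arc_fractions(pts: np.ndarray, closed: bool) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    edge = np.hypot(seg[:, 0], seg[:, 1])
    if closed:
        edge = np.append(edge, np.hypot(*(pts[0] - pts[-1])))
    cum = np.concatenate([[0.0], np.cumsum(edge)])
    return cum / cum[-1]


def _regularize_arc(pts, ref_fractions, closed, gamma=_ARC_REGULARIZATION):
    """Pull each point toward the position on the current polyline at its
    reference arc-length fraction.

    Along smooth featureless wall segments template matching carries no
    tangential information (the aperture problem), so tangential positions
    random-walk; this pull makes them mean-reverting without changing the
    border shape or length, and a hard cap on the residual deviation keeps
    any point from sliding away along the border.  Exact for homogeneous
    deformation (relative arc positions are invariant under uniform
    scaling)."""
    poly = np.vstack([pts, pts[0]]) if closed else pts
    frac = _arc_fractions(pts, closed)  # one entry per poly vertex
    per_point = ref_fractions[: len(pts)]
    targets = np.stack(
        [np.interp(per_point, frac, poly[:, 0]), np.interp(per_point, frac, poly[:, 1])],
        axis=1,
    )
    pulled = pts + gamma * (targets - pts)
    deviation = pulled - targets
    norm = np.hypot(deviation[:, 0], deviation[:, 1])
    over = norm > _ARC_DEVIATION_CAP_PX
    if np.any(over):
        deviation[over] *= (_ARC_DEVIATION_CAP_PX / norm[over])[:, None]
    return targets + deviation


def _step(ref_img, ref_pts, img, pts, params, closed, frame_no, polarity,
          ref_fractions=None):
    disp, valid = _match_displacements(ref_img, ref_pts, img, pts, params, frame_no, closed)
    disp = _fill_invalid(disp, valid, params.smoothing_window_points, closed)
    if params.normal_refinement:
        refined = _refine_along_normal(img, pts + disp, closed, polarity)
        disp = refined - pts
    raw = disp
    if params.smoothing_window_points >= 3:
        # median pass rejects single-point outliers before averaging
        mode = "wrap" if closed else "nearest"
        disp = median_filter(disp, size=(params.smoothing_window_points, 1), mode=mode)
    disp = _smooth_field(disp, params.smoothing_window_points, closed)
    if not closed:
        # open-border end points (annulus corners) carry the only tangential
        # signal on straight walls; averaging them with aperture-limited
        # interior points would make them lag, so they keep their own match
        disp[0] = raw[0]
        disp[-1] = raw[-1]
    new_pts = pts + disp
    if ref_fractions is not None:
        new_pts = _regularize_arc(new_pts, ref_fractions, closed)
    return new_pts


def track_contour(
    sequence: CineSequence,
    initial_contour: Contour,
    params: TrackingParams | None = None,
) -> ContourTrack:
    """Track an initial contour through every frame of a cine sequence.

    The initial contour must lie within frame 0 with a margin of at least
    ``template_half_width_px + search_radius_px`` pixels.  Tracking is
    deterministic: identical inputs give identical tracks.
    """
    if params is None:
        params = TrackingParams()
    spacing = sequence.pixel_spacing_mm
    closed = initial_contour.topology == "closed"
    pts = initial_contour.points / spacing  # work in pixel coordinates

    h, r = params.template_half_width_px, params.search_radius_px
    height, width = sequence.shape
    margin = h + r
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() >= width - margin
        or pts[:, 1].max() >= height - margin
    ):
        raise ValueError(
            f"initial contour too close to the image border (needs {margin} px margin)"
        )

    polarity = _edge_polarity(sequence.frames[0], pts, closed)
    ref_fractions = _arc_fractions(pts, closed)
    ref_img = sequence.frames[0]
    positions = [pts]
    for t in range(1, sequence.phase_count):
        positions.append(
            _step(ref_img, pts, sequence.frames[t], positions[-1], params,
                  closed, t, polarity, ref_fractions)
        )

    if params.drift_compensation:
        # one extra step back onto frame 0 closes the cycle; the residual is
        # accumulated drift, removed linearly across the cycle
        closure = _step(
            ref_img, pts, sequence.frames[0], positions[-1], params, closed,
            sequence.phase_count, polarity, ref_fractions,
        )
        residual = closure - positions[0]
        n = sequence.phase_count
        positions = [p - residual * (t / n) for t, p in enumerate(positions)]

    if params.temporal_smoothing:
        # light temporal coherence filter on each point trajectory; damps
        # single-frame jitter while attenuating a smooth systolic excursion
        # by only ~2% at 25 phases per cycle
        from scipy.ndimage import convolve1d

        stack = np.stack(positions)
        mode = "wrap" if params.drift_compensation else "nearest"
        stack = convolve1d(stack, [0.25, 0.5, 0.25], axis=0, mode=mode)
        positions = list(stack)
        positions[0] = pts  # frame 0 stays the operator-drawn contour

    contours = [
        Contour(points=p * spacing, topology=initial_contour.topology, frame_index=t)
        for t, p in enumerate(positions)
    ]
    return ContourTrack(contours=contours, params=params, source="tracked")


# ---------------------------------------------------------------------------
# strain from tracks
# ---------------------------------------------------------------------------

def ft_global_strain(track: ContourTrack, direction: str) -> StrainCurve:
    """Global strain of a track in a given direction.

    Longitudinal (open borders, four-chamber view) and circumferential
    (closed borders, short-axis view) strain are the border-length Lagrangian
    strain.  Radial strain is the mean over points of the relative change in
    distance to the cavity centroid of the reference (maximal-area) frame;
    for radial curves ``lengths_mm`` carries the mean radius per frame.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    if direction == "longitudinal" and track.topology != "open":
        raise ValueError("longitudinal strain needs an open (four-chamber) border")
    if direction in ("circumferential", "radial") and track.topology != "closed":
        raise ValueError(f"{direction} strain needs a closed (short-axis) border")

    if direction in ("longitudinal", "circumferential"):
        return ebd_strain(track.contours)

    from shapely.geometry import Polygon

    polygons = [Polygon(c.points) for c in track.contours]
    reference = int(np.argmax([p.area for p in polygons]))
    centroid = np.array(polygons[reference].centroid.coords[0])
    radii = np.array(
        [np.hypot(*(c.points - centroid).T) for c in track.contours]
    )  # (T, N)
    r_ref = radii[reference]
    values = 100.0 * np.mean((radii - r_ref) / r_ref, axis=1)
    values[reference] = 0.0
    return StrainCurve(
        values_percent=values,
        lengths_mm=radii.mean(axis=1),
        reference_frame=reference,
    )


def _segment_lengths(points: np.ndarray, bounds: np.ndarray, closed: bool) -> np.ndarray:
    """Polyline length of each point run ``bounds[j]..bounds[j+1]``; for
    closed contours the last run wraps through the closing edge to point 0."""
    n = len(points)
    seg = np.diff(points, axis=0)
    edge = np.hypot(seg[:, 0], seg[:, 1])
    if closed:
        edge = np.append(edge, np.hypot(*(points[0] - points[-1])))
    cum = np.concatenate([[0.0], np.cumsum(edge)])  # cum[i] = length up to point i
    lengths = np.empty(len(bounds) - 1)
    for j in range(len(bounds) - 1):
        lengths[j] = cum[bounds[j + 1]] - cum[bounds[j]]
    return lengths


def ft_segmental_strain(track: ContourTrack, n_segments: int = 6) -> SegmentalStrainResult:
    """Per-segment peak strain on an equal-arc-length partition.

    The contour of the reference (maximal-length) frame is cut into
    ``n_segments`` runs of equal arc length; segment boundaries are shared
    points, so segment lengths sum exactly to the border length and the
    length-weighted mean of segment strains equals the global strain.
    All segments are referenced to the same (global) reference frame.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if track.n_points < 4 * n_segments:
        raise ValueError(
            f"{track.n_points} points are too few for {n_segments} segments "
            f"(need >= {4 * n_segments})"
        )
    closed = track.topology == "closed"
    lengths = track.border_lengths()
    reference = int(np.argmax(lengths))
    ref_pts = track.contours[reference].points

    seg = np.diff(ref_pts, axis=0)
    edge = np.hypot(seg[:, 0], seg[:, 1])
    if closed:
        edge = np.append(edge, np.hypot(*(ref_pts[0] - ref_pts[-1])))
    cum = np.concatenate([[0.0], np.cumsum(edge)])
    total = cum[-1]

    targets = np.arange(1, n_segments) * total / n_segments
    cuts = np.searchsorted(cum, targets)
    bounds = np.concatenate([[0], cuts, [len(ref_pts) if closed else len(ref_pts) - 1]])
    if np.any(np.diff(bounds) < 2):
        raise ValueError("too few points per segment for this partition")

    per_frame = np.stack(
        [_segment_lengths(c.points, bounds, closed) for c in track.contours]
    )  # (T, n_segments)
    ref_lengths = per_frame[reference]
    values = 100.0 * (per_frame - ref_lengths) / ref_lengths  # (T, S)
    values[reference] = 0.0
    return SegmentalStrainResult(
        n_segments=n_segments,
        per_segment_peak_percent=np.max(np.abs(values), axis=0),
        segment_boundaries=cum[bounds] / total,
        segment_reference_lengths_mm=ref_lengths,
        per_segment_values_percent=values.T,
        reference_frame=reference,
    )
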