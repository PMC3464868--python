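"""Synthetic deforming cardiac phantoms with analytic ground truth.

Two geometries emulate SSFP-like cine slices (bright blood pool, darker
myocardium) with a prescribed, analytically known deformation:

``short_axis_ring``
    A circular cavity with a myocardial annulus — the short-axis view.  The
    whole tissue undergoes isotropic scaling about the cavity centre, so the
    endocardial circumference shortens by exactly the prescribed fraction.

``four_chamber_u``
    An open U-shaped border (two straight walls joined by an apical cap) —
    a single ventricle in a four-chamber view.  The scene scales uniformly
    about the border centroid, again shortening the border arc by exactly
    the prescribed fraction.

Because the deformation is a similarity transform, the ground-truth contour
track, border lengths and strain curve are exact closed forms; rendering
only contributes pixel discretisation.  Dark Gaussian "texture" dips are
embedded at fixed material positions in the wall (they move with the
tissue), mimicking the trabeculations and brightness inhomogeneities that
feature tracking exploits.

The module also contains the analytic out-of-plane model: a fixed short-axis
imaging plane through a truncated-cone cavity whose tissue moves apically
during systole, which makes length-based circumferential strain read low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .ebd import StrainCurve, ebd_strain
from .io import CineSequence, Contour
from .tracking import ContourTrack

__all__ = [
    "PhantomSpec",
    "OutOfPlaneSpec",
    "PhantomOutput",
    "make_phantom",
    "simulate_out_of_plane",
    "systolic_waveform",
]

# SSFP-like intensities before noise (myocardium-blood contrast = 1 unit scale)
_I_CAVITY = 1.0
_I_MYO = 0.5
_I_BG = 0.1
_EDGE_SOFT_MM = 0.7  # logistic edge width; emulates partial-volume blur at 1 mm
_BLOB_SIGMA_MM = 2.0  # texture dip scale, mm
_BLOB_AMPLITUDE = 0.25


@dataclass
class PhantomSpec:
    """Parameters of a deforming phantom.

    ``true_peak_strain_percent`` is the absolute shortening of the
    endocardial border at peak systole; the deformation is cyclic (frame 0
    and the implied end of cycle coincide) with peak shortening at the phase
    nearest one third of the cycle.
    """

    geometry: str = "short_axis_ring"
    ed_inner_radius_mm: float = 25.0  # ring: end-diastolic endocardial radius
    ed_length_mm: float = 160.0  # U-shape: end-diastolic border length
    apex_radius_mm: float = 15.0  # U-shape: apical cap radius
    wall_thickness_mm: float = 8.0
    true_peak_strain_percent: float = 20.0
    phase_count: int = 25
    pixel_spacing_mm: float = 1.0
    frame_interval_ms: float = 40.0
    texture_feature_count: int = 40
    noise_sd: float = 0.05
    n_border_points: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("short_axis_ring", "four_chamber_u"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not (0.0 <= self.true_peak_strain_percent < 60.0):
            raise ValueError("true_peak_strain_percent must be in [0, 60)")
        if self.phase_count < 8:
            raise ValueError("phase_count must be >= 8")
        if self.pixel_spacing_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("spacing and wall thickness must be positive")
        if self.noise_sd < 0 or self.texture_feature_count < 0:
            raise ValueError("noise_sd and texture_feature_count must be >= 0")
        if self.geometry == "four_chamber_u":
            if self.ed_length_mm <= np.pi * self.apex_radius_mm:
                raise ValueError(
                    "ed_length_mm too short for the apical cap radius"
                )


@dataclass
class OutOfPlaneSpec:
    """Truncated-cone cavity imaged by a fixed short-axis plane.

    The cavity radius falls linearly from ``base_radius_mm`` at the base to
    ``apex_radius_mm`` at the apex over ``long_axis_mm``.  The imaging plane
    sits ``slice_level_fraction`` of the long axis below the base.  During
    systole the tissue moves ``longitudinal_displacement_mm`` toward the
    apex, so the fixed plane samples tissue that started out more basal.
    """

    base_radius_mm: float
    apex_radius_mm: float
    slice_level_fraction: float = 0.5
    longitudinal_displacement_mm: float = 0.0
    true_cs_percent: float = 15.0
    long_axis_mm: float = 80.0

    def __post_init__(self) -> None:
        if not self.base_radius_mm > self.apex_radius_mm > 0:
            raise ValueError("need base_radius_mm > apex_radius_mm > 0")
        if not 0.0 < self.slice_level_fraction < 1.0:
            raise ValueError("slice_level_fraction must be in (0, 1)")
        if self.longitudinal_displacement_mm < 0:
            raise ValueError("longitudinal_displacement_mm must be >= 0")
        if self.long_axis_mm <= 0:
            raise ValueError("long_axis_mm must be positive")


@dataclass
class PhantomOutput:
    sequence: CineSequence
    truth_track: ContourTrack
    truth_strain: StrainCurve
    spec: PhantomSpec


def systolic_waveform(phase_count: int) -> np.ndarray:
    """Smooth cyclic 0 -> 1 -> 0 activation, peaking at round(phase_count/3).

    Raised cosine over the contraction-relaxation interval followed by
    diastasis at zero; C1-continuous at the joins and across the cycle wrap.
    """
    t_peak = int(round(phase_count / 3))
    t = np.arange(phase_count)
    w = np.zeros(phase_count)
    active = t <= 2 * t_peak
    w[active] = 0.5 * (1.0 - np.cos(np.pi * t[active] / t_peak))
    return w


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ring_truth_points(spec: PhantomSpec, centre: np.ndarray) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(spec.n_border_points) / spec.n_border_points
    return centre + spec.ed_inner_radius_mm * np.stack([np.cos(theta), np.sin(theta)], axis=1)


def _u_curve(spec: PhantomSpec, origin: np.ndarray, s_arc: np.ndarray):
    """Point and outward unit normal of the U border at arc lengths ``s_arc``.

    The border runs from the left annulus corner down the left wall, around
    the apical cap, and up the right wall.  ``origin`` is the cap centre;
    image-coordinate y grows downward so "down the wall" is +y.
    """
    r = spec.apex_radius_mm
    h = (spec.ed_length_mm - np.pi * r) / 2.0  # straight-wall height
    pts = np.empty((len(s_arc), 2))
    nrm = np.empty((len(s_arc), 2))

    left = s_arc <= h
    pts[left, 0] = origin[0] - r
    pts[left, 1] = origin[1] - h + s_arc[left]
    nrm[left] = (-1.0, 0.0)

    arc = (s_arc > h) & (s_arc <= h + np.pi * r)
    phi = np.pi + (s_arc[arc] - h) / r  # pi -> 2*pi through the bottom
    pts[arc, 0] = origin[0] + r * np.cos(phi)
    pts[arc, 1] = origin[1] - r * np.sin(phi)
    nrm[arc, 0] = np.cos(phi)
    nrm[arc, 1] = -np.sin(phi)

    right = s_arc > h + np.pi * r
    pts[right, 0] = origin[0] + r
    pts[right, 1] = origin[1] - (s_arc[right] - h - np.pi * r)
    nrm[right] = (1.0, 0.0)
    return pts, nrm


def _render_ring(spec: PhantomSpec, x_mat, y_mat, centre, blobs):
    d = np.hypot(x_mat - centre[0], y_mat - centre[1])
    r_in = spec.ed_inner_radius_mm
    r_out = r_in + spec.wall_thickness_mm
    wall = expit((r_out - d) / _EDGE_SOFT_MM)
    cavity = expit((r_in - d) / _EDGE_SOFT_MM)
    img = _I_BG + (_I_MYO - _I_BG) * wall
    img = img + (_I_CAVITY - img) * cavity
    return _apply_blobs(img, x_mat, y_mat, blobs)


def _render_u(spec: PhantomSpec, x_mat, y_mat, cap_centre, y_annulus, blobs):
    r = spec.apex_radius_mm
    dx = x_mat - cap_centre[0]
    below_cap = y_mat > cap_centre[1]
    d = np.where(below_cap, np.hypot(dx, y_mat - cap_centre[1]), np.abs(dx))
    wall = expit((r + spec.wall_thickness_mm - d) / _EDGE_SOFT_MM)
    wall = wall * expit((y_mat - y_annulus) / _EDGE_SOFT_MM)  # wall ends at annulus
    cavity = expit((r - d) / _EDGE_SOFT_MM)  # blood pool continues into the atrium
    img = _I_BG + (_I_MYO - _I_BG) * wall
    img = img + (_I_CAVITY - img) * cavity
    return _apply_blobs(img, x_mat, y_mat, blobs)


def _apply_blobs(img, x_mat, y_mat, blobs):
    for bx, by in blobs:
        img = img - _BLOB_AMPLITUDE * np.exp(
            -((x_mat - bx) ** 2 + (y_mat - by) ** 2) / (2.0 * _BLOB_SIGMA_MM**2)
        )
    return img


# ---------------------------------------------------------------------------
# main phantom generator
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a deforming phantom sequence with its exact truth track.

    The deformation law is an isotropic scale ``s(t) = 1 - a * w(t)`` about
    a fixed centre (cavity centre for the ring, border centroid for the U),
    with ``a = true_peak_strain_percent / 100`` and ``w`` the systolic
    waveform.  Frames are rendered by sampling the end-diastolic intensity
    field at back-transformed material coordinates, so texture features move
    exactly with the tissue.  Identical specs (including seed) give
    bit-identical output.
    """
    a = spec.true_peak_strain_percent / 100.0
    scales = 1.0 - a * systolic_waveform(spec.phase_count)
    if np.any(scales <= 0.0):
        raise ValueError("prescribed strain collapses the endocardium (scale <= 0)")

    rng = np.random.default_rng(spec.seed)
    dx_mm = spec.pixel_spacing_mm

    if spec.geometry == "short_axis_ring":
        r_out = spec.ed_inner_radius_mm + spec.wall_thickness_mm
        half = r_out + 8.0
        n_px = 2 * int(np.ceil(half / dx_mm)) + 1
        centre = np.array([(n_px - 1) / 2.0 * dx_mm] * 2)
        truth_ed = _ring_truth_points(spec, centre)
        deform_centre = centre
        # texture at fixed material positions in the wall
        theta = rng.uniform(0.0, 2.0 * np.pi, spec.texture_feature_count)
        rho = spec.ed_inner_radius_mm + spec.wall_thickness_mm * rng.uniform(
            0.5, 0.9, spec.texture_feature_count
        )
        blobs_ed = deform_centre + rho[:, None] * np.stack(
            [np.cos(theta), np.sin(theta)], axis=1
        )
        topology = "closed"
        shape = (n_px, n_px)

        def render(x_mat, y_mat):
            return _render_ring(spec, x_mat, y_mat, centre, blobs_ed)

    else:  # four_chamber_u
        r = spec.apex_radius_mm
        h = (spec.ed_length_mm - np.pi * r) / 2.0
        margin = 8.0
        y_annulus = margin + 10.0  # atrium headroom above the annulus plane
        cap_centre = np.array([r + spec.wall_thickness_mm + margin, y_annulus + h])
        width = int(np.ceil((2 * (r + spec.wall_thickness_mm) + 2 * margin) / dx_mm)) + 1
        height = int(np.ceil((y_annulus + h + r + spec.wall_thickness_mm + margin) / dx_mm)) + 1
        s_arc = np.linspace(0.0, spec.ed_length_mm, spec.n_border_points)
        truth_ed, _ = _u_curve(spec, cap_centre, s_arc)
        deform_centre = truth_ed.mean(axis=0)
        # texture along the border, offset outward into the wall; the basal
        # 8 mm next to the annulus plane stays free of features
        u = rng.uniform(8.0, spec.ed_length_mm - 8.0, spec.texture_feature_count)
        off = spec.wall_thickness_mm * rng.uniform(0.5, 0.9, spec.texture_feature_count)
        on_curve, normals = _u_curve(spec, cap_centre, u)
        blobs_ed = on_curve + off[:, None] * normals
        topology = "open"
        shape = (height, width)

        def render(x_mat, y_mat):
            return _render_u(spec, x_mat, y_mat, cap_centre, y_annulus, blobs_ed)

    cols, rows = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    x_mm = cols * dx_mm
    y_mm = rows * dx_mm

    frames = np.empty((spec.phase_count, *shape))
    contours = []
    for t, s in enumerate(scales):
        # pixel p shows the material point that deformed onto it
        x_mat = deform_centre[0] + (x_mm - deform_centre[0]) / s
        y_mat = deform_centre[1] + (y_mm - deform_centre[1]) / s
        frames[t] = render(x_mat, y_mat)
        pts = deform_centre + (truth_ed - deform_centre) * s
        contours.append(Contour(points=pts, topology=topology, frame_index=t))

    noise = rng.standard_normal(frames.shape)
    if spec.noise_sd > 0:
        frames = frames + spec.noise_sd * noise

    sequence = CineSequence(
        frames=frames,
        pixel_spacing_mm=dx_mm,
        frame_interval_ms=spec.frame_interval_ms,
        source_id=f"phantom:{spec.geometry}:seed{spec.seed}",
    )
    track = ContourTrack(contours=contours, params=None, source="ground_truth")
    return PhantomOutput(
        sequence=sequence,
        truth_track=track,
        truth_strain=ebd_strain(contours),
        spec=spec,
    )


def simulate_out_of_plane(spec: OutOfPlaneSpec) -> tuple[float, float]:
    """Circumferential strain measured by a fixed imaging plane on a
    contracting cone versus the true material shortening.

    The diastolic circumference L0 is read in-plane.  At end-systole the
    plane intersects tissue that started ``longitudinal_displacement_mm``
    more basal (larger radius); that tissue's circumference, after the true
    material shortening, is what the plane measures.  Strain follows the
    length-based definition CS = 100 * (diastolic - systolic) / diastolic,
    so any basal shift makes the measured value read below the true one.

    Returns ``(true_cs_percent, measured_cs_percent)``.
    """
    taper = (spec.base_radius_mm - spec.apex_radius_mm) / spec.long_axis_mm
    z_plane = spec.slice_level_fraction * spec.long_axis_mm
    z_material = z_plane - spec.longitudinal_displacement_mm
    if z_material < 0:
        raise ValueError(
            "longitudinal displacement moves the sampled tissue beyond the base"
        )
    r_diastole = spec.base_radius_mm - taper * z_plane
    r_material = spec.base_radius_mm - taper * z_material  # >= r_diastole
    shortening = spec.true_cs_percent / 100.0
    systolic_circumference = 2.0 * np.pi * r_material * (1.0 - shortening)
    diastolic_circumference = 2.0 * np.pi * r_diastole
    measured = 100.0 * (diastolic_circumference - systolic_circumference) / diastolic_circumference
    return float(spec.true_cs_percent), float(measured)
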