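"""Cine-sequence and contour I/O.

Conventions used throughout the package:

* A cine sequence is a single imaging slice acquired repeatedly across one
  cardiac cycle (phases), stored as a ``(T, H, W)`` float array with
  isotropic in-plane calibration in mm/pixel and a frame interval in ms.
* Contour coordinates are physical millimetres, 0-based, with the origin at
  the centre of the top-left pixel; ``x`` runs along columns, ``y`` along
  rows.  This keeps every length computation in physical units.
* Closed contours never repeat their first point; closure is implied and
  every length computation adds the closing segment explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CineSequence",
    "Contour",
    "read_dicom_series",
    "read_image_stack",
    "write_image_stack",
    "read_contour_file",
    "write_contour_file",
]


@dataclass
class CineSequence:
    """Ordered single-slice image frames spanning one cardiac cycle.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Scalar intensity frames ordered by cardiac phase.
    pixel_spacing_mm : float
        Isotropic in-plane resolution, mm per pixel.
    frame_interval_ms : float
        Temporal spacing between consecutive phases.
    source_id : str
        Free-text provenance tag (directory, file, or phantom spec).
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_ms: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError(
                f"a cine sequence needs at least 2 phases, got {self.frames.shape[0]}"
            )
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.frame_interval_ms > 0:
            raise ValueError("frame_interval_ms must be positive")

    @property
    def phase_count(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) of a single frame."""
        return self.frames.shape[1:]


@dataclass
class Contour:
    """Ordered sub-pixel boundary points for one frame.

    ``topology`` is ``"open"`` for borders traced annulus-to-annulus (four
    chamber view) and ``"closed"`` for a full cavity outline (short axis
    view).  Closed contours do not repeat the first point.
    """

    points: np.ndarray
    topology: str
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array of (x, y) in mm")
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        if self.topology not in ("open", "closed"):
            raise ValueError(f"topology must be 'open' or 'closed', got {self.topology!r}")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")
        if self.topology == "closed" and np.all(self.points[0] == self.points[-1]):
            raise ValueError(
                "closed contours must not repeat the first point; closure is implied"
            )

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _phase_key(ds, path: Path):
    """Sorting key for one cine frame: trigger time preferred, instance
    number as fallback (vendor exports use either)."""
    tt = getattr(ds, "TriggerTime", None)
    if tt is not None:
        return (0, float(tt))
    inum = getattr(ds, "InstanceNumber", None)
    if inum is not None:
        return (1, int(inum))
    raise ValueError(
        f"cannot order cine phases: {path} has neither TriggerTime nor InstanceNumber"
    )


def read_dicom_series(directory_path) -> CineSequence:
    """Read a directory of single-slice cine DICOM files as one sequence.

    Frames are ordered by trigger time when available, otherwise by instance
    number.  Pixel spacing must be isotropic to within 1%; mixed slice
    positions are rejected.
    """
    import pydicom

    directory = Path(directory_path)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise ValueError(f"no files in {directory}")

    entries = []
    for path in paths:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise ValueError(f"cannot read DICOM file {path}: {exc}") from exc
        entries.append((path, ds))

    # reject mixed slice positions (multi-slice exports are out of scope)
    positions = set()
    for path, ds in entries:
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is None:
            pos = getattr(ds, "SliceLocation", None)
        if pos is not None:
            positions.add(tuple(np.round(np.atleast_1d(np.asarray(pos, float)), 3)))
    if len(positions) > 1:
        raise ValueError(
            f"directory {directory} mixes slice positions: {sorted(positions)}"
        )

    keyed = sorted(((_phase_key(ds, p), p, ds) for p, ds in entries), key=lambda e: e[0])
    frames = np.stack([ds.pixel_array.astype(float) for _, _, ds in keyed])
    if frames.shape[0] < 2:
        raise ValueError(
            f"{directory} holds {frames.shape[0]} phase(s); a cine needs at least 2"
        )

    ref = keyed[0][2]
    spacing = getattr(ref, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{keyed[0][1]} has no PixelSpacing")
    sr, sc = float(spacing[0]), float(spacing[1])
    if abs(sr - sc) > 0.01 * max(sr, sc):
        raise ValueError(f"anisotropic pixel spacing {sr} x {sc} mm exceeds 1%")

    trigger_times = [k[1] for k, _, _ in keyed if k[0] == 0]
    if len(trigger_times) == len(keyed) and len(set(trigger_times)) > 1:
        interval = float(np.median(np.diff(sorted(trigger_times))))
    else:
        ft = getattr(ref, "FrameTime", None)
        if ft is None:
            raise ValueError(
                "cannot determine frame interval: no varying TriggerTime and no FrameTime"
            )
        interval = float(ft)

    return CineSequence(
        frames=frames,
        pixel_spacing_mm=(sr + sc) / 2.0,
        frame_interval_ms=interval,
        source_id=str(directory),
    )


# ---------------------------------------------------------------------------
# Image stacks (TIFF / NPY / NPZ)
# ---------------------------------------------------------------------------

def read_image_stack(file_path, pixel_spacing_mm: float, frame_interval_ms: float) -> CineSequence:
    """Read a multi-frame TIFF or numpy archive as a cine sequence.

    Calibration is not stored in these formats and must be supplied.
    """
    path = Path(file_path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        frames = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".npy":
        frames = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as archive:
            key = "frames" if "frames" in archive else archive.files[0]
            frames = archive[key]
    else:
        raise ValueError(f"unsupported stack format {suffix!r} (use .tif/.npy/.npz)")
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    return CineSequence(
        frames=frames,
        pixel_spacing_mm=pixel_spacing_mm,
        frame_interval_ms=frame_interval_ms,
        source_id=str(path),
    )


def write_image_stack(sequence: CineSequence, file_path) -> None:
    """Write the frames of a sequence to TIFF (float32) or NPY/NPZ (float64).

    NPY/NPZ round-trips are bit exact; TIFF is exact for values representable
    in float32.
    """
    path = Path(file_path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, sequence.frames.astype(np.float32))
    elif suffix == ".npy":
        np.save(path, sequence.frames)
    elif suffix == ".npz":
        np.savez_compressed(path, frames=sequence.frames)
    else:
        raise ValueError(f"unsupported stack format {suffix!r} (use .tif/.npy/.npz)")


# ---------------------------------------------------------------------------
# Contour files
# ---------------------------------------------------------------------------

_CONTOUR_COLUMNS = ["frame_index", "point_order", "x_mm", "y_mm", "topology"]


def read_contour_file(file_path) -> list[Contour]:
    """Read per-frame contours from CSV (or JSON records with the same fields).

    Expected columns: ``frame_index, point_order, x_mm, y_mm, topology``.
    Returns one :class:`Contour` per frame, sorted by frame index, points
    sorted by ``point_order``.
    """
    path = Path(file_path)
    if path.suffix.lower() == ".json":
        table = pd.DataFrame(json.loads(path.read_text()))
    else:
        table = pd.read_csv(path)
    missing = [c for c in _CONTOUR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path} lacks columns {missing}")
    if table.duplicated(subset=["frame_index", "point_order"]).any():
        dup = table[table.duplicated(subset=["frame_index", "point_order"], keep=False)]
        pair = dup.iloc[0]
        raise ValueError(
            f"duplicate (frame_index, point_order) = "
            f"({int(pair.frame_index)}, {int(pair.point_order)}) in {path}"
        )
    topologies = set(table["topology"].unique())
    if len(topologies) > 1:
        raise ValueError(f"{path} mixes topologies {sorted(topologies)}")

    contours = []
    for frame_index, grp in table.groupby("frame_index", sort=True):
        grp = grp.sort_values("point_order")
        contours.append(
            Contour(
                points=grp[["x_mm", "y_mm"]].to_numpy(float),
                topology=str(grp["topology"].iloc[0]),
                frame_index=int(frame_index),
            )
        )
    return contours


def write_contour_file(contours, file_path) -> None:
    """Write contours as CSV readable by :func:`read_contour_file`.

    Coordinates are written with 6 decimal places (lossless at sub-micron
    precision for mm-scale anatomy).
    """
    if not contours:
        raise ValueError("cannot write an empty contour list")
    rows = []
    for contour in contours:
        for order, (x, y) in enumerate(contour.points):
            rows.append(
                {
                    "frame_index": contour.frame_index,
                    "point_order": order,
                    "x_mm": x,
                    "y_mm": y,
                    "topology": contour.topology,
                }
            )
    table = pd.DataFrame(rows, columns=_CONTOUR_COLUMNS)
    table.to_csv(file_path, index=False, float_format="%.6f")
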