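"""File I/O: volumes (DICOM series / NIfTI / NRRD), landmarks, cohort tables.

Volume reading and writing is delegated to SimpleITK; this module only
adapts between ``sitk.Image`` and :class:`~rwniche.grid.VoxelGrid`
(index order ``(i, j, k)`` = image ``(x, y, z)``, world geometry from
the header).  Landmarks are accepted either as a 3D-Slicer-style
fiducial markup JSON or as a simple ``name,x,y,z`` CSV; the four
required labels are ``Cochlea_r-1`` (midmodiolar apex), ``Cochlea_r-2``
(midmodiolar basal turn), ``Cochlea_r-3`` (a point on the round window
membrane) and ``RWN_1`` (tip of the bony overhang).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grid import LabelMask, VoxelGrid

APEX_LABEL = "Cochlea_r-1"
BASAL_LABEL = "Cochlea_r-2"
RWM_LABEL = "Cochlea_r-3"
TIP_LABEL = "RWN_1"
LANDMARK_LABELS = (APEX_LABEL, BASAL_LABEL, RWM_LABEL, TIP_LABEL)

COHORT_COLUMNS = ("id", "sex", "age", "side", "vol_mm3", "area_mm2", "oh_mm", "d_mm")


class FormatError(ValueError):
    """Raised for unreadable or ambiguous input files."""


@dataclass(frozen=True)
class LandmarkSet:
    """The four manually placed landmarks, world mm."""

    apex: np.ndarray
    basal: np.ndarray
    rwm_point: np.ndarray
    overhang_tip: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        for name in ("apex", "basal", "rwm_point", "overhang_tip"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} has non-finite coordinates")
            object.__setattr__(self, name, p)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.allclose(self.apex, self.basal):
            raise ValueError("apex and basal landmarks coincide")

    def replace(self, **kw) -> "LandmarkSet":
        return replace(self, **kw)


@dataclass
class CaseRecord:
    """One case: intensity volume, RWN mask, landmarks, cohort metadata."""

    id: str
    volume: VoxelGrid
    mask: LabelMask
    landmarks: LandmarkSet
    age: float = float("nan")
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if np.isfinite(self.age) and self.age < 0:
            raise ValueError("age must be >= 0")
        if self.mask.n_foreground == 0:
            raise ValueError("case mask is empty")


# ---------------------------------------------------------------------------
# volumes


def _image_to_grid(img: sitk.Image) -> VoxelGrid:
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return VoxelGrid(
        data=data,
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def _grid_to_image(grid: VoxelGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data.transpose(2, 1, 0)))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(tuple(grid.direction.ravel()))
    return img


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a DICOM series directory, NIfTI or NRRD volume.

    Geometry (spacing, origin, direction cosines) is taken from the
    header; intensities are returned unmodified.  Anisotropic spacing is
    permitted.  A DICOM directory containing more than one series is
    rejected as ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        series_ids = reader.GetGDCMSeriesIDs(str(path))
        if not series_ids:
            raise FormatError(f"no DICOM series found in directory {path}")
        if len(series_ids) > 1:
            raise FormatError(
                f"directory {path} contains {len(series_ids)} DICOM series "
                f"(UIDs {', '.join(series_ids)}); split them or point at one series"
            )
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path), series_ids[0]))
        img = reader.Execute()
    else:
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - message passthrough
            raise FormatError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {img.GetDimension()}-D")
    return _image_to_grid(img)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as NRRD or NIfTI (by file extension)."""
    sitk.WriteImage(_grid_to_image(grid), str(Path(path)))


def read_mask(path: str | Path, grid: VoxelGrid | None = None) -> LabelMask:
    """Read a binary mask; any nonzero voxel is foreground.

    If ``grid`` is given, the mask must match its shape and geometry and
    is attached to it; otherwise the mask's own header geometry is used.
    """
    mgrid = read_volume(path)
    if grid is not None:
        if mgrid.shape != grid.shape:
            raise FormatError(
                f"mask shape {mgrid.shape} does not match volume shape {grid.shape}"
            )
        if not mgrid.same_geometry(grid, atol=1e-4):
            raise FormatError("mask world geometry does not match the volume")
        return LabelMask(data=mgrid.data, grid=grid)
    return LabelMask(data=mgrid.data, grid=mgrid)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    grid = VoxelGrid(
        data=mask.data.astype(np.uint8),
        spacing=mask.grid.spacing,
        origin=mask.grid.origin,
        direction=mask.grid.direction,
    )
    write_volume(grid, path)


# ---------------------------------------------------------------------------
# landmarks


def _landmarks_from_points(points: dict[str, np.ndarray], side: str) -> LandmarkSet:
    missing = [name for name in LANDMARK_LABELS if name not in points]
    if missing:
        raise FormatError("missing landmark " + ", ".join(missing))
    return LandmarkSet(
        apex=points[APEX_LABEL],
        basal=points[BASAL_LABEL],
        rwm_point=points[RWM_LABEL],
        overhang_tip=points[TIP_LABEL],
        side=side,
    )


def read_landmarks(path: str | Path, side: str = "right") -> LandmarkSet:
    """Read landmarks from a Slicer-style markup JSON or a name,x,y,z CSV.

    Label-to-field mapping is by name and independent of row order.  A
    missing or duplicated label is an error listing the offending names.
    """
    path = Path(path)
    if path.suffix.lower() == ".json" or path.name.endswith(".mrk.json"):
        payload = json.loads(path.read_text())
        markups = payload.get("markups", [payload])
        points: dict[str, np.ndarray] = {}
        for markup in markups:
            for cp in markup.get("controlPoints", []):
                label = cp["label"]
                if label in points:
                    raise FormatError(f"duplicated landmark {label}")
                points[label] = np.asarray(cp["position"], dtype=float)
        return _landmarks_from_points(points, side)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and row[0].strip()]
    points = {}
    for row in rows:
        label = row[0].strip()
        if label.lower() in ("name", "label"):
            continue
        if label in points:
            raise FormatError(f"duplicated landmark {label}")
        points[label] = np.asarray([float(v) for v in row[1:4]], dtype=float)
    return _landmarks_from_points(points, side)


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for label, point in zip(
            LANDMARK_LABELS,
            (landmarks.apex, landmarks.basal, landmarks.rwm_point, landmarks.overhang_tip),
        ):
            writer.writerow([label, *(repr(float(v)) for v in point)])


def write_landmarks_json(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks in the Slicer fiducial-markup JSON dialect."""
    control_points = [
        {"id": str(i + 1), "label": label, "position": [float(v) for v in point]}
        for i, (label, point) in enumerate(
            zip(
                LANDMARK_LABELS,
                (landmarks.apex, landmarks.basal, landmarks.rwm_point, landmarks.overhang_tip),
            )
        )
    ]
    payload = {
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": control_points,
            }
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# cohort tables


def write_cohort_table(records: Sequence[dict], path: str | Path) -> None:
    """Write per-case morphometry rows as CSV.

    Each record is a mapping with at least the keys in
    ``COHORT_COLUMNS``; numbers are written at full precision.
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty cohort table")
    frame = pd.DataFrame(list(records))
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort records missing columns: {missing}")
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    frame = frame[list(COHORT_COLUMNS) + extra]
    frame.to_csv(path, index=False, float_format="%.17g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    return frame
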