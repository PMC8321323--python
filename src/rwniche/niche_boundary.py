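"""Open boundary of the niche toward the middle ear: the tip cylinder.

The niche has no bony wall toward the tympanic cavity, so its outer
border is defined geometrically: the distance from the bony-overhang
tip landmark to the midmodiolar axis defines an (uncapped) cylinder
around that axis, and the segmentation is clipped so it does not extend
beyond the cylinder.  Inclusion is decided at voxel centers with "<=",
so a voxel whose center lies exactly on the cylinder is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cochlear_frame import CochlearFrame, world_to_frame
from .grid import LabelMask

MIN_CYLINDER_RADIUS_MM = 0.2


class ImplausibleLandmarkError(ValueError):
    """Overhang tip essentially on the midmodiolar axis."""


@dataclass(frozen=True)
class NicheBoundary:
    """Cylinder about the frame's z-axis bounding the niche."""

    radius: float
    frame: CochlearFrame

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be > 0")


def cylinder_radius(frame: CochlearFrame, overhang_tip: np.ndarray) -> float:
    """Radial distance (mm) of the overhang tip from the midmodiolar axis."""
    x, y, _ = world_to_frame(frame, np.asarray(overhang_tip, dtype=float))
    radius = float(np.hypot(x, y))
    if radius < MIN_CYLINDER_RADIUS_MM:
        raise ImplausibleLandmarkError(
            f"overhang tip lies {radius:.3g} mm from the midmodiolar axis "
            f"(< {MIN_CYLINDER_RADIUS_MM} mm); landmark implausible"
        )
    return radius


def radial_distances(mask_or_points, frame: CochlearFrame) -> np.ndarray:
    """Radial distance from the frame z-axis, for points or mask voxels."""
    if isinstance(mask_or_points, LabelMask):
        pts = mask_or_points.foreground_world()
    else:
        pts = np.atleast_2d(np.asarray(mask_or_points, dtype=float))
    fr = world_to_frame(frame, pts)
    return np.hypot(fr[:, 0], fr[:, 1])


def clip_to_cylinder(mask: LabelMask, frame: CochlearFrame, radius: float) -> LabelMask:
    """Keep exactly the foreground voxels whose center is within ``radius``.

    The cylinder is infinite along the frame z-axis.  The result is a
    subset of the input and the operation is idempotent.  An empty
    result is returned with a warning, not an error.
    """
    if radius <= 0:
        raise ValueError("cylinder radius must be > 0")
    idx = mask.foreground_indices()
    if len(idx) == 0:
        return mask.copy_with(np.zeros(mask.grid.shape, dtype=np.uint8))
    keep = radial_distances(mask.grid.index_to_world(idx), frame) <= radius
    out = np.zeros(mask.grid.shape, dtype=np.uint8)
    kept = idx[keep]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    if kept.shape[0] == 0:
        warnings.warn(
            f"cylinder clip (radius {radius:.3g} mm) removed every foreground voxel",
            stacklevel=2,
        )
    return mask.copy_with(out)
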