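"""Cochlea-relative coordinate frame from the three cochlear landmarks.

The frame mirrors the measurement convention used for the niche
morphometrics: the z-axis runs along the midmodiolar axis from the
basal turn toward the apex, the x-axis points radially from that axis
toward the round window, and y completes a right-handed system
(ey = ez x ex).  The origin is the orthogonal projection of the
round-window-membrane landmark onto the midmodiolar axis, which puts
z = 0 at membrane level and makes x the radial direction at the round
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LabelMask, VoxelGrid
from .io_formats import CaseRecord, LandmarkSet

MIN_AXIS_LENGTH_MM = 0.5
MIN_RADIAL_DISTANCE_MM = 0.1


class DegenerateLandmarksError(ValueError):
    """Landmark configuration too degenerate to define the frame."""


@dataclass(frozen=True)
class CochlearFrame:
    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "ex", "ey", "ez"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        basis = np.column_stack([self.ex, self.ey, self.ez])
        if not np.allclose(basis.T @ basis, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.dot(self.ey, np.cross(self.ez, self.ex)) < 0:
            raise ValueError("frame must be right-handed (ey = ez x ex)")

    def rotated_pi_about_ez(self) -> "CochlearFrame":
        """Frame with ex and ey negated (same z axis and origin).

        Used to fix the sign of the y axis for the overhang measurement
        without breaking right-handedness.
        """
        return CochlearFrame(origin=self.origin, ex=-self.ex, ey=-self.ey, ez=self.ez)


def build_frame(landmarks: LandmarkSet) -> CochlearFrame:
    """Construct the frame from apex, basal-turn and RWM landmarks.

    ez = unit(apex - basal); the origin is the projection of the RWM
    point onto the line through basal along ez; ex = unit(rwm - origin);
    ey = ez x ex.
    """
    apex, basal, rwm = landmarks.apex, landmarks.basal, landmarks.rwm_point
    axis = apex - basal
    length = float(np.linalg.norm(axis))
    if length < MIN_AXIS_LENGTH_MM:
        raise DegenerateLandmarksError(
            f"apex-basal distance {length:.3g} mm < {MIN_AXIS_LENGTH_MM} mm: "
            "midmodiolar axis is degenerate"
        )
    ez = axis / length
    origin = basal + np.dot(rwm - basal, ez) * ez
    radial = rwm - origin
    rnorm = float(np.linalg.norm(radial))
    if rnorm < MIN_RADIAL_DISTANCE_MM:
        raise DegenerateLandmarksError(
            f"RWM landmark lies {rnorm:.3g} mm from the midmodiolar axis "
            f"(< {MIN_RADIAL_DISTANCE_MM} mm): collinear landmarks"
        )
    ex = radial / rnorm
    ey = np.cross(ez, ex)
    return CochlearFrame(origin=origin, ex=ex, ey=ey, ez=ez)


def world_to_frame(frame: CochlearFrame, points: np.ndarray) -> np.ndarray:
    """World mm -> frame (x, y, z) mm; accepts a point or an (n, 3) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - frame.origin
    basis = np.column_stack([frame.ex, frame.ey, frame.ez])
    out = pts @ basis
    return out[0] if np.asarray(points).ndim == 1 else out


def frame_to_world(frame: CochlearFrame, points: np.ndarray) -> np.ndarray:
    """Inverse of :func:`world_to_frame`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    basis = np.column_stack([frame.ex, frame.ey, frame.ez])
    out = pts @ basis.T + frame.origin
    return out[0] if np.asarray(points).ndim == 1 else out


# ---------------------------------------------------------------------------
# left-to-right mirroring


def _world_x_axis(grid: VoxelGrid) -> int:
    """Array axis whose direction column is (+/-) world x.

    Mirroring is implemented as a pure array flip (no interpolation), so
    it requires an axis-aligned direction matrix.
    """
    mags = np.abs(grid.direction)
    is_signed_permutation = (
        np.allclose(mags.max(axis=0), 1.0, atol=1e-6)
        and np.allclose(mags.sum(axis=0), 1.0, atol=1e-6)
        and np.allclose(mags.sum(axis=1), 1.0, atol=1e-6)
    )
    if not is_signed_permutation:
        raise ValueError(
            "mirroring requires an axis-aligned (permutation/flip) direction matrix"
        )
    return int(np.argmax(mags[0]))


def mirror_grid(grid: VoxelGrid, plane_x: float | None = None) -> tuple[VoxelGrid, float]:
    """Reflect a grid across the world plane x = plane_x (array flip only).

    Returns the mirrored grid and the plane position used (defaults to
    the world-x center of the volume).
    """
    axis = _world_x_axis(grid)
    n = grid.shape[axis]
    # world x of centers along the flipped axis
    step = grid.direction[0, axis] * grid.spacing[axis]
    x0 = grid.origin[0]
    x_last = x0 + step * (n - 1)
    if plane_x is None:
        plane_x = 0.5 * (x0 + x_last)
    new_origin = np.asarray(grid.origin, dtype=float).copy()
    new_origin[0] = 2.0 * plane_x - x_last
    data = np.flip(grid.data, axis=axis).copy()
    return (
        VoxelGrid(data=data, spacing=grid.spacing, origin=tuple(new_origin), direction=grid.direction),
        float(plane_x),
    )


def mirror_point(point: np.ndarray, plane_x: float) -> np.ndarray:
    out = np.asarray(point, dtype=float).copy()
    out[0] = 2.0 * plane_x - out[0]
    return out


def mirror_case(case: CaseRecord) -> CaseRecord:
    """Mirror a left-sided case to the right across the volume's world-x center.

    Right-sided cases are returned unchanged.  The reflection is a pure
    array-axis flip plus landmark coordinate negation, so all
    morphometric scalars of a mirrored case are bit-identical to the
    original's.
    """
    if case.landmarks.side == "right":
        return case
    return reflect_case(case)


def reflect_case(case: CaseRecord) -> CaseRecord:
    """Unconditionally reflect a case across the volume's world-x center.

    The side label is swapped; applying the reflection twice returns a
    voxel-identical copy of the input (involution).
    """
    volume, plane_x = mirror_grid(case.volume)
    mask_grid, _ = mirror_grid(
        VoxelGrid(
            data=case.mask.data,
            spacing=case.mask.grid.spacing,
            origin=case.mask.grid.origin,
            direction=case.mask.grid.direction,
        ),
        plane_x=plane_x,
    )
    lm = case.landmarks
    landmarks = LandmarkSet(
        apex=mirror_point(lm.apex, plane_x),
        basal=mirror_point(lm.basal, plane_x),
        rwm_point=mirror_point(lm.rwm_point, plane_x),
        overhang_tip=mirror_point(lm.overhang_tip, plane_x),
        side="right" if lm.side == "left" else "left",
    )
    return CaseRecord(
        id=case.id,
        volume=volume,
        mask=LabelMask(data=mask_grid.data, grid=volume),
        landmarks=landmarks,
        age=case.age,
        sex=case.sex,
    )
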