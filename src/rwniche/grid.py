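"""Voxel-grid containers with world (physical, mm) geometry.

Arrays are indexed ``(i, j, k)`` such that the world position of the
*center* of voxel ``(i, j, k)`` is::

    world = origin + direction @ (index * spacing)

i.e. index axis 0 maps to the first column of ``direction``.  With an
identity direction matrix, axis 0 is world x, axis 1 world y, axis 2
world z.  All geometry downstream is computed in world millimetres;
voxel positions always refer to voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """A 3-D scalar intensity image with physical geometry.

    Parameters
    ----------
    data
        3-D array of intensities, index order ``(i, j, k)``.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all > 0.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal direction-cosine matrix; column ``a`` is the
        world direction of increasing index axis ``a``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World mm positions of voxel centers for integer or fractional indices.

        ``indices`` is ``(n, 3)`` (or ``(3,)``); returns the same shape.
        """
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = (idx * np.asarray(self.spacing)) @ self.direction.T + np.asarray(self.origin)
        return pts[0] if np.asarray(indices).ndim == 1 else pts

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world` (fractional indices)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = ((pts - np.asarray(self.origin)) @ self.direction) / np.asarray(self.spacing)
        return idx[0] if np.asarray(points).ndim == 1 else idx

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class LabelMask:
    """Binary segmentation aligned to a :class:`VoxelGrid`.

    ``data`` holds 0/1 (uint8); ``grid`` carries the shared world
    geometry.  The mask's own array shape must equal the grid shape.
    """

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={data.ndim}")
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = (data != 0).astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def foreground_indices(self) -> np.ndarray:
        """Integer ``(n, 3)`` indices of foreground voxels."""
        return np.argwhere(self.data != 0)

    def foreground_world(self) -> np.ndarray:
        """World mm centers of foreground voxels, ``(n, 3)``."""
        return self.grid.index_to_world(self.foreground_indices())

    def copy_with(self, data: np.ndarray) -> "LabelMask":
        return LabelMask(data=data, grid=self.grid)
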