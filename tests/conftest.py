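"""Shared fixtures: phantom cases and constructed interface cavities."""

from __future__ import annotations

import numpy as np
import pytest

from rwniche.grid import LabelMask, VoxelGrid
from rwniche.io_formats import CaseRecord
from rwniche.synthetic_data import generate_phantom, solve_phantom_spec

BONE, SOFT, AIR = 1800.0, 300.0, 0.0

# Cohort summary targets used for default phantoms (per-metric mean).
DEFAULT_TARGETS = dict(vol_mm3=4.54, area_mm2=2.93, oh_mm=0.56, d_mm=1.35)


@pytest.fixture(scope="session")
def default_spec():
    return solve_phantom_spec(**DEFAULT_TARGETS)


@pytest.fixture(scope="session")
def phantom(default_spec):
    """One voxelized default phantom (volume, mask, landmarks, truth)."""
    return generate_phantom(default_spec, seed=11)


@pytest.fixture(scope="session")
def phantom_case(phantom) -> CaseRecord:
    volume, mask, landmarks, _ = phantom
    return CaseRecord(
        id="phantom11", volume=volume, mask=mask, landmarks=landmarks, age=50.0, sex="female"
    )


def build_cavity_case(
    kind: str, h: float = 0.08, tilt_deg: float = 45.0, half_width: float = 0.4
) -> tuple[LabelMask, VoxelGrid, np.ndarray, float]:
    """Construct a bone block with an air cavity over a soft interface.

    ``kind`` selects the interface geometry under the cavity floor:
    ``flat`` (axis-aligned square patch), ``tilt`` (plane tilted by
    ``tilt_deg`` about x) or ``hemi`` (hemispherical bowl, r = 1 mm).
    Returns (mask, grid, st_dir, true membrane area); ``st_dir`` points
    from the soft side up into the cavity, as the fitted scala model
    would report it.
    """
    if kind in ("flat", "tilt"):
        L = half_width
        t = np.tan(np.radians(tilt_deg)) if kind == "tilt" else 0.0
        z_top = L * t + 0.3  # ceiling clear of the tilted plane everywhere
        lo = np.array([-L - 0.6, -L - 0.6, -L * t - 0.9])
        hi = np.array([L + 0.6, L + 0.6, z_top + 0.3])
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / h)) for a in range(3))
        xs, ys, zs = (lo[a] + h / 2 + h * np.arange(shape[a]) for a in range(3))
        X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
        plane = Y * t
        in_patch = (np.abs(X) <= L) & (np.abs(Y) <= L)
        cavity = in_patch & (Z >= plane) & (Z < z_top)
        data = np.full(shape, BONE, dtype=np.float32)
        # slab slightly wider than the cavity so the staircase's edge
        # risers are soft-backed like every interior riser
        in_slab_xy = (np.abs(X) <= L + 0.2) & (np.abs(Y) <= L + 0.2)
        slab = in_slab_xy & (Z >= plane - 0.3) & (Z < plane)
        data[np.broadcast_to(slab, shape)] = SOFT
        data[np.broadcast_to(cavity, shape)] = AIR
        mask = np.broadcast_to(cavity, shape).astype(np.uint8)
        true_area = (2 * L) ** 2 * np.sqrt(1 + t**2)
    elif kind == "hemi":
        r = 1.0
        lo = np.array([-r - 0.6, -r - 0.6, -r - 0.6])
        hi = np.array([r + 0.6, r + 0.6, 0.9])
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / h)) for a in range(3))
        xs, ys, zs = (lo[a] + h / 2 + h * np.arange(shape[a]) for a in range(3))
        X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
        R2 = X**2 + Y**2 + Z**2
        dome = (R2 <= r**2) & (Z < 0)
        column = (X**2 + Y**2 <= r**2) & (Z >= 0) & (Z < 0.7)
        cavity = dome | column
        data = np.full(shape, BONE, dtype=np.float32)
        shell = (R2 > r**2) & (R2 <= (r + 0.3) ** 2) & (Z < 0)
        data[np.broadcast_to(shell, shape)] = SOFT
        data[np.broadcast_to(cavity, shape)] = AIR
        mask = np.broadcast_to(cavity, shape).astype(np.uint8)
        true_area = 2 * np.pi * r**2
    else:  # pragma: no cover
        raise ValueError(kind)
    grid = VoxelGrid(data=data, spacing=(h, h, h), origin=tuple(lo + h / 2))
    st_dir = np.array([0.0, 0.0, 1.0])
    return LabelMask(data=mask, grid=grid), grid, st_dir, float(true_area)


def random_mask_and_grid(rng: np.random.Generator, shape=(20, 20, 20), p=0.3,
                         spacing=(0.1, 0.12, 0.08)) -> LabelMask:
    grid = VoxelGrid(
        data=np.zeros(shape, dtype=np.float32),
        spacing=spacing,
        origin=tuple(rng.uniform(-1, 1, 3)),
    )
    return LabelMask(data=(rng.random(shape) < p).astype(np.uint8), grid=grid)
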