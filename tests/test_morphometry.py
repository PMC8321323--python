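"""Per-case metrics: volume, depth, overhang, membrane interface and area."""

import numpy as np
import pytest

from rwniche.cochlear_frame import build_frame, frame_to_world, world_to_frame
from rwniche.grid import LabelMask, VoxelGrid
from rwniche.io_formats import CaseRecord, LandmarkSet
from rwniche.morphometry import (
    AmbiguousMembraneError,
    EmptyMaskError,
    FACE_BONE,
    FACE_SOFT,
    NoMembraneError,
    boundary_faces,
    compute_area,
    compute_depth,
    compute_overhang,
    compute_volume,
    extract_rwm_interface,
    orient_frame_for_overhang,
    run_morphometry,
)
from rwniche.synthetic_data import generate_phantom, solve_phantom_spec
from conftest import BONE, SOFT, AIR, build_cavity_case, DEFAULT_TARGETS

Z_FRAME = build_frame(
    LandmarkSet(apex=(0, 0, 10), basal=(0, 0, 0), rwm_point=(5, 0, 0), overhang_tip=(4, 1, 1))
)


def _mask_from_points(points, spacing=0.08, pad=3):
    """Small mask with foreground voxels at the given world points (on-grid)."""
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0) - pad * spacing
    shape = tuple(int(np.ceil((pts.max(axis=0)[a] - lo[a]) / spacing)) + pad for a in range(3))
    grid = VoxelGrid(np.zeros(shape, dtype=np.float32), spacing=(spacing,) * 3,
                     origin=tuple(lo + spacing / 2))
    data = np.zeros(shape, dtype=np.uint8)
    idx = np.rint(grid.world_to_index(pts)).astype(int)
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return LabelMask(data=data, grid=grid)


# ---------------------------------------------------------------------------
# volume


def test_volume_is_count_times_voxel_volume():
    rng = np.random.default_rng(0)
    data = (rng.random((10, 12, 14)) < 0.4).astype(np.uint8)
    grid = VoxelGrid(np.zeros_like(data, dtype=np.float32), spacing=(0.08, 0.08, 0.08))
    mask = LabelMask(data=data, grid=grid)
    assert compute_volume(mask) == pytest.approx(data.sum() * 0.08**3, rel=1e-12)


def test_thousand_voxels_at_standard_spacing():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data.flat[:1000] = 1
    grid = VoxelGrid(np.zeros_like(data, dtype=np.float32), spacing=(0.08, 0.08, 0.08))
    assert compute_volume(LabelMask(data=data, grid=grid)) == pytest.approx(0.512)


def test_empty_mask_errors():
    grid = VoxelGrid(np.zeros((4, 4, 4), dtype=np.float32), spacing=(0.1, 0.1, 0.1))
    empty = LabelMask(data=np.zeros((4, 4, 4), dtype=np.uint8), grid=grid)
    for fn in (compute_volume, lambda m: compute_depth(m, Z_FRAME)):
        with pytest.raises(EmptyMaskError):
            fn(empty)


def test_digitized_sphere_volume_converges():
    """Voxelized r = 1 mm sphere at 0.02 mm spacing is within 1% of 4 pi / 3."""
    h = 0.02
    n = int(np.ceil(2.2 / h))
    ax = (np.arange(n) - (n - 1) / 2) * h
    inside = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2) <= 1.0
    grid = VoxelGrid(np.zeros(inside.shape, dtype=np.uint8), spacing=(h, h, h))
    vol = compute_volume(LabelMask(data=inside.astype(np.uint8), grid=grid))
    assert vol == pytest.approx(4 * np.pi / 3, rel=0.01)


# ---------------------------------------------------------------------------
# depth


def test_depth_is_center_extent_along_frame_z():
    pts = [(5, 0, 0.10), (5.08, 0, 0.74), (5, 0.08, 1.45)]
    mask = _mask_from_points(pts)
    # grid snapping: recompute what the centers actually are
    z = world_to_frame(Z_FRAME, mask.foreground_world())[:, 2]
    assert compute_depth(mask, Z_FRAME) == pytest.approx(z.max() - z.min(), abs=1e-12)
    assert compute_depth(mask, Z_FRAME) == pytest.approx(1.35, abs=0.09)


def test_single_voxel_has_zero_depth():
    mask = _mask_from_points([(5, 0, 1.0)])
    assert compute_depth(mask, Z_FRAME) == 0.0


def test_depth_equivariant_under_rigid_rotation():
    """Rotating mask geometry and landmarks together leaves depth unchanged."""
    from scipy.spatial.transform import Rotation

    pts = [(5, 0, 0.1), (5.4, 0.2, 0.9), (4.8, -0.3, 1.3)]
    mask = _mask_from_points(pts)
    depth0 = compute_depth(mask, Z_FRAME)
    rot = Rotation.random(random_state=3).as_matrix()
    rotated_grid = VoxelGrid(
        data=mask.grid.data, spacing=mask.grid.spacing,
        origin=rot @ np.asarray(mask.grid.origin),
        direction=rot @ mask.grid.direction,
    )
    rotated_mask = LabelMask(data=mask.data, grid=rotated_grid)
    rotated_frame = build_frame(
        LandmarkSet(apex=rot @ np.array([0, 0, 10.0]), basal=rot @ np.zeros(3),
                    rwm_point=rot @ np.array([5.0, 0, 0]), overhang_tip=rot @ np.array([4.0, 1, 1]))
    )
    assert compute_depth(rotated_mask, rotated_frame) == pytest.approx(depth0, abs=1e-9)


# ---------------------------------------------------------------------------
# overhang


def test_overhang_constructed_example():
    """Tip at frame-y 0.30, furthest foreground center at 0.86 -> oh = 0.56."""
    ys = [-0.50, -0.20, 0.10, 0.86]
    pts = [frame_to_world(Z_FRAME, np.array([5.0, y, 0.5])) for y in ys]
    mask = _mask_from_points(pts)
    tip = frame_to_world(Z_FRAME, np.array([4.0, 0.30, 1.0]))
    oriented, flipped = orient_frame_for_overhang(Z_FRAME, mask, tip)
    assert not flipped  # tip sits on the +y side of the centroid already
    assert compute_overhang(mask, oriented, tip) == pytest.approx(0.56, abs=0.09)


def test_overhang_clamps_at_zero():
    pts = [frame_to_world(Z_FRAME, np.array([5.0, y, 0.5])) for y in (-0.3, -0.1, 0.0)]
    mask = _mask_from_points(pts)
    tip = frame_to_world(Z_FRAME, np.array([4.0, 1.5, 1.0]))
    oriented, _ = orient_frame_for_overhang(Z_FRAME, mask, tip)
    assert compute_overhang(mask, oriented, tip) == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_overhang_matches_brute_force_max(seed):
    rng = np.random.default_rng(seed)
    pts = [frame_to_world(Z_FRAME, np.array([5.0, 0, 0.5]) + rng.normal(size=3))
           for _ in range(15)]
    mask = _mask_from_points(pts)
    tip = frame_to_world(Z_FRAME, np.array([4.0, 0.2, 1.0]))
    oriented, _ = orient_frame_for_overhang(Z_FRAME, mask, tip)
    got = compute_overhang(mask, oriented, tip)
    tip_y = world_to_frame(oriented, tip)[1]
    best = max(
        world_to_frame(oriented, mask.grid.index_to_world(idx))[1] - tip_y
        for idx in mask.foreground_indices()
    )
    assert got == pytest.approx(max(0.0, best), abs=1e-12)


def test_orientation_flip_when_tip_is_on_minus_y_side():
    pts = [frame_to_world(Z_FRAME, np.array([5.0, y, 0.5])) for y in (0.0, 0.2, 0.4)]
    mask = _mask_from_points(pts)
    tip = frame_to_world(Z_FRAME, np.array([4.0, -0.1, 1.0]))
    oriented, flipped = orient_frame_for_overhang(Z_FRAME, mask, tip)
    assert flipped
    # after the flip the tip is on the +y side and oh is small, not ~full width
    assert compute_overhang(mask, oriented, tip) < 0.6


# ---------------------------------------------------------------------------
# interface extraction and area


def test_cubic_cavity_face_classification_counts():
    """Open-top cube: bone walls, soft floor; classified counts match construction."""
    h = 0.08
    n = 30
    data = np.full((n, n, n), BONE, dtype=np.float32)
    cav = np.zeros((n, n, n), dtype=bool)
    cav[10:20, 10:20, 10:20] = True
    data[cav] = AIR
    data[10:20, 10:20, 20:] = AIR      # open top column (air above)
    data[10:20, 10:20, 5:10] = SOFT    # soft slab below the floor
    grid = VoxelGrid(data, spacing=(h, h, h))
    mask = LabelMask(data=cav.astype(np.uint8), grid=grid)
    surface = extract_rwm_interface(mask, grid, st_dir=np.array([0.0, 0.2, 0.98]),
                                    bone_threshold=1000.0)
    counts = surface.class_counts()
    assert counts["bone_contact"] == 4 * 100   # four side walls
    assert counts["soft"] == 100 + 100         # floor (soft below) + open top (air above)
    # the membrane is the floor: 100 faces facing -z
    assert int(surface.is_rwm.sum()) == 100
    rwm_normals = surface.normals[surface.is_rwm]
    np.testing.assert_allclose(rwm_normals, np.tile([0, 0, -1.0], (100, 1)))
    assert compute_area(surface, "face_count") == pytest.approx(100 * h * h, rel=1e-12)


def test_threshold_above_everything_falls_back_to_soft_with_warning():
    mask, grid, st_dir, _ = build_cavity_case("flat")
    with pytest.warns(UserWarning, match="no boundary face classified as bone"):
        surface = extract_rwm_interface(mask, grid, st_dir, bone_threshold=1e9)
    assert int((surface.classes == FACE_BONE).sum()) == 0
    assert np.any(surface.is_rwm)


def test_fully_enclosed_cavity_has_no_membrane():
    h = 0.08
    data = np.full((20, 20, 20), BONE, dtype=np.float32)
    cav = np.zeros((20, 20, 20), dtype=bool)
    cav[5:15, 5:15, 5:15] = True
    data[cav] = AIR
    grid = VoxelGrid(data, spacing=(h, h, h))
    mask = LabelMask(data=cav.astype(np.uint8), grid=grid)
    with pytest.raises(NoMembraneError):
        extract_rwm_interface(mask, grid, st_dir=np.array([0, 0, 1.0]), bone_threshold=1000.0)


def test_two_equal_membrane_candidates_raise_ambiguity():
    """Two identical soft floor patches separated by a bone strip."""
    h = 0.08
    n = 40
    data = np.full((n, n, n), BONE, dtype=np.float32)
    cav = np.zeros((n, n, n), dtype=bool)
    cav[5:35, 5:35, 10:20] = True
    data[cav] = AIR
    data[5:35, 5:35, 20:] = AIR
    data[8:16, 8:32, 5:10] = SOFT   # patch 1 below the floor
    data[24:32, 8:32, 5:10] = SOFT  # patch 2, same size
    grid = VoxelGrid(data, spacing=(h, h, h))
    mask = LabelMask(data=cav.astype(np.uint8), grid=grid)
    with pytest.raises(AmbiguousMembraneError, match="similar size"):
        extract_rwm_interface(mask, grid, st_dir=np.array([0.0, 0.1, 0.99]),
                              bone_threshold=1000.0)


def test_flat_patch_area_estimators():
    mask, grid, st_dir, truth = build_cavity_case("flat")
    surface = extract_rwm_interface(mask, grid, st_dir)
    assert compute_area(surface, "face_count") == pytest.approx(truth, rel=1e-6)
    assert compute_area(surface, "corrected") == pytest.approx(truth, rel=0.02)


def test_tilted_plane_area_estimators():
    """45 degree plane: face counting overestimates by sqrt(2); corrected stays close."""
    mask, grid, st_dir, truth = build_cavity_case("tilt", tilt_deg=45.0, half_width=0.8)
    surface = extract_rwm_interface(mask, grid, st_dir)
    ratio = compute_area(surface, "face_count") / truth
    assert ratio == pytest.approx(np.sqrt(2), rel=0.03)
    assert compute_area(surface, "corrected") == pytest.approx(truth, rel=0.05)


def test_hemisphere_area_estimator():
    mask, grid, st_dir, truth = build_cavity_case("hemi")
    surface = extract_rwm_interface(mask, grid, st_dir)
    assert compute_area(surface, "corrected") == pytest.approx(truth, rel=0.03)
    # face counting upper-bounds the corrected estimate on curved patches
    assert compute_area(surface, "face_count") >= compute_area(surface, "corrected")


def test_boundary_faces_separate_foreground_from_background():
    rng = np.random.default_rng(9)
    data = (rng.random((12, 12, 12)) < 0.5).astype(np.uint8)
    grid = VoxelGrid(np.zeros_like(data, dtype=np.float32), spacing=(0.1, 0.1, 0.1))
    mask = LabelMask(data=data, grid=grid)
    owner, axis, sign = boundary_faces(mask)
    assert np.all(mask.data[owner[:, 0], owner[:, 1], owner[:, 2]] == 1)
    neighbor = owner.copy()
    neighbor[np.arange(len(owner)), axis] += sign
    inb = np.all((neighbor >= 0) & (neighbor < 12), axis=1)
    nb = neighbor[inb]
    assert np.all(mask.data[nb[:, 0], nb[:, 1], nb[:, 2]] == 0)
    # total face count equals the brute-force sum over the 6 neighbourhoods
    padded = np.pad(data, 1)
    brute = 0
    for shift_axis in range(3):
        for s in (1, -1):
            rolled = np.roll(padded, -s, axis=shift_axis)
            brute += int((padded & ~rolled.astype(bool)).sum())
    assert len(owner) == brute


# ---------------------------------------------------------------------------
# end-to-end


def test_run_morphometry_recovers_phantom(phantom_case, phantom):
    _, _, _, truth = phantom
    res = run_morphometry(phantom_case)
    assert res.vol_mm3 == pytest.approx(truth.vol_mm3, rel=0.02)
    assert res.area_mm2 == pytest.approx(truth.area_mm2, rel=0.05)
    assert res.oh_mm == pytest.approx(truth.oh_mm, abs=0.08)
    assert res.d_mm == pytest.approx(truth.d_mm, abs=0.08)
    assert res.n_voxels * phantom_case.mask.grid.voxel_volume == pytest.approx(res.vol_mm3)
    assert res.provenance["face_class_counts"]["bone_contact"] > 0


def test_zero_overhang_phantom_measures_at_most_one_voxel():
    spec = solve_phantom_spec(
        DEFAULT_TARGETS["vol_mm3"], DEFAULT_TARGETS["area_mm2"], 0.0,
        DEFAULT_TARGETS["d_mm"], include_cochlea=False,
    )
    volume, mask, landmarks, truth = generate_phantom(spec, seed=4)
    case = CaseRecord(id="oh0", volume=volume, mask=mask, landmarks=landmarks,
                      age=40.0, sex="male")
    res = run_morphometry(case)
    assert truth.oh_mm <= 0.02
    assert res.oh_mm <= 0.08


def test_stage_errors_carry_stage_names(phantom_case):
    from dataclasses import replace
    from rwniche.morphometry import PipelineStageError

    axis = phantom_case.landmarks.apex - phantom_case.landmarks.basal
    axis = axis / np.linalg.norm(axis)
    bad_landmarks = phantom_case.landmarks.replace(
        rwm_point=phantom_case.landmarks.basal + axis  # on the midmodiolar axis
    )
    bad = CaseRecord(id="bad", volume=phantom_case.volume, mask=phantom_case.mask,
                     landmarks=bad_landmarks, age=1.0, sex="male")
    with pytest.raises(PipelineStageError, match=r"\[build_frame\]"):
        run_morphometry(bad)
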