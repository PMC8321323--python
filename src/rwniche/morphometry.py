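"""Per-case niche morphometrics: volume, depth, overhang, membrane area.

The four quantities reported per case are

* ``Vol`` - niche volume: foreground voxel count times voxel volume of
  the cylinder-clipped segmentation (mm^3);
* ``d``   - niche depth: extent of foreground voxel centers along the
  frame z-axis (max - min, mm), i.e. from membrane level toward the
  bony overhang;
* ``oh``  - bony-overhang length: how far the niche cavity continues
  past the overhang-tip landmark along the frame y-axis, clamped at
  zero (mm);
* ``A``   - round-window-membrane area: area of the scala-facing soft
  component of the mask's boundary-face surface (mm^2), estimated
  either from a smoothed triangle mesh (default) or by raw voxel-face
  counting (oracle estimator, overestimates oblique planes).

Membrane extraction classifies every inter-voxel boundary face of the
clipped mask by what lies on its background side: bone (intensity at or
above a threshold), the open mouth of the niche (outside the clip
cylinder), or soft tissue.  The membrane is the largest edge-connected
soft component whose area-weighted mean outward normal faces the scala
tympani, as oriented by the fitted spiral model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .cochlear_frame import CochlearFrame, build_frame, mirror_case, world_to_frame
from .grid import LabelMask, VoxelGrid
from .io_formats import CaseRecord
from .niche_boundary import clip_to_cylinder, cylinder_radius, radial_distances
from .scala_model import fit_scala, st_entrance_direction

FACE_BONE = 0
FACE_SOFT = 1
FACE_MOUTH = 2
_CLASS_NAMES = {FACE_BONE: "bone_contact", FACE_SOFT: "soft", FACE_MOUTH: "mouth"}


class EmptyMaskError(ValueError):
    pass


class NoMembraneError(RuntimeError):
    """No soft boundary face, or none facing the scala tympani."""


class AmbiguousMembraneError(RuntimeError):
    """Two near-equal scala-facing soft components; refusing to guess."""


class PipelineStageError(RuntimeError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# scalar metrics


def compute_volume(mask: LabelMask) -> float:
    """Foreground voxel count times voxel volume (mm^3)."""
    n = mask.n_foreground
    if n == 0:
        raise EmptyMaskError("cannot compute volume of an empty mask")
    return n * mask.grid.voxel_volume


def compute_depth(mask: LabelMask, frame: CochlearFrame) -> float:
    """Extent (max - min) of foreground voxel centers along frame z (mm).

    Center-extent convention: a one-voxel-thick slab has depth 0.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("cannot compute depth of an empty mask")
    z = world_to_frame(frame, mask.foreground_world())[:, 2]
    return float(z.max() - z.min())


def orient_frame_for_overhang(
    frame: CochlearFrame, mask: LabelMask, overhang_tip: np.ndarray
) -> tuple[CochlearFrame, bool]:
    """Fix the sign of the y-axis for the overhang measurement.

    The overhang shelf is attached to the niche wall nearest the tip, so
    +y is oriented to point from the mask centroid toward the tip: if
    the tip's frame-y coordinate is below the centroid's, the frame is
    rotated half a turn about its z-axis (x and y both negated, staying
    right-handed).  Returns (frame, flipped).
    """
    centroid = mask.foreground_world().mean(axis=0)
    tip_y = world_to_frame(frame, np.asarray(overhang_tip, dtype=float))[1]
    centroid_y = world_to_frame(frame, centroid)[1]
    if tip_y < centroid_y:
        return frame.rotated_pi_about_ez(), True
    return frame, False


def compute_overhang(
    mask: LabelMask, frame: CochlearFrame, overhang_tip: np.ndarray
) -> float:
    """Overhang length: cavity extent past the tip along +y, clamped at 0 (mm).

    The frame passed in is assumed already oriented (see
    :func:`orient_frame_for_overhang`); ``run_morphometry`` handles the
    orientation and records whether the y-axis was flipped.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("cannot compute overhang of an empty mask")
    y = world_to_frame(frame, mask.foreground_world())[:, 1]
    tip_y = world_to_frame(frame, np.asarray(overhang_tip, dtype=float))[1]
    return float(max(0.0, y.max() - tip_y))


# ---------------------------------------------------------------------------
# membrane interface


@dataclass
class InterfaceSurface:
    """Classified boundary faces of the clipped mask, plus the RWM mesh.

    Every face separates exactly one foreground and one background
    voxel.  ``owner`` is the foreground voxel index, ``axis``/``sign``
    the face direction, ``centers``/``normals`` world mm geometry,
    ``areas`` the raw face areas and ``classes`` one of
    ``FACE_BONE``/``FACE_SOFT``/``FACE_MOUTH``.  Soft faces carry an
    edge-connectivity component id in ``component`` (-1 elsewhere);
    ``rwm_component`` marks the component classified as the membrane.
    """

    owner: np.ndarray
    axis: np.ndarray
    sign: np.ndarray
    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    classes: np.ndarray
    component: np.ndarray
    rwm_component: int
    mesh_vertices: np.ndarray
    mesh_faces: np.ndarray
    threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def is_rwm(self) -> np.ndarray:
        return (self.classes == FACE_SOFT) & (self.component == self.rwm_component)

    @property
    def rwm_face_area(self) -> float:
        return float(self.areas[self.is_rwm].sum())

    @property
    def rwm_mesh_area(self) -> float:
        if len(self.mesh_faces) == 0:
            return 0.0
        v = self.mesh_vertices
        tri = v[self.mesh_faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def rwm_corrected_area(self, radius_factor: float = 4.0) -> float:
        """Normal-corrected membrane area (projection identity).

        Each membrane face contributes its raw area times the cosine
        between its axis-aligned normal and a locally estimated surface
        normal; for a digitized plane the staircase projects exactly
        onto the plane, so the sum recovers the true area for any
        orientation.  Local normals come from an area-weighted PCA
        plane fit over the membrane component's own faces within
        ``radius_factor`` voxels, so adjacent bone walls cannot skew
        them.
        """
        sel = self.is_rwm
        if not np.any(sel):
            return 0.0
        centers = self.centers[sel]
        normals = self.normals[sel]
        areas = self.areas[sel]
        radius = radius_factor * float(np.sqrt(areas.max()))
        tree = cKDTree(centers)
        neighbor_lists = tree.query_ball_point(centers, r=radius)
        total = 0.0
        for i, nb in enumerate(neighbor_lists):
            pts = centers[nb]
            w = areas[nb]
            mu = (pts * w[:, None]).sum(axis=0) / w.sum()
            d = (pts - mu) * np.sqrt(w)[:, None]
            if len(nb) < 3:
                total += areas[i]
                continue
            _, _, vt = np.linalg.svd(d, full_matrices=False)
            n = vt[-1]
            total += areas[i] * abs(float(np.dot(normals[i], n)))
        return float(total)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int((self.classes == code).sum()) for code, name in _CLASS_NAMES.items()
        }


def boundary_faces(mask: LabelMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate 6-connectivity boundary faces of a mask.

    Returns ``(owner, axis, sign)`` arrays: the foreground voxel owning
    each face, the array axis the face is perpendicular to, and the
    direction (+1/-1) of its background neighbor.  Faces at the array
    border count as boundary faces.
    """
    fg = mask.data.astype(bool)
    owners, axes, signs = [], [], []
    for axis in range(3):
        for sign in (+1, -1):
            shifted = np.zeros_like(fg)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign > 0:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            shifted[tuple(dst)] = fg[tuple(src)]
            face = fg & ~shifted
            idx = np.argwhere(face)
            owners.append(idx)
            axes.append(np.full(len(idx), axis, dtype=np.int8))
            signs.append(np.full(len(idx), sign, dtype=np.int8))
    return np.concatenate(owners), np.concatenate(axes), np.concatenate(signs)


def auto_bone_threshold(mask: LabelMask, grid: VoxelGrid, shell_voxels: int = 2) -> float:
    """Otsu's threshold on the intensities in a shell around the mask.

    CBCT intensities are not HU-calibrated, so a fixed number is not
    defensible; the threshold is recomputed per case from a 2-voxel
    6-connectivity dilation shell.
    """
    from skimage.filters import threshold_otsu

    fg = mask.data.astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)
    dilated = ndimage.binary_dilation(fg, structure=structure, iterations=shell_voxels)
    shell = dilated & ~fg
    values = np.asarray(grid.data)[shell]
    if values.size == 0:
        raise ValueError("mask has no surrounding shell to estimate a bone threshold from")
    if np.ptp(values) == 0:
        raise ValueError("shell intensities are constant; cannot estimate a bone threshold")
    return float(threshold_otsu(values))


def _face_components(owner: np.ndarray, axis: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Label faces by shared-edge connectivity (union-find over edges)."""
    n = len(owner)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    edge_map: dict[tuple, int] = {}
    for f in range(n):
        i, j, k = (int(v) for v in owner[f])
        a = int(axis[f])
        s = int(sign[f])
        # face corners on the doubled-integer lattice
        base = np.array([2 * i, 2 * j, 2 * k])
        base[a] += s
        others = [b for b in range(3) if b != a]
        corners = []
        for da in (-1, 1):
            for db in (-1, 1):
                c = base.copy()
                c[others[0]] += da
                c[others[1]] += db
                corners.append(tuple(c))
        # 4 edges: corner pairs differing in exactly one in-plane axis
        edges = [
            (corners[0], corners[1]),
            (corners[0], corners[2]),
            (corners[1], corners[3]),
            (corners[2], corners[3]),
        ]
        for e in edges:
            key = e if e[0] <= e[1] else (e[1], e[0])
            other = edge_map.get(key)
            if other is None:
                edge_map[key] = f
            else:
                union(other, f)
    labels = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
    # relabel densely
    _, dense = np.unique(labels, return_inverse=True)
    return dense


def extract_rwm_interface(
    mask: LabelMask,
    grid: VoxelGrid,
    st_dir: np.ndarray,
    bone_threshold: float | str = "auto",
    frame: CochlearFrame | None = None,
    clip_radius: float | None = None,
    ambiguity_ratio: float = 0.9,
    smoothing_sigma: float = 1.0,
) -> InterfaceSurface:
    """Classify boundary faces and extract the membrane surface.

    Faces are classified *bone_contact* if the background neighbor's
    intensity is at or above ``bone_threshold`` (``"auto"`` = Otsu on a
    2-voxel shell), *mouth* if the background neighbor center lies
    outside the clip cylinder (when ``frame`` and ``clip_radius`` are
    given), else *soft*.  The membrane is the largest edge-connected
    soft component whose area-weighted mean outward normal has positive
    dot product with ``-st_dir``; its triangle mesh is extracted by
    marching cubes on a Gaussian-smoothed crop of the mask, keeping the
    triangles whose nearest boundary face belongs to that component.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("cannot extract an interface from an empty mask")
    st_dir = np.asarray(st_dir, dtype=float)
    st_dir = st_dir / np.linalg.norm(st_dir)
    warn_list: list[str] = []

    if bone_threshold == "auto":
        threshold = auto_bone_threshold(mask, grid)
    else:
        threshold = float(bone_threshold)

    owner, axis, sign = boundary_faces(mask)
    n = len(owner)
    spacing = np.asarray(mask.grid.spacing)

    neighbor = owner.copy()
    neighbor[np.arange(n), axis] += sign
    in_bounds = np.all((neighbor >= 0) & (neighbor < np.asarray(mask.grid.shape)), axis=1)
    neighbor_intensity = np.full(n, -np.inf)
    nb = neighbor[in_bounds]
    neighbor_intensity[in_bounds] = np.asarray(grid.data, dtype=float)[
        nb[:, 0], nb[:, 1], nb[:, 2]
    ]

    # world geometry of the faces
    owner_world = mask.grid.index_to_world(owner)
    normals = (sign[:, None] * mask.grid.direction[:, axis].T).astype(float)
    centers = owner_world + 0.5 * spacing[axis][:, None] * normals
    other = np.array([[1, 2], [0, 2], [0, 1]])
    areas = spacing[other[axis][:, 0]] * spacing[other[axis][:, 1]]

    classes = np.full(n, FACE_SOFT, dtype=np.int8)
    classes[neighbor_intensity >= threshold] = FACE_BONE
    if frame is not None and clip_radius is not None:
        neighbor_world = mask.grid.index_to_world(neighbor.astype(float))
        outside = radial_distances(neighbor_world, frame) > clip_radius
        classes[(classes != FACE_BONE) & outside] = FACE_MOUTH

    if not np.any(classes == FACE_BONE):
        warn_list.append(
            "no boundary face classified as bone contact; treating all non-mouth faces as soft"
        )
        warnings.warn(warn_list[-1], stacklevel=2)

    soft_idx = np.flatnonzero(classes == FACE_SOFT)
    if soft_idx.size == 0:
        raise NoMembraneError("no soft boundary face: the niche appears fully bone-enclosed")

    component = np.full(n, -1, dtype=np.int64)
    component[soft_idx] = _face_components(owner[soft_idx], axis[soft_idx], sign[soft_idx])

    # candidate components facing the scala
    comp_ids = np.unique(component[soft_idx])
    comp_area = {}
    comp_facing = {}
    for cid in comp_ids:
        sel = component == cid
        area = float(areas[sel].sum())
        mean_normal = (normals[sel] * areas[sel][:, None]).sum(axis=0)
        norm = np.linalg.norm(mean_normal)
        facing = norm > 0 and float(np.dot(mean_normal / norm, -st_dir)) > 0
        comp_area[cid] = area
        comp_facing[cid] = facing
    candidates = [cid for cid in comp_ids if comp_facing[cid]]
    if not candidates:
        if not np.any(classes == FACE_BONE):
            # all-soft fallback: a closed all-soft boundary has a near-zero
            # mean normal, so the facing test is uninformative; take the
            # largest component and say so
            warn_list.append(
                "no component passes the scala-facing test in all-soft fallback; "
                "using the largest soft component"
            )
            warnings.warn(warn_list[-1], stacklevel=2)
            candidates = list(comp_ids)
        else:
            raise NoMembraneError(
                "no soft boundary component faces the scala tympani; "
                "cannot identify the membrane"
            )
    candidates.sort(key=lambda cid: -comp_area[cid])
    if len(candidates) > 1 and comp_area[candidates[1]] >= ambiguity_ratio * comp_area[candidates[0]]:
        raise AmbiguousMembraneError(
            "two scala-facing soft components of similar size: "
            f"{comp_area[candidates[0]]:.3f} mm^2 vs {comp_area[candidates[1]]:.3f} mm^2"
        )
    rwm_component = int(candidates[0])

    mesh_vertices, mesh_faces = _rwm_mesh(
        mask, owner, classes, component, rwm_component, centers, smoothing_sigma
    )
    return InterfaceSurface(
        owner=owner,
        axis=axis,
        sign=sign,
        centers=centers,
        normals=normals,
        areas=areas,
        classes=classes,
        component=component,
        rwm_component=rwm_component,
        mesh_vertices=mesh_vertices,
        mesh_faces=mesh_faces,
        threshold=threshold,
        warnings=warn_list,
    )


def _rwm_mesh(
    mask: LabelMask,
    owner: np.ndarray,
    classes: np.ndarray,
    component: np.ndarray,
    rwm_component: int,
    centers: np.ndarray,
    smoothing_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes mesh of the membrane patch (world mm).

    The binary mask is cropped around the membrane's owner voxels,
    smoothed with a Gaussian (sigma in voxels), contoured at 0.5, and
    each triangle is kept iff its centroid's nearest boundary face (of
    any class) belongs to the membrane component and is within 1.5
    voxels.
    """
    from skimage.measure import marching_cubes

    is_rwm = (classes == FACE_SOFT) & (component == rwm_component)
    rwm_owners = owner[is_rwm]
    pad = max(4, int(np.ceil(3 * smoothing_sigma)) + 2)
    lo = np.maximum(rwm_owners.min(axis=0) - pad, 0)
    hi = np.minimum(rwm_owners.max(axis=0) + pad + 1, np.asarray(mask.grid.shape))
    sub = mask.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
    if min(sub.shape) < 2:
        return np.zeros((0, 3)), np.zeros((0, 3), dtype=int)
    smoothed = ndimage.gaussian_filter(sub, sigma=smoothing_sigma)
    if smoothed.max() <= 0.5 or smoothed.min() >= 0.5:
        return np.zeros((0, 3)), np.zeros((0, 3), dtype=int)
    spacing = mask.grid.spacing
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=spacing)
    verts_idx = verts / np.asarray(spacing) + lo
    verts_world = mask.grid.index_to_world(verts_idx)
    tri_centroids = verts_world[faces].mean(axis=1)

    tree = cKDTree(centers)
    dist, nearest = tree.query(tri_centroids)
    keep = is_rwm[nearest] & (dist <= 1.5 * max(spacing))
    kept_faces = faces[keep]
    used = np.unique(kept_faces)
    remap = np.full(len(verts_world), -1, dtype=int)
    remap[used] = np.arange(len(used))
    return verts_world[used], remap[kept_faces]


def compute_area(surface: InterfaceSurface, estimator: str = "corrected") -> float:
    """Membrane area (mm^2) by the chosen estimator.

    ``corrected`` (default) is the normal-corrected face sum, which is
    exact for digitized planes of any orientation; ``mesh`` sums
    triangle areas of the smoothed marching-cubes membrane patch (it
    under-reports near concave wall junctions by roughly the smoothing
    width times the patch perimeter); ``face_count`` sums raw
    voxel-face areas, which is exact for axis-aligned patches but
    overestimates oblique planes by up to sqrt(3).
    """
    if not np.any(surface.is_rwm):
        raise NoMembraneError("interface surface has an empty membrane component")
    if estimator == "corrected":
        return surface.rwm_corrected_area()
    if estimator == "mesh":
        area = surface.rwm_mesh_area
        if area == 0.0:
            raise NoMembraneError("membrane mesh is empty")
        return area
    if estimator == "face_count":
        return surface.rwm_face_area
    raise ValueError(f"unknown area estimator {estimator!r}")


# ---------------------------------------------------------------------------
# end-to-end per-case pipeline


@dataclass
class NicheMorphometry:
    """Per-case result: the four scalars plus provenance."""

    vol_mm3: float
    area_mm2: float
    oh_mm: float
    d_mm: float
    n_voxels: int
    cylinder_radius_mm: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "vol_mm3": self.vol_mm3,
            "area_mm2": self.area_mm2,
            "oh_mm": self.oh_mm,
            "d_mm": self.d_mm,
            "n_voxels": self.n_voxels,
            "cylinder_radius_mm": self.cylinder_radius_mm,
            "provenance": self.provenance,
        }


def run_morphometry(case: CaseRecord, config=None) -> NicheMorphometry:
    """Run the full per-case pipeline.

    Stages: mirror left cases to the right, build the cochlear frame,
    fit the spiral model, derive the tip cylinder, clip the mask,
    measure volume/depth/overhang, extract the membrane interface and
    measure its area.  Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    case = stage("mirror_case", mirror_case, case)
    frame = stage("build_frame", build_frame, case.landmarks)
    scala = stage(
        "fit_scala", fit_scala, case.landmarks, cfg.spiral_params
    )
    st_dir = st_entrance_direction(scala)
    radius = stage("cylinder_radius", cylinder_radius, frame, case.landmarks.overhang_tip)
    clipped = stage("clip_to_cylinder", clip_to_cylinder, case.mask, frame, radius)
    vol = stage("compute_volume", compute_volume, clipped)
    depth = stage("compute_depth", compute_depth, clipped, frame)
    oriented, y_flipped = stage(
        "orient_frame", orient_frame_for_overhang, frame, clipped, case.landmarks.overhang_tip
    )
    oh = stage("compute_overhang", compute_overhang, clipped, oriented, case.landmarks.overhang_tip)
    surface = stage(
        "extract_rwm_interface",
        extract_rwm_interface,
        clipped,
        case.volume,
        st_dir,
        bone_threshold=cfg.bone_threshold,
        frame=frame,
        clip_radius=radius,
        smoothing_sigma=cfg.smoothing_sigma,
    )
    area = stage("compute_area", compute_area, surface, cfg.area_estimator)
    provenance = {
        "case_id": case.id,
        "side_after_mirror": case.landmarks.side,
        "frame_origin": [float(v) for v in oriented.origin],
        "frame_ex": [float(v) for v in oriented.ex],
        "frame_ey": [float(v) for v in oriented.ey],
        "frame_ez": [float(v) for v in oriented.ez],
        "y_flipped_for_overhang": bool(y_flipped),
        "bone_threshold": surface.threshold,
        "st_direction": [float(v) for v in st_dir],
        "area_estimator": cfg.area_estimator,
        "area_corrected_mm2": surface.rwm_corrected_area(),
        "area_mesh_mm2": surface.rwm_mesh_area,
        "area_face_count_mm2": surface.rwm_face_area,
        "face_class_counts": surface.class_counts(),
        "warnings": list(surface.warnings),
    }
    return NicheMorphometry(
        vol_mm3=vol,
        area_mm2=area,
        oh_mm=oh,
        d_mm=depth,
        n_voxels=clipped.n_foreground,
        cylinder_radius_mm=radius,
        provenance=provenance,
    )
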