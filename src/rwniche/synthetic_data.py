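"""Synthetic temporal-bone phantoms with known ground truth.

No per-patient imaging accompanies the cohort summaries this package
targets, so validation runs on voxelized phantoms that emulate the
measured structures: a bone block containing a spiral cochlear canal,
a niche cavity that opens through a small mouth into an air-filled
middle-ear space, a bony lip roofing the cavity, and a soft-tissue
membrane patch at the cavity floor.  Every phantom carries
continuous-geometry truth values for the four morphometrics, so the
pipeline can be scored against an oracle that is independent of the
pipeline itself.

Geometry (right-sided case; the world frame coincides with the cochlear
frame the pipeline will reconstruct):

* the midmodiolar axis is the world z-axis; the basal-turn landmark is
  at the origin and the apex at ``(0, 0, H)``;
* the niche cavity is a straight-walled prism over a superellipse
  cross-section (|x'/ax|^n + |y/ay|^n <= 1, n = 4, centred at
  ``(xc, 0)``), extending from its floor up to a roof near
  ``z = d_top``; the superellipse keeps the cavity wide near its
  x/y extremes, so extent measurements degrade gracefully with voxel
  size instead of losing a whole sliver at a tangent edge;
* the membrane is a superelliptical patch (semi-axes ``bx, by``, same
  exponent) of a plane tilted by ``membrane_tilt_deg`` about the
  x-axis so it faces the scala entrance rather than straight down; the
  plane passes through the patch's +y edge at z = 0, so the membrane
  pit dips *below* the surrounding floor and the soft-tissue slab
  beneath it is never exposed sideways to the cavity;
* roof and floor ring carry small tilts (``roof_tilt_deg``,
  ``floor_tilt_deg`` about the y-axis, both through the cavity centre
  so volume is unaffected): real niche walls are not grid-aligned
  planes, and an exactly grid-parallel surface would alias its whole
  area into a single voxel layer;
* a bone lip of thickness ``lip_thickness`` roofs the cavity except for
  a small circular mouth hole that connects the cavity to the air space
  above the lip;
* the overhang-tip landmark sits at the lip's outer edge at frame-y
  ``ay - oh``, so the tip cylinder circumscribes the whole cavity and
  the overhang length equals ``oh`` by construction;
* the scan grid does not coincide with the anatomy: the whole anatomy
  is rotated by ``scan_tilt_deg`` about the world x-axis and shifted by
  a random sub-voxel phase before voxelization, as in a real
  acquisition, where the scanner axes never align with the cochlear
  frame.  (With an aligned grid, every frame-z coordinate would be a
  lattice multiple and extent measures would carry a systematic
  half-voxel-per-end bias.)

Closed-form truth: with S(n) = 4 Gamma(1+1/n)^2 / Gamma(1+2/n) the
superellipse area factor (S(2) = pi) and delta = by tan(tilt),

    Vol = S(n) ax ay d_top + S(n) bx by delta
    A   = S(n) bx by / cos(tilt)

(the roof and floor-ring tilt planes pass through the cavity's x
centroid and cancel; the membrane plane contributes the pit volume).
Depth and overhang truth use the same cavity indicator evaluated on a
4x-supersampled grid with the voxel-center extent convention, matching
how the pipeline measures them but at four times the resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import gamma as _gamma
from scipy.stats import truncnorm


from .cochlear_frame import reflect_case
from .grid import LabelMask, VoxelGrid
from .io_formats import CaseRecord, LandmarkSet
from .scala_model import ScalaModel, SpiralParams


def superellipse_area_factor(exponent: float) -> float:
    """Area of |x/a|^n + |y/b|^n <= 1 is this factor times a*b (pi for n=2)."""
    n = exponent
    return 4.0 * _gamma(1 + 1 / n) ** 2 / _gamma(1 + 2 / n)

# Cohort targets: mean, std, lower and upper truncation of the sampled
# per-case morphometrics (mm^3 / mm^2 / mm).
DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "vol_mm3": (4.54, 1.05, 2.28, 6.64),
    "area_mm2": (2.93, 0.72, 1.30, 4.39),
    "oh_mm": (0.56, 0.27, 0.04, 1.24),
    "d_mm": (1.35, 0.22, 0.98, 1.88),
}
DEFAULT_SEX_RATIO = 22 / 50  # fraction male
DEFAULT_LEFT_FRACTION = 16 / 50
DEFAULT_AGE_RANGE = (13, 92)


class InfeasibleTargetsError(ValueError):
    """Sampled (Vol, A, oh, d) combination admits no phantom geometry."""


@dataclass(frozen=True)
class Intensities:
    """Tissue intensity means and additive Gaussian noise (arbitrary units)."""

    bone: float = 1800.0
    soft: float = 300.0
    air: float = 0.0
    noise_std: float = 60.0

    def __post_init__(self) -> None:
        if not (self.bone > self.soft > self.air):
            raise ValueError("need bone > soft > air intensity")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric phantom anatomy (lengths in mm)."""

    voxel_spacing: float = 0.08
    cavity_center_x: float = 3.3
    cavity_semi_x: float = 1.00
    cavity_semi_y: float = 1.40
    cavity_height: float = 0.73       # d_top: floor level to lip underside
    cavity_exponent: float = 4.0      # superellipse exponent of the cross-section
    membrane_semi_x: float = 0.74
    membrane_semi_y: float = 1.03
    membrane_tilt_deg: float = 15.0
    membrane_thickness: float = 0.35
    roof_tilt_deg: float = 4.0
    floor_tilt_deg: float = 2.0
    overhang_mm: float = 0.56         # target oh; fixes the tip landmark
    lip_thickness: float = 0.4
    mouth_hole_radius: float = 0.35
    spiral: SpiralParams = field(default_factory=SpiralParams)
    include_cochlea: bool = True
    intensities: Intensities = field(default_factory=Intensities)
    scan_tilt_deg: float = 18.0       # anatomy-to-scan-grid rotation about world x
    landmark_jitter_mm: float = 0.0
    side: str = "right"
    age: float = 53.0
    sex: str = "female"

    def __post_init__(self) -> None:
        for name in (
            "voxel_spacing", "cavity_semi_x", "cavity_semi_y", "cavity_height",
            "membrane_semi_x", "membrane_semi_y", "membrane_thickness",
            "lip_thickness", "mouth_hole_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.overhang_mm < 0:
            raise ValueError("overhang_mm must be >= 0")
        if not 0 <= self.membrane_tilt_deg < 60:
            raise ValueError("membrane_tilt_deg must be in [0, 60)")
        if not 0 <= self.roof_tilt_deg < 20 or not 0 <= self.floor_tilt_deg < 20:
            raise ValueError("roof/floor tilts must be in [0, 20) degrees")
        if self.cavity_exponent < 2:
            raise ValueError("cavity_exponent must be >= 2")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    # -- derived geometry ---------------------------------------------------

    @property
    def tilt_rad(self) -> float:
        return math.radians(self.membrane_tilt_deg)

    @property
    def membrane_dip(self) -> float:
        """delta = by tan(tilt); the membrane pit bottom sits at -2 delta."""
        return self.membrane_semi_y * math.tan(self.tilt_rad)

    @property
    def roof_rise(self) -> float:
        return self.cavity_semi_x * math.tan(math.radians(self.roof_tilt_deg))

    @property
    def tip_y(self) -> float:
        return self.cavity_semi_y - self.overhang_mm

    @property
    def tip_point(self) -> np.ndarray:
        return np.array(
            [
                self.cavity_center_x + self.cavity_semi_x + 0.25,
                self.tip_y,
                self.cavity_height + 0.5 * self.lip_thickness,
            ]
        )

    def membrane_plane_z(self, y: np.ndarray) -> np.ndarray:
        """Tilted membrane plane through the patch's +y edge at z = 0."""
        return (y - self.membrane_semi_y) * math.tan(self.tilt_rad)

    def truth(self, supersample: int = 4) -> "GroundTruth":
        """Continuous-geometry truth for Vol/A plus supersampled d/oh."""
        s = superellipse_area_factor(self.cavity_exponent)
        mem_area_proj = s * self.membrane_semi_x * self.membrane_semi_y
        vol = (
            s * self.cavity_semi_x * self.cavity_semi_y * self.cavity_height
            + mem_area_proj * self.membrane_dip
        )
        area = mem_area_proj / math.cos(self.tilt_rad)
        d, oh = self._supersampled_extents(supersample)
        return GroundTruth(vol_mm3=vol, area_mm2=area, oh_mm=oh, d_mm=d)

    def membrane_patch_indicator(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        n = self.cavity_exponent
        um = np.abs((x - self.cavity_center_x) / self.membrane_semi_x) ** n
        vm = np.abs(y / self.membrane_semi_y) ** n
        return um + vm <= 1.0

    def cavity_indicator(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boolean cavity membership for broadcastable world coordinates."""
        xc = self.cavity_center_x
        n = self.cavity_exponent
        u = np.abs((x - xc) / self.cavity_semi_x) ** n
        v = np.abs(y / self.cavity_semi_y) ** n
        in_cross_section = u + v <= 1.0
        in_mem = self.membrane_patch_indicator(x, y)
        floor = np.where(
            in_mem,
            self.membrane_plane_z(y),
            (x - xc) * math.tan(math.radians(self.floor_tilt_deg)),
        )
        roof = self.cavity_height + (x - xc) * math.tan(math.radians(self.roof_tilt_deg))
        return in_cross_section & (z >= floor) & (z < roof)

    def _supersampled_extents(self, supersample: int) -> tuple[float, float]:
        step = self.voxel_spacing / supersample
        xc, ax, ay = self.cavity_center_x, self.cavity_semi_x, self.cavity_semi_y
        z_floor_min = min(
            -2 * self.membrane_dip, -ax * math.tan(math.radians(self.floor_tilt_deg))
        )
        lo = np.array([xc - ax - step, -ay - step, z_floor_min - step])
        hi = np.array([xc + ax + step, ay + step, self.cavity_height + self.roof_rise + step])
        xs = np.arange(lo[0] + step / 2, hi[0], step)
        ys = np.arange(lo[1] + step / 2, hi[1], step)
        zs = np.arange(lo[2] + step / 2, hi[2], step)
        inside = self.cavity_indicator(
            xs[:, None, None], ys[None, :, None], zs[None, None, :]
        )
        if not inside.any():
            raise InfeasibleTargetsError("cavity contains no supersampled voxel center")
        z_any = inside.any(axis=(0, 1))
        y_any = inside.any(axis=(0, 2))
        d = float(zs[z_any].max() - zs[z_any].min())
        oh = float(max(0.0, ys[y_any].max() - self.tip_y))
        return d, oh


@dataclass(frozen=True)
class GroundTruth:
    vol_mm3: float
    area_mm2: float
    oh_mm: float
    d_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "vol_mm3": self.vol_mm3,
            "area_mm2": self.area_mm2,
            "oh_mm": self.oh_mm,
            "d_mm": self.d_mm,
        }


# ---------------------------------------------------------------------------
# target -> geometry solver


def solve_phantom_spec(
    vol_mm3: float,
    area_mm2: float,
    oh_mm: float,
    d_mm: float,
    aspect: float = 1.4,
    membrane_tilt_deg: float = 15.0,
    roof_tilt_deg: float = 4.0,
    floor_tilt_deg: float = 2.0,
    cavity_exponent: float = 4.0,
    fit_margin: float = 0.92,
    **overrides,
) -> PhantomSpec:
    """Phantom geometry whose continuous truth hits the four targets.

    Solves, in order: the membrane patch from the area target
    (projected area = A cos(tilt), y/x aspect fixed), then the cavity
    cross-section and height jointly from the volume and depth targets

        V = S ax ay d_top + S bx by delta
        d = d_top + ax tan(roof_tilt) + 2 delta,   delta = by tan(tilt)

    with S the superellipse area factor (a fixed-point iteration in
    ax, since the roof-tilt term couples the two equations), and
    finally the tip position from the overhang target.  Raises
    :class:`InfeasibleTargetsError` when the membrane would not fit
    inside the cavity floor, the cavity height would collapse, or the
    overhang would exceed the cavity's y extent.
    """
    tilt = math.radians(membrane_tilt_deg)
    s = superellipse_area_factor(cavity_exponent)
    bx = math.sqrt(area_mm2 * math.cos(tilt) / (s * aspect))
    by = aspect * bx
    dip = by * math.tan(tilt)
    tan_roof = math.tan(math.radians(roof_tilt_deg))
    v_cyl = vol_mm3 - s * bx * by * dip  # volume left for the prism part
    if v_cyl <= 0.2 * vol_mm3:
        raise InfeasibleTargetsError(
            "membrane pit would hold most of the volume target; targets infeasible"
        )
    ax = 1.0
    for _ in range(50):
        d_top = d_mm - 2 * dip - ax * tan_roof
        if d_top < 0.3:
            raise InfeasibleTargetsError(
                f"depth target {d_mm} mm leaves cavity height {d_top:.2f} mm after the "
                "membrane pit; targets infeasible"
            )
        ax_new = math.sqrt(v_cyl / (s * aspect * d_top))
        if abs(ax_new - ax) < 1e-12:
            ax = ax_new
            break
        ax = ax_new
    ay = aspect * ax
    d_top = d_mm - 2 * dip - ax * tan_roof
    if bx > fit_margin * ax or by > fit_margin * ay:
        raise InfeasibleTargetsError(
            f"membrane ellipse ({bx:.2f} x {by:.2f} mm) does not fit the cavity floor "
            f"({ax:.2f} x {ay:.2f} mm)"
        )
    if oh_mm > 0.9 * ay:
        raise InfeasibleTargetsError(
            f"overhang target {oh_mm:.2f} mm exceeds the cavity y semi-axis {ay:.2f} mm"
        )
    return PhantomSpec(
        cavity_semi_x=ax,
        cavity_semi_y=ay,
        cavity_height=d_top,
        cavity_exponent=cavity_exponent,
        membrane_semi_x=bx,
        membrane_semi_y=by,
        membrane_tilt_deg=membrane_tilt_deg,
        roof_tilt_deg=roof_tilt_deg,
        floor_tilt_deg=floor_tilt_deg,
        overhang_mm=oh_mm,
        **overrides,
    )


# ---------------------------------------------------------------------------
# voxelization


def _spiral_canal_mask(
    spec: PhantomSpec,
    xa: np.ndarray,
    ya: np.ndarray,
    za: np.ndarray,
) -> np.ndarray:
    """Voxels inside the spiral cochlear canal (excluding the niche shell).

    Coordinate arrays are anatomy-frame positions of the voxel centers,
    broadcastable to the block shape.
    """
    model = ScalaModel(params=spec.spiral)
    p = spec.spiral
    n_samples = max(200, int(p.theta_max / 0.01))
    theta = np.linspace(0.0, p.theta_max, n_samples)
    centers = model.canonical_centerline(theta)
    radii = model.tube_radius(theta)
    r_max = radii.max()

    shape = np.broadcast_shapes(xa.shape, ya.shape, za.shape)
    out = np.zeros(shape, dtype=bool)
    # candidate voxels: inside the spiral's bounding annulus
    rad2 = xa**2 + ya**2
    a_min = p.basal_radius * p.radial_decay**p.turns
    cand = (
        (rad2 >= max(0.0, a_min - r_max - 0.2) ** 2)
        & (rad2 <= (p.basal_radius + r_max + 0.2) ** 2)
        & (za >= -r_max - 0.1)
        & (za <= p.axis_length + r_max + 0.1)
    )
    cand = np.broadcast_to(cand, shape)
    idx = np.argwhere(cand)
    if len(idx) == 0:
        return out
    xa3, ya3, za3 = (np.broadcast_to(c, shape) for c in (xa, ya, za))
    pts = np.column_stack([xa3[cand], ya3[cand], za3[cand]])
    tree = cKDTree(centers)
    dist, nearest = tree.query(pts, workers=-1)
    inside = dist <= radii[nearest]
    # keep a bone shell between canal and cavity so the niche wall stays bone
    shell = 0.3
    xc = spec.cavity_center_x
    near_cavity = (
        (((pts[:, 0] - xc) / (spec.cavity_semi_x + shell)) ** 2
         + (pts[:, 1] / (spec.cavity_semi_y + shell)) ** 2 <= 1.0)
        & (pts[:, 2] >= -2 * spec.membrane_dip - spec.membrane_thickness - shell)
        & (pts[:, 2] <= spec.cavity_height + spec.roof_rise + shell)
    )
    inside &= ~near_cavity
    sel = idx[inside]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


def generate_phantom(
    spec: PhantomSpec | None = None, seed: int = 0
) -> tuple[VoxelGrid, LabelMask, LandmarkSet, GroundTruth]:
    """Voxelize a phantom: intensity volume, true RWN mask, landmarks, truth.

    Deterministic for a given ``(spec, seed)``; the seed drives the
    additive intensity noise and optional landmark jitter.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    h = spec.voxel_spacing
    xc, ax, ay = spec.cavity_center_x, spec.cavity_semi_x, spec.cavity_semi_y
    d_top = spec.cavity_height
    p = spec.spiral
    if ax >= xc:
        raise InfeasibleTargetsError("niche cavity reaches the midmodiolar axis")

    # anatomy-frame bounding box of everything we carve
    margin = 0.6
    z_bottom = -2 * spec.membrane_dip - spec.membrane_thickness - margin
    z_top = d_top + spec.roof_rise + spec.lip_thickness + margin
    if spec.include_cochlea:
        r_out = p.basal_radius + p.tube_radius_start
        lo_a = np.array(
            [
                -(r_out + margin),
                -max(r_out, ay) - margin,
                min(z_bottom, -p.tube_radius_start - 0.3),
            ]
        )
        hi_a = np.array(
            [
                xc + ax + margin + 0.3,
                max(r_out, ay) + margin,
                max(p.axis_length + p.tube_radius_end + 0.3, z_top),
            ]
        )
    else:
        lo_a = np.array([xc - ax - margin, -ay - margin, z_bottom])
        hi_a = np.array([xc + ax + margin + 0.3, ay + margin, z_top])

    # scan grid: anatomy rotated about world x plus a random sub-voxel
    # phase, so the cochlear frame never aligns with the voxel lattice
    alpha = math.radians(spec.scan_tilt_deg)
    ca, sa = math.cos(alpha), math.sin(alpha)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    shift = rng.uniform(0.0, h, size=3)
    corners = np.array(
        [
            [xi, yi, zi]
            for xi in (lo_a[0], hi_a[0])
            for yi in (lo_a[1], hi_a[1])
            for zi in (lo_a[2], hi_a[2])
        ]
    )
    corners_w = corners @ rot.T + shift
    lo = corners_w.min(axis=0)
    hi = corners_w.max(axis=0)

    shape = tuple(int(np.ceil((hi[a] - lo[a]) / h)) for a in range(3))
    origin = tuple(lo + h / 2)
    xs = lo[0] + h / 2 + h * np.arange(shape[0])
    ys = lo[1] + h / 2 + h * np.arange(shape[1])
    zs = lo[2] + h / 2 + h * np.arange(shape[2])
    # anatomy-frame coordinates of the world voxel centers (p_a = R^T (p_w - t))
    Xa = (xs - shift[0])[:, None, None]
    Yw = (ys - shift[1])[None, :, None]
    Zw = (zs - shift[2])[None, None, :]
    Ya = ca * Yw + sa * Zw
    Za = -sa * Yw + ca * Zw

    inten = spec.intensities
    data = np.full(shape, inten.bone, dtype=np.float32)

    if spec.include_cochlea:
        canal = _spiral_canal_mask(spec, Xa, Ya, Za)
        data[canal] = inten.soft

    # soft slab below the membrane patch
    in_mem = spec.membrane_patch_indicator(Xa, Ya)
    plane = spec.membrane_plane_z(Ya)
    slab = in_mem & (Za >= plane - spec.membrane_thickness) & (Za < plane)
    data[np.broadcast_to(slab, shape)] = inten.soft

    # middle-ear air space above the lip, mouth hole through the lip
    air_space = np.broadcast_to(
        (Za >= d_top + spec.roof_rise + spec.lip_thickness) & (Xa >= xc - ax), shape
    )
    data[air_space] = inten.air
    hole_y = min(max(spec.tip_y - spec.mouth_hole_radius - 0.15, -0.7 * ay), 0.7 * ay)
    roof = d_top + (Xa - xc) * math.tan(math.radians(spec.roof_tilt_deg))
    hole = (
        ((Xa - xc) ** 2 + (Ya - hole_y) ** 2 <= spec.mouth_hole_radius**2)
        & (Za >= roof)
        & (Za < roof + spec.lip_thickness + spec.roof_rise)
    )
    data[np.broadcast_to(hole, shape)] = inten.air

    cavity = np.broadcast_to(spec.cavity_indicator(Xa, Ya, Za), shape)
    if not cavity.any():
        raise InfeasibleTargetsError("cavity contains no voxel center")
    if (
        cavity[0].any() or cavity[-1].any()
        or cavity[:, 0].any() or cavity[:, -1].any()
        or cavity[:, :, 0].any() or cavity[:, :, -1].any()
    ):
        raise InfeasibleTargetsError("niche cavity is not contained in the bone block")
    data[cavity] = inten.air

    # the tip cylinder must circumscribe the cavity (clipping is a no-op
    # on the true mask; the cylinder's role is to bound a manual leak)
    tip_a = spec.tip_point
    tip_radius = math.hypot(tip_a[0], tip_a[1])
    Xa3 = np.broadcast_to(Xa, shape)
    Ya3 = np.broadcast_to(Ya, shape)
    max_radial = float(np.hypot(Xa3[cavity], Ya3[cavity]).max())
    if max_radial > tip_radius:
        raise InfeasibleTargetsError(
            f"cavity extends to radius {max_radial:.2f} mm, beyond the tip cylinder "
            f"({tip_radius:.2f} mm)"
        )

    if inten.noise_std > 0:
        data += rng.normal(0.0, inten.noise_std, size=shape).astype(np.float32)

    grid = VoxelGrid(data=data, spacing=(h, h, h), origin=origin)
    mask = LabelMask(data=cavity.astype(np.uint8), grid=grid)

    anatomy_landmarks = np.array(
        [
            [0.0, 0.0, p.axis_length],  # apex
            [0.0, 0.0, 0.0],            # basal turn
            [xc, 0.0, 0.0],             # RWM point (membrane centre level)
            tip_a,                      # overhang tip
        ]
    )
    world_landmarks = anatomy_landmarks @ rot.T + shift
    if spec.landmark_jitter_mm > 0:
        world_landmarks = world_landmarks + rng.normal(
            0.0, spec.landmark_jitter_mm, size=(4, 3)
        )
    apex, basal, rwm, tip = world_landmarks
    landmarks = LandmarkSet(apex=apex, basal=basal, rwm_point=rwm, overhang_tip=tip, side="right")
    truth = spec.truth()

    if spec.side == "left":
        case = CaseRecord(
            id="phantom", volume=grid, mask=mask, landmarks=landmarks,
            age=spec.age, sex=spec.sex,
        )
        flipped = reflect_case(case)  # right -> left
        return flipped.volume, flipped.mask, flipped.landmarks, truth
    return grid, mask, landmarks, truth


# ---------------------------------------------------------------------------
# cohorts


def sample_truth_table(
    n: int,
    seed: int = 0,
    distributions: dict[str, tuple[float, float, float, float]] | None = None,
    sex_ratio: float = DEFAULT_SEX_RATIO,
    left_fraction: float = DEFAULT_LEFT_FRACTION,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    max_tries: int = 100,
    solver_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Sample per-case target metrics and demographics (no voxelization).

    Targets are drawn independently from truncated normals and a case is
    resampled (up to ``max_tries``) whenever the combination admits no
    phantom geometry.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = distributions or DEFAULT_DISTRIBUTIONS
    for name, (mean, std, lo, hi) in dists.items():
        if std <= 0 or hi <= lo:
            raise ValueError(f"invalid truncated-normal parameters for {name}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for attempt in range(max_tries):
            draw = {}
            for name, (mean, std, lo, hi) in dists.items():
                a, b = (lo - mean) / std, (hi - mean) / std
                draw[name] = float(truncnorm.rvs(a, b, loc=mean, scale=std, random_state=rng))
            try:
                solve_phantom_spec(
                    draw["vol_mm3"], draw["area_mm2"], draw["oh_mm"], draw["d_mm"],
                    **(solver_kwargs or {}),
                )
            except InfeasibleTargetsError:
                continue
            break
        else:
            raise InfeasibleTargetsError(
                f"no feasible target combination after {max_tries} tries"
            )
        rows.append({"id": f"case{i:03d}", **draw})
    table = pd.DataFrame(rows)

    n_male = int(round(n * sex_ratio))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    n_left = int(round(n * left_fraction))
    sides = np.array(["left"] * n_left + ["right"] * (n - n_left))
    rng.shuffle(sides)
    table["sex"] = sexes
    table["side"] = sides
    table["age"] = rng.integers(age_range[0], age_range[1] + 1, size=n)
    return table


def generate_cohort(
    n: int,
    seed: int = 0,
    distributions: dict[str, tuple[float, float, float, float]] | None = None,
    sex_ratio: float = DEFAULT_SEX_RATIO,
    left_fraction: float = DEFAULT_LEFT_FRACTION,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    spec_overrides: dict | None = None,
    solver_kwargs: dict | None = None,
) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Generate ``n`` voxelized phantom cases plus their truth table.

    The truth table holds, per case, the demographics and the
    continuous-geometry truth of the four morphometrics (recomputed from
    the solved geometry, so it reflects what the voxelized anatomy
    actually encodes, not merely the sampled targets).
    """
    table = sample_truth_table(
        n, seed=seed, distributions=distributions, sex_ratio=sex_ratio,
        left_fraction=left_fraction, age_range=age_range, solver_kwargs=solver_kwargs,
    )
    rng = np.random.default_rng(seed + 1)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    cases: list[CaseRecord] = []
    truth_rows = []
    for i, row in table.iterrows():
        spec = solve_phantom_spec(
            row["vol_mm3"], row["area_mm2"], row["oh_mm"], row["d_mm"],
            **(solver_kwargs or {}),
            side=row["side"], age=float(row["age"]), sex=row["sex"],
            **(spec_overrides or {}),
        )
        volume, mask, landmarks, truth = generate_phantom(spec, seed=int(case_seeds[i]))
        cases.append(
            CaseRecord(
                id=row["id"], volume=volume, mask=mask, landmarks=landmarks,
                age=float(row["age"]), sex=row["sex"],
            )
        )
        truth_rows.append(
            {
                "id": row["id"], "sex": row["sex"], "age": float(row["age"]),
                "side": row["side"], **truth.as_dict(),
            }
        )
    return cases, pd.DataFrame(truth_rows)
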