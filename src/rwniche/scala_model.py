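"""Parametric scala tympani / scala vestibuli spiral-tube model.

A canonical logarithmic-spiral tube with a linearly tapering circular
cross-section stands in for a statistical mean-shape model.  Its role
in the pipeline is purely geometric: positioned by the three cochlear
landmarks via a similarity transform, it tells the morphometry stage
where the scala-tympani entrance lies and in which direction the round
window membrane faces; it also provides QC surface meshes.  It is never
used to segment.

Canonical frame: the modiolar axis is the z-axis, the basal entrance of
the scala (the round-window end) is at angle theta = 0 on the +x side,
and the spiral winds counter-clockwise (toward +y at theta = 0) while
rising toward the apex:

    c(theta) = (a(theta) cos(theta), a(theta) sin(theta), pitch * theta / 2pi)
    a(theta) = a0 * decay**(theta / 2pi)

with ``turns`` total turns, so the canonical apex sits at height
``turns * pitch`` above the basal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cochlear_frame import build_frame
from .io_formats import LandmarkSet


@dataclass(frozen=True)
class SpiralParams:
    """Geometry of the canonical scala spiral.

    turns
        Number of full turns of the centerline (human cochlea ~2.5).
    basal_radius
        Distance a0 (mm) of the basal entrance from the modiolar axis.
    radial_decay
        Radius multiplier per full turn, in (0, 1].
    pitch
        Axial rise (mm) per full turn; canonical axis length is
        ``turns * pitch``.
    tube_radius_start, tube_radius_end
        Lumen radius (mm) at theta = 0 and at the apical end, linearly
        interpolated in theta.
    """

    turns: float = 2.5
    basal_radius: float = 2.8
    radial_decay: float = 0.6
    pitch: float = 2.0
    tube_radius_start: float = 0.6
    tube_radius_end: float = 0.2

    def __post_init__(self) -> None:
        for name in ("turns", "basal_radius", "pitch", "tube_radius_start", "tube_radius_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.radial_decay <= 1:
            raise ValueError("radial_decay must be in (0, 1]")

    @property
    def theta_max(self) -> float:
        return 2.0 * np.pi * self.turns

    @property
    def axis_length(self) -> float:
        return self.turns * self.pitch


@dataclass(frozen=True)
class Similarity:
    """Isotropic similarity transform p -> scale * R @ p + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        if self.scale <= 0:
            raise ValueError("similarity scale must be > 0")
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be a proper orthonormal matrix")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_direction(self, v: np.ndarray) -> np.ndarray:
        out = self.rotation @ np.asarray(v, dtype=float).reshape(3)
        return out / np.linalg.norm(out)

    @staticmethod
    def identity() -> "Similarity":
        return Similarity(rotation=np.eye(3), translation=np.zeros(3), scale=1.0)


@dataclass
class ScalaModel:
    """A spiral tube in world coordinates: canonical spiral + similarity."""

    params: SpiralParams = field(default_factory=SpiralParams)
    transform: Similarity = field(default_factory=Similarity.identity)

    # -- canonical geometry -------------------------------------------------

    def canonical_centerline(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        a = self.params.basal_radius * self.params.radial_decay ** (theta / (2 * np.pi))
        pts = np.column_stack(
            [a * np.cos(theta), a * np.sin(theta), self.params.pitch * theta / (2 * np.pi)]
        )
        return pts

    def canonical_tangent(self, theta) -> np.ndarray:
        """Analytic d c / d theta (canonical frame, unnormalized).

        Scalar theta gives a (3,) vector; an array gives (n, 3).
        """
        p = self.params
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        k = -np.log(p.radial_decay) / (2 * np.pi)  # a(theta) = a0 exp(-k theta)
        a = p.basal_radius * np.exp(-k * th)
        da = -k * a
        out = np.column_stack(
            [
                da * np.cos(th) - a * np.sin(th),
                da * np.sin(th) + a * np.cos(th),
                np.full_like(th, p.pitch / (2 * np.pi)),
            ]
        )
        return out[0] if np.isscalar(theta) or np.asarray(theta).ndim == 0 else out

    def tube_radius(self, theta: np.ndarray) -> np.ndarray:
        p = self.params
        t = np.asarray(theta, dtype=float) / p.theta_max
        return p.tube_radius_start + (p.tube_radius_end - p.tube_radius_start) * t

    def centerline(self, theta: np.ndarray) -> np.ndarray:
        """World-coordinate centerline points."""
        return self.transform.apply(self.canonical_centerline(theta))

    # -- derived quantities -------------------------------------------------

    def tube_volume(self, n: int = 4000) -> float:
        """Analytic tube volume, integral of pi r(theta)^2 |c'(theta)| d theta.

        Evaluated in world units (scale applied); accurate for tubes
        whose radius is small against the local curvature radius.
        """
        theta = np.linspace(0.0, self.params.theta_max, n)
        speed = np.linalg.norm(self.canonical_tangent(theta), axis=1)
        r = self.tube_radius(theta)
        s = self.transform.scale
        integrand = np.pi * (s * r) ** 2 * (s * speed)
        return float(np.trapezoid(integrand, theta))

    def surface_mesh(self, n_theta: int = 200, n_phi: int = 24):
        """Triangle mesh of the tube surface (world mm) for QC export."""
        import trimesh

        theta = np.linspace(0.0, self.params.theta_max, n_theta)
        centers = self.canonical_centerline(theta)
        radii = self.tube_radius(theta)
        # local frames along the curve
        tangents = self.canonical_tangent(theta)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        ref = np.array([0.0, 0.0, 1.0])
        n1 = np.cross(tangents, ref)
        bad = np.linalg.norm(n1, axis=1) < 1e-6
        n1[bad] = np.array([1.0, 0.0, 0.0])
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(tangents, n1)
        phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
        verts = (
            centers[:, None, :]
            + radii[:, None, None] * (np.cos(phi)[None, :, None] * n1[:, None, :] + np.sin(phi)[None, :, None] * n2[:, None, :])
        ).reshape(-1, 3)
        faces = []
        for i in range(n_theta - 1):
            for j in range(n_phi):
                a = i * n_phi + j
                b = i * n_phi + (j + 1) % n_phi
                c = (i + 1) * n_phi + j
                d = (i + 1) * n_phi + (j + 1) % n_phi
                faces.append([a, b, d])
                faces.append([a, d, c])
        verts = self.transform.apply(verts)
        return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)

    def export_mesh(self, path: str | Path, **kw) -> None:
        self.surface_mesh(**kw).export(str(path))


def canonical_scala(params: SpiralParams | None = None) -> ScalaModel:
    """The canonical (untransformed) scala model."""
    return ScalaModel(params=params or SpiralParams())


def fit_similarity(
    apex: np.ndarray,
    basal: np.ndarray,
    rwm_point: np.ndarray,
    params: SpiralParams | None = None,
) -> Similarity:
    """Similarity placing the canonical spiral at the landmarks.

    Maps the canonical modiolar axis (z) onto the line basal -> apex,
    scales so the canonical axis length matches ``|apex - basal|``, and
    rotates about the axis so the canonical theta = 0 entrance direction
    (+x) points toward the RWM landmark.  Deterministic closed form.
    """
    params = params or SpiralParams()
    frame = build_frame(
        LandmarkSet(apex=apex, basal=basal, rwm_point=rwm_point, overhang_tip=rwm_point, side="right")
    )
    scale = float(np.linalg.norm(np.asarray(apex, dtype=float) - np.asarray(basal, dtype=float)))
    scale /= params.axis_length
    rotation = np.column_stack([frame.ex, frame.ey, frame.ez])
    return Similarity(rotation=rotation, translation=np.asarray(basal, dtype=float), scale=scale)


def fit_scala(landmarks: LandmarkSet, params: SpiralParams | None = None) -> ScalaModel:
    """Canonical model plus the landmark-fitted similarity."""
    params = params or SpiralParams()
    transform = fit_similarity(landmarks.apex, landmarks.basal, landmarks.rwm_point, params)
    return ScalaModel(params=params, transform=transform)


def st_entrance_direction(model: ScalaModel) -> np.ndarray:
    """Unit vector pointing out of the scala-tympani entrance, world frame.

    This is ``-dc/dtheta`` at theta = 0 mapped through the fitted
    rotation: it points from the ST entrance into the niche region, and
    its negation is the direction a scala-facing membrane normal should
    have.
    """
    tangent = model.canonical_tangent(0.0)
    return model.transform.apply_direction(-tangent)
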