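"""Pipeline configuration shared by the library and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from .scala_model import SpiralParams


@dataclass
class PipelineConfig:
    """Tunable choices for the per-case pipeline and cohort statistics.

    bone_threshold
        ``"auto"`` (Otsu on a 2-voxel shell around the mask, recomputed
        per case) or a fixed intensity.
    area_estimator
        ``"corrected"`` (normal-corrected face sum, default),
        ``"mesh"`` (smoothed marching-cubes triangle area) or
        ``"face_count"`` (raw voxel-face sum).
    smoothing_sigma
        Gaussian sigma in voxels for the membrane mesh extraction.
    t_test
        ``"student"`` (pooled-variance, default) or ``"welch"``.
    normality_floor
        Minimum sample size for the omnibus normality test.
    seed
        Master seed for any randomness (synthetic cohorts).
    """

    bone_threshold: float | str = "auto"
    area_estimator: str = "corrected"
    smoothing_sigma: float = 1.0
    t_test: str = "student"
    normality_floor: int = 20
    seed: int = 0
    spiral_params: SpiralParams = field(default_factory=SpiralParams)
    export_qc_meshes: bool = False
    export_clipped_masks: bool = False

    def __post_init__(self) -> None:
        if self.area_estimator not in ("corrected", "mesh", "face_count"):
            raise ValueError(f"invalid area_estimator {self.area_estimator!r}")
        if self.t_test not in ("student", "welch"):
            raise ValueError(f"invalid t_test {self.t_test!r}")
        if self.bone_threshold != "auto":
            self.bone_threshold = float(self.bone_threshold)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
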