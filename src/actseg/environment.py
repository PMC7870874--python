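"""The agent's environment: a volume plus a moving estimate cloud/mesh.

Wraps observation encoding, physical action application and the reward
(reduction of the mean vertex-to-ground-truth distance) behind a small
gym-like interface used by both training loops and inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from actseg.actions import ActionScale, apply_action
from actseg.geometry import PointCloud, SurfaceMesh, Volume, compute_normals, one_sided_distance
from actseg.observation import (
    Observation,
    encode_pointcloud_observation,
    encode_surface_observation,
)

__all__ = ["ObservationConfig", "AgentEnv", "compute_reward"]


@dataclass
class ObservationConfig:
    mode: str = "surface_ray"  # or "patch"
    n_samples: int = 61
    spacing_mm: float = 1.0
    patch: tuple = (7, 7, 7)
    patch_step_mm: float = 1.0

    @property
    def width_image(self) -> int:
        if self.mode == "surface_ray":
            return self.n_samples
        return int(np.prod(self.patch))

    @property
    def width_total(self) -> int:
        # surface mode appends normals to the unit-sphere positions
        return self.width_image + (6 if self.mode == "surface_ray" else 3)


def compute_reward(V_before, V_after, G) -> float:
    """Decrease of the mean vertex->ground-truth distance (positive = better)."""
    return one_sided_distance(V_before, G) - one_sided_distance(V_after, G)


@dataclass
class AgentEnv:
    volume: Volume
    truth: PointCloud
    estimate: PointCloud
    obs_cfg: ObservationConfig = field(default_factory=ObservationConfig)
    scale_cfg: ActionScale = field(default_factory=ActionScale)

    def observe(self) -> Observation:
        if self.obs_cfg.mode == "surface_ray":
            mesh = self.estimate
            if not isinstance(mesh, SurfaceMesh):
                raise TypeError("surface_ray observations require a SurfaceMesh")
            if mesh.normals is None:
                mesh = compute_normals(mesh)
                self.estimate = mesh
            return encode_surface_observation(
                mesh, self.volume, self.obs_cfg.n_samples, self.obs_cfg.spacing_mm
            )
        return encode_pointcloud_observation(
            self.estimate, self.volume, self.obs_cfg.patch, self.obs_cfg.patch_step_mm
        )

    def distance(self) -> float:
        """Mean one-sided estimate->truth distance (the reward potential)."""
        return one_sided_distance(self.estimate, self.truth)

    def step(self, action_type: str, vec: np.ndarray, stage: str = "normalized") -> float:
        """Apply one action; returns the immediate reward."""
        before = self.estimate
        self.estimate = apply_action(before, action_type, vec, self.scale_cfg, stage=stage)
        return compute_reward(before, self.estimate, self.truth)

    def clone(self) -> "AgentEnv":
        return AgentEnv(self.volume, self.truth, self.estimate.copy(), self.obs_cfg, self.scale_cfg)
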