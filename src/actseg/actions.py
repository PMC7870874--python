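"""Action model: translation / scale / rotation / per-vertex deformation.

Actions exist in three stages.  ``raw`` actions are in physical units
(mm, unitless scale factors, radians).  ``normalized`` actions live on the
unit sphere (translation, deformation) or in [-1, 1] ranges (scale,
rotation).  ``beta`` actions are normalized actions multiplied by the
acceleration factor beta, which sets the per-step step size of the agent.

Scale and rotation act about the centroid of the transformed cloud, so they
do not alias with translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from actseg.geometry import InvalidInputError, PointCloud

__all__ = [
    "ACTION_TYPES",
    "ActionScale",
    "ActionSet",
    "euler_to_matrix",
    "matrix_to_euler",
    "normalize_action_set",
    "apply_beta",
    "apply_action",
]

ACTION_TYPES = ("translation", "scale", "rotation", "deformation")


@dataclass(frozen=True)
class ActionScale:
    """Configured physical ranges used to (de)normalize actions.

    ``step_mm``: physical length of a unit-norm translation/deformation.
    ``s_max``: per-step per-axis scale bound; normalized scale is
    ``log(s)/log(s_max)`` clamped to [-1, 1].
    ``r_max``: per-step rotation bound in radians.
    ``norm_eps_mm``: floor of the translation/deformation normalizer
    ``t' = t / max(||t||, eps)``.  At the default the normalized action
    always has unit norm (fixed step size); raising it toward ``step_mm``
    makes targets shrink proportionally once the optimal action is smaller
    than the floor, which damps oscillation near convergence.
    """

    step_mm: float = 5.0
    s_max: float = 1.25
    r_max: float = float(np.deg2rad(10.0))
    norm_eps_mm: float = 1e-8


@dataclass
class ActionSet:
    """A (possibly partial) set of candidate actions at one time step."""

    translation: np.ndarray | None = None
    scale: np.ndarray | None = None
    rotation: np.ndarray | None = None
    deformation: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        for name in ("translation", "scale", "rotation"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.float64).reshape(3)
                object.__setattr__(self, name, v)
        if self.deformation is not None:
            d = np.asarray(self.deformation, dtype=np.float64)
            if d.ndim != 2 or d.shape[1] != 3:
                raise InvalidInputError("deformation must be N x 3")
            self.deformation = d

    def types(self) -> tuple:
        return tuple(t for t in ACTION_TYPES if getattr(self, t) is not None)

    def get(self, action_type: str) -> np.ndarray:
        v = getattr(self, action_type)
        if v is None:
            raise InvalidInputError(f"action set has no {action_type!r} component")
        return v


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix for intrinsic angles (rx, ry, rz), applied X.Y.Z."""
    rx, ry, rz = np.asarray(angles, dtype=np.float64)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix` (X.Y.Z convention)."""
    R = np.asarray(R, dtype=np.float64)
    sy = np.clip(R[0, 2], -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(abs(sy) - 1.0) > 1e-9:
        rx = np.arctan2(-R[1, 2], R[2, 2])
        rz = np.arctan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock
        rx = np.arctan2(R[2, 1], R[1, 1])
        rz = 0.0
    return np.array([rx, ry, rz])


def normalize_action_set(
    actions: ActionSet, scale_cfg: ActionScale, eps: float | None = None
) -> ActionSet:
    """Map a raw action set onto the unit sphere / configured ranges.

    Translation is scaled to unit norm (directions preserved); the
    deformation field is divided by its largest row norm so the largest
    per-vertex displacement sits on the unit sphere; scale and rotation are
    mapped into [-1, 1] via ``log(s)/log(s_max)`` and ``r/r_max``.
    """
    if actions.stage != "raw":
        raise InvalidInputError("normalize_action_set expects raw-stage actions")
    if eps is None:
        eps = scale_cfg.norm_eps_mm
    out = replace(actions)
    if actions.translation is not None:
        t = actions.translation
        out.translation = t / max(float(np.linalg.norm(t)), eps)
    if actions.deformation is not None:
        d = actions.deformation
        m = float(np.max(np.linalg.norm(d, axis=1)))
        out.deformation = d / max(m, eps) if m > 0 else d.copy()
    if actions.scale is not None:
        s = np.maximum(actions.scale, 1e-12)
        out.scale = np.clip(np.log(s) / np.log(scale_cfg.s_max), -1.0, 1.0)
    if actions.rotation is not None:
        out.rotation = np.clip(actions.rotation / scale_cfg.r_max, -1.0, 1.0)
    out.stage = "normalized"
    return out


def apply_beta(actions: ActionSet, beta: float) -> ActionSet:
    """Multiply every normalized component by the acceleration factor beta."""
    if beta <= 0:
        raise InvalidInputError("beta must be > 0")
    if actions.stage != "normalized":
        raise InvalidInputError("apply_beta expects normalized-stage actions")
    out = replace(actions)
    for name in ACTION_TYPES:
        v = getattr(actions, name)
        if v is not None:
            setattr(out, name, v * beta)
    out.stage = "beta"
    return out


def _denormalize(action_type: str, vec: np.ndarray, scale_cfg: ActionScale, step_mm: float):
    if action_type in ("translation", "deformation"):
        return vec * step_mm
    if action_type == "scale":
        return scale_cfg.s_max ** np.asarray(vec, dtype=np.float64)
    if action_type == "rotation":
        return np.asarray(vec, dtype=np.float64) * scale_cfg.r_max
    raise InvalidInputError(f"unknown action type {action_type!r}")


def apply_action(
    cloud: PointCloud,
    action_type: str,
    vec: np.ndarray,
    scale_cfg: ActionScale | None = None,
    stage: str = "raw",
    step_mm: float | None = None,
) -> PointCloud:
    """Apply one action to a cloud; vertex count and ordering are preserved.

    ``stage='raw'`` interprets ``vec`` in physical units.  Normalized/beta
    vectors are mapped back to physical units via ``scale_cfg`` with
    ``step_mm`` (defaults to ``scale_cfg.step_mm``) as the length of a
    unit-norm translation/deformation.
    """
    if action_type not in ACTION_TYPES:
        raise InvalidInputError(f"unknown action type {action_type!r}")
    vec = np.asarray(vec, dtype=np.float64)
    if stage != "raw":
        if scale_cfg is None:
            raise InvalidInputError("scale_cfg required for normalized actions")
        vec = _denormalize(action_type, vec, scale_cfg, step_mm if step_mm is not None else scale_cfg.step_mm)
    pts = cloud.points
    if action_type == "translation":
        new = pts + vec.reshape(1, 3)
    elif action_type == "deformation":
        if vec.shape != pts.shape:
            raise InvalidInputError("deformation shape must match cloud")
        new = pts + vec
    elif action_type == "scale":
        c = pts.mean(axis=0)
        new = c + (pts - c) * vec.reshape(1, 3)
    else:  # rotation
        c = pts.mean(axis=0)
        R = euler_to_matrix(vec)
        new = c + (pts - c) @ R.T
    return cloud.with_points(new)
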