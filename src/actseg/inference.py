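"""Greedy MDP rollout for segmentation/registration plus evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from actseg.actions import ActionScale
from actseg.environment import AgentEnv, ObservationConfig
from actseg.geometry import (
    InvalidInputError,
    PointCloud,
    SurfaceMesh,
    Volume,
    symmetric_distance,
    voxel_to_world,
)
from actseg.networks import ActorNetwork, ValueNetwork
from actseg.observation import encode_pointcloud_observation

__all__ = [
    "EpisodeConfig",
    "Trajectory",
    "run_episode",
    "run_actor_rollout",
    "register_landmarks",
    "dice_score",
    "voxelize_mesh",
    "mean_surface_distance",
    "target_registration_error",
    "beta_study",
]

# fixed greedy tie-break: prefer the most expressive action
_TIE_ORDER = ("deformation", "translation", "rotation", "scale")


@dataclass
class EpisodeConfig:
    t_max: int = 50
    q_min: float = 0.05
    obs_cfg: ObservationConfig = field(default_factory=ObservationConfig)
    scale_cfg: ActionScale = field(default_factory=ActionScale)


@dataclass
class Trajectory:
    meshes: list
    action_types: list
    q_values: list
    rewards: list
    termination: str

    @property
    def final(self):
        return self.meshes[-1]

    def __len__(self) -> int:
        return len(self.meshes)


def _argmax_q(qs: dict) -> str:
    best = max(qs.values())
    for t in _TIE_ORDER:
        if t in qs and qs[t] == best:
            return t
    return max(qs, key=qs.get)


def run_episode(
    vol: Volume,
    V0,
    actor: ActorNetwork,
    value: ValueNetwork,
    cfg: EpisodeConfig,
    truth=None,
) -> Trajectory:
    """Greedy rollout: actor proposes, value scores, argmax-Q action applied.

    Stops when the best Q drops below ``q_min`` or after ``t_max`` steps.
    Rewards are recorded when ``truth`` is given.
    """
    env = AgentEnv(vol, truth if truth is not None else V0, V0.copy(), cfg.obs_cfg, cfg.scale_cfg)
    meshes = [env.estimate.copy()]
    action_types: list = []
    q_values: list = []
    rewards: list = []
    termination = "t_max"
    for t in range(cfg.t_max):
        obs = env.observe()
        pred = {k: v.data[0] for k, v in actor.forward(obs.features).items()}
        qs = {k: float(v.data[0]) for k, v in value.forward(obs.features, pred).items()}
        if not all(np.isfinite(q) for q in qs.values()):
            raise RuntimeError(f"non-finite Q values at step {t}: {qs}")
        q_values.append(dict(qs))
        if max(qs.values()) < cfg.q_min:
            termination = "q_min"
            break
        a_type = _argmax_q(qs)
        r = env.step(a_type, pred[a_type], stage="normalized")
        action_types.append(a_type)
        if truth is not None:
            rewards.append(r)
        meshes.append(env.estimate.copy())
    return Trajectory(meshes, action_types, q_values, rewards, termination)


def run_actor_rollout(
    vol: Volume,
    V0,
    actor: ActorNetwork,
    cfg: EpisodeConfig,
    truth=None,
    stage: str = "normalized",
    action_type: str = "deformation",
) -> list:
    """Actor-only rollout applying one fixed action type every step.

    Returns the list of estimates per step (length t_max + 1).  Used by the
    non-rigid-only registration variant and the beta-study harness.
    """
    env = AgentEnv(vol, truth if truth is not None else V0, V0.copy(), cfg.obs_cfg, cfg.scale_cfg)
    states = [env.estimate.copy()]
    for _ in range(cfg.t_max):
        obs = env.observe()
        pred = actor.forward(obs.features)
        if action_type not in pred:
            raise InvalidInputError(f"actor has no {action_type!r} head")
        env.step(action_type, pred[action_type].data[0], stage=stage)
        states.append(env.estimate.copy())
    return states


def register_landmarks(
    vol: Volume,
    landmarks: np.ndarray,
    actor: ActorNetwork,
    cfg: EpisodeConfig,
    pad_to: int | None = None,
    rng: np.random.Generator | None = None,
    tol_mm: float = 1e-2,
) -> np.ndarray:
    """Iteratively displace landmarks with the non-rigid actor.

    The landmark list is padded to ``pad_to`` by duplicating randomly chosen
    landmarks; duplication does not affect the originals' predictions (the
    networks max-pool and the patch encoding is duplication-invariant).
    Returns only the original landmarks.
    """
    pts = np.atleast_2d(np.asarray(landmarks, dtype=np.float64))
    if len(pts) == 0:
        raise InvalidInputError("no landmarks to register")
    n_orig = len(pts)
    if pad_to is not None and pad_to > n_orig:
        rng = rng or np.random.default_rng(0)
        extra = rng.integers(0, n_orig, size=pad_to - n_orig)
        pts = np.concatenate([pts, pts[extra]], axis=0)
    for _ in range(cfg.t_max):
        obs = encode_pointcloud_observation(
            PointCloud(pts), vol, cfg.obs_cfg.patch, cfg.obs_cfg.patch_step_mm
        )
        pred = actor.forward(obs.features)["deformation"].data[0]
        step = pred * cfg.scale_cfg.step_mm
        pts = pts + step
        if float(np.mean(np.linalg.norm(step[:n_orig], axis=1))) < tol_mm:
            break
    return pts[:n_orig]


# ---------------------------------------------------------------------------
# metrics


def voxelize_mesh(mesh: SurfaceMesh, like: Volume) -> np.ndarray:
    """Boolean inside-mask on the voxel grid of ``like``.

    Each voxel center is classified by the parity of triangle crossings of a
    world-space ray cast along +z.  Requires a watertight mesh.
    """
    if not mesh.is_watertight():
        raise InvalidInputError("mesh is not watertight; voxelization undefined")
    shape = like.data.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    pts = voxel_to_world(like, vox)
    # tiny irrational offset avoids rays passing exactly through edges
    pts = pts + np.array([np.pi * 1e-7, np.e * 1e-7, 0.0])

    tri = mesh.points[mesh.faces]  # (F, 3, 3)
    a2 = tri[:, :, :2]
    az = tri[:, :, 2]
    e1 = a2[:, 1] - a2[:, 0]
    e2 = a2[:, 2] - a2[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    ok = np.abs(det) > 1e-15

    inside = np.zeros(len(pts), dtype=bool)
    chunk = 8192
    for start in range(0, len(pts), chunk):
        p = pts[start : start + chunk]
        rel = p[:, None, :2] - a2[None, :, 0, :]  # (m, F, 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (rel[..., 0] * e2[None, :, 1] - rel[..., 1] * e2[None, :, 0]) / det[None, :]
            v = (e1[None, :, 0] * rel[..., 1] - e1[None, :, 1] * rel[..., 0]) / det[None, :]
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1)
        zint = az[None, :, 0] + u * (az[None, :, 1] - az[None, :, 0]) + v * (az[None, :, 2] - az[None, :, 0])
        above = hit & (zint > p[:, None, 2])
        inside[start : start + chunk] = (above.sum(axis=1) % 2) == 1
    return inside.reshape(shape)


def dice_score(mesh: SurfaceMesh, labels: Volume) -> float:
    """Dice overlap between the voxelized mesh and a binary label volume."""
    pred = voxelize_mesh(mesh, labels)
    truth = labels.data > 0.5
    inter = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * inter / denom)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance of each point to any triangle (vectorized, Eberly-style).

    ``points`` is (n, 3); ``tri`` is (m, 3, 3).  Returns (n,) distances.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a  # (m, 3)
    ac = c - a
    p = points[:, None, :] - a[None, :, :]  # (n, m, 3)
    d00 = np.einsum("mi,mi->m", ab, ab)
    d01 = np.einsum("mi,mi->m", ab, ac)
    d11 = np.einsum("mi,mi->m", ac, ac)
    d20 = np.einsum("nmi,mi->nm", p, ab)
    d21 = np.einsum("nmi,mi->nm", p, ac)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    u = (d11 * d20 - d01 * d21) / denom  # barycentric of the plane projection
    v = (d00 * d21 - d01 * d20) / denom
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)

    def edge_t(d2_edge, dot_edge):
        return np.clip(d2_edge / np.maximum(dot_edge, 1e-300), 0.0, 1.0)

    # candidates: interior projection (only valid inside) + the three edges
    t_ab = edge_t(d20, d00)
    t_ac = edge_t(d21, d11)
    bc = c - b
    p_b = points[:, None, :] - b[None, :, :]
    t_bc = edge_t(np.einsum("nmi,mi->nm", p_b, bc), np.einsum("mi,mi->m", bc, bc))

    d_interior = np.linalg.norm(p - (u[..., None] * ab[None] + v[..., None] * ac[None]), axis=-1)
    d_interior = np.where(inside, d_interior, np.inf)
    d_ab_edge = np.linalg.norm(p - t_ab[..., None] * ab[None], axis=-1)
    d_ac_edge = np.linalg.norm(p - t_ac[..., None] * ac[None], axis=-1)
    d_bc_edge = np.linalg.norm(p_b - t_bc[..., None] * bc[None], axis=-1)
    best = np.minimum(np.minimum(d_interior, d_ab_edge), np.minimum(d_ac_edge, d_bc_edge))
    return best.min(axis=1)


def _points_to_mesh(points: np.ndarray, mesh: SurfaceMesh, chunk: int = 512) -> np.ndarray:
    tri = mesh.points[mesh.faces]
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        out[start : start + chunk] = _point_triangle_distance(points[start : start + chunk], tri)
    return out


def mean_surface_distance(mesh, truth) -> float:
    """Symmetric mean surface distance in mm.

    When both arguments are triangle meshes this is the mean point-to-surface
    (point-to-triangle) distance averaged over both directions, so vertices
    sliding tangentially along a shared surface do not count as error.  For
    plain point clouds it falls back to the symmetric vertex distance.
    """
    if isinstance(mesh, SurfaceMesh) and isinstance(truth, SurfaceMesh):
        d_ab = _points_to_mesh(mesh.points, truth)
        d_ba = _points_to_mesh(truth.points, mesh)
        return float(0.5 * (d_ab.mean() + d_ba.mean()))
    return symmetric_distance(mesh, truth)


def target_registration_error(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Mean, min and max Euclidean landmark error (Table-style 'mean (range)')."""
    pred = np.atleast_2d(np.asarray(pred, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if pred.shape != truth.shape:
        raise InvalidInputError("landmark lists must have equal length")
    d = np.linalg.norm(pred - truth, axis=1)
    return {"mean": float(d.mean()), "min": float(d.min()), "max": float(d.max())}


# ---------------------------------------------------------------------------
# beta-study harness


def beta_study(
    variants: dict,
    cases: list,
    cfg: EpisodeConfig,
) -> dict:
    """Mean vertex distance over time for each trained actor variant.

    ``variants`` maps name -> (actor, stage) where stage is 'normalized' for
    beta-trained actors and 'raw' for the one-shot variants.  ``cases`` is a
    list of (volume, V0, truth).  Returns name -> (t_max+1,) mean vertex
    distance curve averaged over cases.
    """
    curves = {}
    for name, (actor, stage) in variants.items():
        per_case = []
        for vol, v0, truth in cases:
            states = run_actor_rollout(vol, v0, actor, cfg, truth=truth, stage=stage)
            per_case.append([symmetric_distance(s, truth) for s in states])
        curves[name] = np.mean(per_case, axis=0)
    return curves
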