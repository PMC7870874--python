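"""Training loops: DAGGER imitation learning and DDPG/DDQN joint training.

The actor is first trained to imitate the analytic demonstrator with
DAGGER-style dataset aggregation; the value network is then trained with a
double-DQN bootstrap target while the actor is refined at a slower rate by
the deterministic policy gradient through the value network.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from actseg.autodiff import Adam, Tensor
from actseg.demonstrator import Demonstrator, correspondences
from actseg.environment import AgentEnv
from actseg.geometry import InvalidInputError
from actseg.networks import ActorNetwork, ValueNetwork, action_loss, distance_loss
from actseg.observation import Observation

__all__ = [
    "Transition",
    "TrainConfig",
    "q_bounds",
    "ddqn_target",
    "ReplayBuffer",
    "dagger_train",
    "ddpg_train",
    "augment_image_features",
]

logger = logging.getLogger(__name__)


@dataclass
class Transition:
    features: np.ndarray  # o_t per-vertex feature block
    action_type: str
    action_vec: np.ndarray  # chosen normalized action
    reward: float
    next_features: np.ndarray  # o_{t+1}
    terminal: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.reward):
            raise InvalidInputError("transition reward must be finite")


@dataclass
class TrainConfig:
    beta: float = 1.0
    gamma: float = 0.9
    step_mm: float = 5.0  # physical length of a unit normalized translation/deformation
    s_max: float = 1.25  # per-step scale range bound
    r_max_deg: float = 10.0  # per-step rotation range bound
    norm_eps_mm: float = 1e-8  # proportional-normalization floor (see ActionScale)
    lam: float = 1.0  # deformation smoothness
    lam1: float = 0.1  # action-norm regularizer
    lam2: float = 0.1  # auxiliary distance loss
    # DAGGER
    dagger_iterations: int = 5
    rollouts_per_iteration: int = 4
    steps_per_rollout: int = 10
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    val_rollouts: int = 2
    target_mode: str = "beta"  # beta | raw | raw_lr
    learning_rate_action: float = 0.5  # for raw_lr one-shot variant
    # DDPG / DDQN
    ddpg_episodes: int = 30
    t_max: int = 10
    eps_start: float = 1.0
    eps_end: float = 0.1
    eps_decay_steps: int = 150
    value_lr: float = 1e-3
    actor_lr: float = 1e-4
    actor_update_period: int = 10
    target_update_period: int = 100
    replay_capacity: int = 10_000
    ddpg_batch: int = 32
    success_tol_mm: float = 0.5
    d_max: float = 60.0
    q_min_factor: float = 0.05
    seed: int = 0

    @property
    def q_min(self) -> float:
        return self.q_min_factor * self.beta


def q_bounds(beta: float, gamma: float, mean_action_loss: float, d_max: float) -> tuple:
    """Q-value bounds from the reward bounds r+ ~= beta, r- ~= -sqrt(L_bar)."""
    if gamma >= 1.0:
        raise InvalidInputError("gamma must be < 1 for bounded Q values")
    if mean_action_loss < 0:
        raise InvalidInputError("mean action loss must be >= 0")
    if mean_action_loss >= beta * beta:
        warnings.warn("mean action loss >= beta^2: reward lower bound exceeds -beta")
    lower = -np.sqrt(mean_action_loss) / (1.0 - gamma)
    upper = min(beta / (1.0 - gamma), d_max)
    return float(lower), float(upper)


def ddqn_target(
    transition: Transition,
    actor: ActorNetwork,
    target_value: ValueNetwork,
    gamma: float,
    clip: tuple | None = None,
) -> float:
    """Double-DQN bootstrap: r + gamma * max_a' Q_target(o', actor(o'))."""
    if transition.terminal:
        y = transition.reward
    else:
        pred = actor.forward(transition.next_features)
        qs = target_value.forward(transition.next_features, {k: v.data for k, v in pred.items()})
        y = transition.reward + gamma * max(float(q.data[0]) for q in qs.values())
    if clip is not None:
        y = float(np.clip(y, clip[0], clip[1]))
    return float(y)


class ReplayBuffer:
    def __init__(self, capacity: int):
        self.buf: deque = deque(maxlen=capacity)

    def push(self, tr: Transition) -> None:
        self.buf.append(tr)

    def sample(self, rng: np.random.Generator, batch: int) -> list:
        idx = rng.integers(0, len(self.buf), size=batch)
        return [self.buf[i] for i in idx]

    def __len__(self) -> int:
        return len(self.buf)


def augment_image_features(obs: Observation, sigma: float, rng: np.random.Generator) -> Observation:
    """Add i.i.d. Gaussian noise to the image features only."""
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    img = obs.image_features
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape)
    return Observation(
        img, obs.point_features.copy(), obs.center.copy(), obs.radius, obs.img_mean, obs.img_std
    )


# ---------------------------------------------------------------------------
# DAGGER


def _demo_targets(demo: Demonstrator, env: AgentEnv, cfg: TrainConfig) -> dict:
    """Targets for the configured mode, as {type: array}."""
    if cfg.target_mode == "beta":
        tgt = demo.targets(env.estimate, env.truth)
        return {t: tgt.get(t) for t in tgt.types()}
    raw = demo.optimal_actions(env.estimate, env.truth)
    scale = 1.0 if cfg.target_mode == "raw" else cfg.learning_rate_action
    return {t: raw.get(t) * scale for t in raw.types()}


def _rollout(
    demo: Demonstrator,
    env: AgentEnv,
    cfg: TrainConfig,
    rng: np.random.Generator,
    actor: ActorNetwork | None,
    noise_sigma: float = 0.0,
) -> list:
    """Visit steps_per_rollout states; label each with demonstrator targets.

    ``actor=None`` rolls out the demonstrator's own actions (iteration 0);
    otherwise the actor's predictions drive the episode, one action type
    chosen uniformly at random per step (the multi-task selection rule).
    """
    stage = "normalized" if cfg.target_mode == "beta" else "raw"
    samples = []
    for _ in range(cfg.steps_per_rollout):
        obs = env.observe()
        if noise_sigma > 0:
            obs = augment_image_features(obs, noise_sigma, rng)
        targets = _demo_targets(demo, env, cfg)
        samples.append(
            {
                "features": obs.features,
                "targets": targets,
                "points": env.estimate.points.copy(),
                "corr": correspondences(env.estimate, env.truth),
            }
        )
        if actor is None:
            acts = targets
        else:
            acts = {k: v.data[0] for k, v in actor.forward(obs.features).items()}
        a_type = list(acts)[rng.integers(len(acts))]
        env.step(a_type, acts[a_type], stage=stage)
    return samples


def _batched(samples: list, idx: np.ndarray) -> tuple:
    feats = np.stack([samples[i]["features"] for i in idx])
    types = samples[idx[0]]["targets"].keys()
    targets = {t: np.stack([samples[i]["targets"][t] for i in idx]) for t in types}
    points = np.stack([samples[i]["points"] for i in idx])
    corr = np.stack([samples[i]["corr"] for i in idx])
    return feats, targets, points, corr


def _actor_loss(
    actor: ActorNetwork, feats, targets, points, corr, cfg: TrainConfig
) -> tuple:
    pred = actor.forward(feats)
    la = action_loss(pred, targets, cfg.lam1, cfg.beta if cfg.target_mode == "beta" else 1.0)
    # auxiliary distance loss through the deformation (or translation) head
    step = actor_step_mm(actor, cfg)
    ld = None
    if "deformation" in pred:
        moved = Tensor(points) + pred["deformation"] * step
        ld = distance_loss(moved, corr, cfg.lam2)
    elif "translation" in pred:
        B = pred["translation"].data.shape[0]
        moved = Tensor(points) + pred["translation"].reshape(B, 1, 3) * step
        ld = distance_loss(moved, corr, cfg.lam2)
    total = la if ld is None else la + ld
    return total, la, ld


def actor_step_mm(actor: ActorNetwork, cfg: TrainConfig) -> float:
    """Physical length of a unit normalized step (1 for raw one-shot modes)."""
    return cfg.step_mm if cfg.target_mode == "beta" else 1.0


def evaluate_action_loss(actor: ActorNetwork, samples: list, cfg: TrainConfig) -> float:
    if not samples:
        return float("nan")
    idx = np.arange(len(samples))
    feats, targets, _, _ = _batched(samples, idx)
    pred = actor.forward(feats)
    la = action_loss(pred, targets, 0.0, cfg.beta)
    return float(la.data)


def dagger_train(
    demo: Demonstrator,
    env_factory,
    actor: ActorNetwork,
    cfg: TrainConfig,
    noise_sigma: float = 0.0,
) -> dict:
    """DAGGER: aggregate demonstrator labels along learner-visited states.

    ``env_factory(rng)`` must return a fresh :class:`AgentEnv` per rollout.
    Returns a history dict with per-iteration dataset sizes, training loss,
    and validation action loss on held-out demonstrator rollouts.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(actor.params, lr=cfg.lr)

    val = []
    for _ in range(cfg.val_rollouts):
        val.extend(_rollout(demo, env_factory(rng), cfg, rng, actor=None))

    dataset: list = []
    history = {"dataset_size": [], "train_loss": [], "val_action_loss": []}
    for iteration in range(cfg.dagger_iterations):
        driver = None if iteration == 0 else actor
        for _ in range(cfg.rollouts_per_iteration):
            dataset.extend(
                _rollout(demo, env_factory(rng), cfg, rng, actor=driver, noise_sigma=noise_sigma)
            )
        last_loss = float("nan")
        for _ in range(cfg.epochs):
            order = rng.permutation(len(dataset))
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                feats, targets, points, corr = _batched(dataset, idx)
                total, _, _ = _actor_loss(actor, feats, targets, points, corr, cfg)
                opt.zero_grad()
                total.backward()
                opt.step()
                last_loss = float(total.data)
        history["dataset_size"].append(len(dataset))
        history["train_loss"].append(last_loss)
        history["val_action_loss"].append(evaluate_action_loss(actor, val, cfg))
    return history


# ---------------------------------------------------------------------------
# DDPG / DDQN


def _epsilon(step: int, cfg: TrainConfig) -> float:
    if cfg.eps_decay_steps <= 0:
        return cfg.eps_end
    frac = min(step / cfg.eps_decay_steps, 1.0)
    return cfg.eps_start + frac * (cfg.eps_end - cfg.eps_start)


def select_action(qs: dict, eps: float, rng: np.random.Generator) -> str:
    """Epsilon-greedy over the candidate action types."""
    types = sorted(qs)
    if rng.random() < eps:
        return types[rng.integers(len(types))]
    return max(types, key=lambda t: qs[t])


def _batched_targets(
    batch: list,
    actor: ActorNetwork,
    target_value: ValueNetwork,
    gamma: float,
    clip: tuple | None,
) -> np.ndarray:
    """Vectorized double-DQN targets for a replay batch."""
    next_feats = np.stack([tr.next_features for tr in batch])
    pred = actor.forward(next_feats)
    qs = target_value.forward(next_feats, {k: v.data for k, v in pred.items()})
    qmax = np.max(np.stack([q.data for q in qs.values()]), axis=0)
    r = np.array([tr.reward for tr in batch])
    nonterminal = np.array([0.0 if tr.terminal else 1.0 for tr in batch])
    y = r + gamma * qmax * nonterminal
    if clip is not None:
        y = np.clip(y, clip[0], clip[1])
    return y


def _value_update(
    value: ValueNetwork,
    actor: ActorNetwork,
    target_value: ValueNetwork,
    batch: list,
    opt: Adam,
    cfg: TrainConfig,
    clip: tuple | None,
) -> float:
    ys = _batched_targets(batch, actor, target_value, cfg.gamma, clip)
    loss_total = 0.0
    opt.zero_grad()
    # group by action type so each group is one batched forward pass
    by_type: dict = {}
    for i, tr in enumerate(batch):
        by_type.setdefault(tr.action_type, []).append(i)
    n = len(batch)
    for a_type, idxs in by_type.items():
        feats = np.stack([batch[i].features for i in idxs])
        vec = np.stack([batch[i].action_vec for i in idxs])
        q = value.forward(feats, {a_type: vec})[a_type]
        target = np.array([ys[i] for i in idxs])
        loss = (q - Tensor(target)).square().sum() * (1.0 / n)
        loss.backward()
        loss_total += float(loss.data)
    opt.step()
    return loss_total


def _actor_policy_update(
    actor: ActorNetwork, value: ValueNetwork, batch: list, opt: Adam
) -> None:
    feats = np.stack([tr.features for tr in batch])
    pred = actor.forward(feats)
    qs = value.forward(feats, pred)
    total = None
    for q in qs.values():
        term = q.mean()
        total = term if total is None else total + term
    loss = -total
    opt.zero_grad()
    # freeze value parameters: clear their grads after backward
    loss.backward()
    for p in value.params.values():
        p.grad = None
    opt.step()


def ddpg_train(
    actor: ActorNetwork,
    value: ValueNetwork,
    target_value: ValueNetwork,
    env_factory,
    cfg: TrainConfig,
    mean_action_loss: float | None = None,
) -> dict:
    """Joint actor/value training (the actor is assumed DAGGER-pre-trained).

    Each environment step stores a transition and updates the value network
    on a replay batch toward the double-DQN target; the actor is updated by
    the deterministic policy gradient every ``actor_update_period`` value
    updates, and the target network is a hard copy of the value network every
    ``target_update_period`` updates.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    value_opt = Adam(value.params, lr=cfg.value_lr)
    actor_opt = Adam(actor.params, lr=cfg.actor_lr)
    replay = ReplayBuffer(cfg.replay_capacity)
    target_value.load_state_dict(value.state_dict())

    clip = None
    if mean_action_loss is not None and cfg.gamma < 1.0:
        # rewards are in mm while the Eq-style bounds are in normalized step
        # units; rescale by the physical step length
        lo, hi = q_bounds(cfg.beta, cfg.gamma, mean_action_loss, cfg.d_max / cfg.step_mm)
        clip = (lo * cfg.step_mm, hi * cfg.step_mm)

    history = {"episode_reward": [], "episode_final_distance": [], "value_loss": []}
    updates = 0
    global_step = 0
    for _ in range(cfg.ddpg_episodes):
        env = env_factory(rng)
        total_r = 0.0
        obs = env.observe()
        for t in range(cfg.t_max):
            pred = {k: v.data[0] for k, v in actor.forward(obs.features).items()}
            qs = {
                k: float(v.data[0])
                for k, v in value.forward(obs.features, pred).items()
            }
            a_type = select_action(qs, _epsilon(global_step, cfg), rng)
            r = env.step(a_type, pred[a_type], stage="normalized")
            total_r += r
            next_obs = env.observe()
            terminal = env.distance() < cfg.success_tol_mm
            replay.push(
                Transition(obs.features, a_type, pred[a_type], r, next_obs.features, terminal)
            )
            obs = next_obs
            global_step += 1
            if len(replay) >= cfg.ddpg_batch:
                batch = replay.sample(rng, cfg.ddpg_batch)
                vloss = _value_update(value, actor, target_value, batch, value_opt, cfg, clip)
                history["value_loss"].append(vloss)
                updates += 1
                if updates % cfg.actor_update_period == 0:
                    _actor_policy_update(actor, value, replay.sample(rng, cfg.ddpg_batch), actor_opt)
                if updates % cfg.target_update_period == 0:
                    target_value.load_state_dict(value.state_dict())
            if terminal:
                break
        history["episode_reward"].append(total_r)
        history["episode_final_distance"].append(env.distance())
    return history
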