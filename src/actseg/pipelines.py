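"""End-to-end recipes wiring phantoms, training loops and inference together.

These are the code paths behind the CLI subcommands and the acceptance
harness: build phantom case sets, train a segmentation agent (DAGGER +
DDPG), train non-rigid-only actors (registration / beta-study variants),
and run greedy inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from actseg.actions import ActionScale
from actseg.demonstrator import Demonstrator
from actseg.environment import AgentEnv, ObservationConfig
from actseg.geometry import SurfaceMesh, Volume
from actseg.inference import EpisodeConfig, run_episode
from actseg.networks import ActorNetwork, NetConfig, ValueNetwork
from actseg.phantoms import PhantomSpec, generate_phantom, log_filter
from actseg.shape_model import AugmentConfig, augment_mesh
from actseg.training import TrainConfig, dagger_train, ddpg_train

__all__ = [
    "PhantomCase",
    "make_phantom_cases",
    "SegmentationAgent",
    "train_segmentation_agent",
    "train_deformation_actor",
    "segment_case",
]


@dataclass
class PhantomCase:
    volume: Volume
    truth: SurfaceMesh
    labels: Volume
    spec: PhantomSpec


def make_phantom_cases(
    n: int,
    seed: int = 0,
    modalities: tuple = ("ct_like",),
    log_sigma_mm: float | None = None,
    **spec_overrides,
) -> list:
    """Generate n phantom cases, cycling through the requested modalities."""
    cases = []
    for i in range(n):
        spec = PhantomSpec(
            seed=seed + 1000 * i, modality=modalities[i % len(modalities)], **spec_overrides
        )
        vol, mesh, labels = generate_phantom(spec)
        if log_sigma_mm is not None:
            vol = log_filter(vol, log_sigma_mm)
        cases.append(PhantomCase(vol, mesh, labels, spec))
    return cases


@dataclass
class SegmentationAgent:
    actor: ActorNetwork
    value: ValueNetwork | None
    obs_cfg: ObservationConfig
    scale_cfg: ActionScale
    train_cfg: TrainConfig
    history: dict = field(default_factory=dict)

    def episode_config(self, t_max: int = 50, q_min: float | None = None) -> EpisodeConfig:
        if q_min is None:
            q_min = self.train_cfg.q_min * self.train_cfg.step_mm
        return EpisodeConfig(t_max=t_max, q_min=q_min, obs_cfg=self.obs_cfg, scale_cfg=self.scale_cfg)


def _init_augment() -> AugmentConfig:
    return AugmentConfig(
        translation_mm=0.0,  # shift applied separately with a norm-uniform draw
        scale_range=(0.9, 1.1),
        rotation_deg=8.0,
        jitter_mm=0.3,
        smooth_passes=0,
    )


def make_env_factory(
    cases: list,
    obs_cfg: ObservationConfig,
    scale_cfg: ActionScale,
    max_shift_mm: float = 20.0,
):
    """Fresh training episodes: random case, ground truth perturbed into V0.

    The initial displacement magnitude is drawn uniformly in
    [0, max_shift_mm] (uniform direction) so rollouts also visit
    near-converged states, which is where fine-action accuracy is learned.
    """
    aug = _init_augment()

    def factory(rng: np.random.Generator) -> AgentEnv:
        case = cases[rng.integers(len(cases))]
        v0 = augment_mesh(case.truth, None, rng, aug)
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        shift = direction * rng.uniform(0.0, max_shift_mm)
        v0 = v0.with_points(v0.points + shift)
        return AgentEnv(case.volume, case.truth, v0, obs_cfg, scale_cfg)

    return factory


def train_segmentation_agent(
    cases: list,
    cfg: TrainConfig,
    base: int = 16,
    max_shift_mm: float = 20.0,
    obs_cfg: ObservationConfig | None = None,
    train_value: bool = True,
    action_types: tuple = ("translation", "scale", "rotation", "deformation"),
) -> SegmentationAgent:
    """DAGGER-pretrain the actor, then jointly train actor+value with DDPG."""
    obs_cfg = obs_cfg or ObservationConfig()
    scale_cfg = ActionScale(
        step_mm=cfg.step_mm,
        s_max=cfg.s_max,
        r_max=float(np.deg2rad(cfg.r_max_deg)),
        norm_eps_mm=cfg.norm_eps_mm,
    )
    demo = Demonstrator(scale_cfg, lam=cfg.lam, beta=cfg.beta, action_types=action_types)
    net_cfg = NetConfig(obs_cfg.width_total, base=base, action_types=action_types, seed=cfg.seed)
    actor = ActorNetwork(net_cfg)
    env_factory = make_env_factory(cases, obs_cfg, scale_cfg, max_shift_mm)

    history = {"dagger": dagger_train(demo, env_factory, actor, cfg)}
    value = None
    if train_value:
        value = ValueNetwork(replace(net_cfg, seed=cfg.seed + 7))
        target = ValueNetwork(replace(net_cfg, seed=cfg.seed + 7))
        la = history["dagger"]["val_action_loss"][-1]
        mean_loss = 0.5 * la if np.isfinite(la) else None
        history["ddpg"] = ddpg_train(actor, value, target, env_factory, cfg, mean_action_loss=mean_loss)
    return SegmentationAgent(actor, value, obs_cfg, scale_cfg, cfg, history)


def train_deformation_actor(
    env_factory,
    feature_width: int,
    cfg: TrainConfig,
    base: int = 32,
    seed_offset: int = 0,
) -> ActorNetwork:
    """Non-rigid-only actor trained purely by DAGGER (registration variant)."""
    scale_cfg = ActionScale(step_mm=cfg.step_mm)
    demo = Demonstrator(scale_cfg, lam=cfg.lam, beta=cfg.beta, action_types=("deformation",))
    actor = ActorNetwork(
        NetConfig(feature_width, base=base, action_types=("deformation",), seed=cfg.seed + seed_offset)
    )
    dagger_train(demo, env_factory, actor, cfg)
    return actor


def run_beta_study(
    seed: int = 0,
    betas: tuple = (0.5, 1.0, 2.0),
    include_one_shot: bool = True,
    n_train: int = 4,
    n_test: int = 2,
    t_max: int = 50,
    max_shift_mm: float = 15.0,
    base: int = 16,
    cfg: TrainConfig | None = None,
) -> dict:
    """Train deformation-only actors per variant and record distance curves.

    Variants: normalized actors for each beta, plus raw one-shot (the actor
    learns the full optimal deformation) and one-shot with a learning rate.
    All variants share training data amounts and network capacity.  Returns
    ``name -> mean vertex distance curve`` over ``n_test`` held-out phantoms.
    """
    from actseg.inference import beta_study as _beta_curves

    base_cfg = cfg or TrainConfig(
        seed=seed,
        step_mm=2.0,
        dagger_iterations=3,
        rollouts_per_iteration=4,
        steps_per_rollout=8,
        epochs=15,
        lam2=0.0,
    )
    obs_cfg = ObservationConfig()
    train_cases = make_phantom_cases(n_train, seed=seed)
    test_cases = make_phantom_cases(n_test, seed=seed + 555_000)

    variants = {}
    specs = [(f"beta_{b:g}", replace(base_cfg, beta=b, target_mode="beta")) for b in betas]
    if include_one_shot:
        # the action-norm regularizer is meaningless for unnormalized targets
        specs.append(("one_shot", replace(base_cfg, target_mode="raw", lam1=0.0)))
        specs.append(("one_shot_lr", replace(base_cfg, target_mode="raw_lr", lam1=0.0)))
    for name, vcfg in specs:
        factory = make_env_factory(
            train_cases, obs_cfg, ActionScale(step_mm=vcfg.step_mm), max_shift_mm
        )
        actor = train_deformation_actor(factory, obs_cfg.width_total, vcfg, base=base)
        stage = "normalized" if vcfg.target_mode == "beta" else "raw"
        variants[name] = (actor, stage)

    rng = np.random.default_rng(seed + 99)
    eval_cases = []
    for case in test_cases:
        shift = rng.uniform(-1.0, 1.0, size=3)
        shift = shift / np.linalg.norm(shift) * max_shift_mm
        v0 = case.truth.with_points(case.truth.points + shift)
        eval_cases.append((case.volume, v0, case.truth))

    ep_cfg = EpisodeConfig(
        t_max=t_max, obs_cfg=obs_cfg, scale_cfg=ActionScale(step_mm=base_cfg.step_mm)
    )
    return _beta_curves(variants, eval_cases, ep_cfg)


def segment_case(
    case_volume: Volume,
    template: SurfaceMesh,
    agent: SegmentationAgent,
    t_max: int = 50,
    truth=None,
):
    """Greedy value-selected rollout from a template placement."""
    if agent.value is None:
        raise ValueError("agent has no value network; use run_actor_rollout instead")
    cfg = agent.episode_config(t_max=t_max)
    return run_episode(case_volume, template, agent.actor, agent.value, cfg, truth=truth)
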