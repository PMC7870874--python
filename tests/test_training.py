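import numpy as np
import pytest

from actseg.actions import ActionScale
from actseg.demonstrator import Demonstrator
from actseg.environment import AgentEnv, ObservationConfig, compute_reward
from actseg.geometry import InvalidInputError, PointCloud, SurfaceMesh, Volume, icosphere
from actseg.networks import ActorNetwork, NetConfig, ValueNetwork
from actseg.observation import encode_surface_observation
from actseg.phantoms import PhantomSpec, generate_phantom
from actseg.training import (
    ReplayBuffer,
    TrainConfig,
    Transition,
    augment_image_features,
    dagger_train,
    ddqn_target,
    q_bounds,
    select_action,
)


@pytest.fixture(scope="module")
def seg_env():
    vol, mesh, _ = generate_phantom(PhantomSpec(seed=21))
    v0 = mesh.with_points(mesh.points + [8.0, -4.0, 6.0])
    return AgentEnv(vol, mesh, v0, ObservationConfig(), ActionScale(step_mm=4.0))


class TestReward:
    def test_no_motion_zero(self, seg_env):
        assert compute_reward(seg_env.estimate, seg_env.estimate, seg_env.truth) == 0.0

    def test_simple_reduction(self):
        g = PointCloud(np.zeros((1, 3)))
        before = PointCloud([[2.0, 0, 0]])
        after = PointCloud([[1.2, 0, 0]])
        assert compute_reward(before, after, g) == pytest.approx(0.8)

    def test_telescoping(self, seg_env):
        env = seg_env.clone()
        demo = Demonstrator(env.scale_cfg, beta=0.5)
        d0 = env.distance()
        total = 0.0
        rng = np.random.default_rng(0)
        for _ in range(15):
            tgt = demo.targets(env.estimate, env.truth)
            a = rng.choice(list(tgt.types()))
            total += env.step(a, tgt.get(a))
        assert total == pytest.approx(d0 - env.distance(), abs=1e-12)


class TestQBounds:
    def test_paper_arithmetic(self):
        lower, upper = q_bounds(beta=1.0, gamma=0.9, mean_action_loss=0.25, d_max=20.0)
        assert upper == pytest.approx(10.0)
        assert lower == pytest.approx(-5.0)

    def test_d_max_binds(self):
        _, upper = q_bounds(1.0, 0.9, 0.0, d_max=5.0)
        assert upper == 5.0

    def test_gamma_one_rejected(self):
        with pytest.raises(InvalidInputError):
            q_bounds(1.0, 1.0, 0.1, 20.0)

    def test_large_loss_warns(self):
        with pytest.warns(UserWarning):
            q_bounds(1.0, 0.9, 2.0, 20.0)

    def test_lower_below_upper(self):
        lower, upper = q_bounds(0.5, 0.8, 0.2, 30.0)
        assert lower < upper


class TestDdqnTarget:
    @pytest.fixture
    def nets(self):
        cfg = NetConfig(feature_width=9, base=4, seed=0)
        return ActorNetwork(cfg), ValueNetwork(cfg)

    def _transition(self, rng, terminal, r=0.5):
        f = rng.normal(size=(5, 9))
        return Transition(f, "translation", np.zeros(3), r, rng.normal(size=(5, 9)), terminal)

    def test_terminal_is_reward(self, nets, rng):
        actor, value = nets
        tr = self._transition(rng, terminal=True)
        assert ddqn_target(tr, actor, value, gamma=0.9) == 0.5

    def test_gamma_zero(self, nets, rng):
        actor, value = nets
        tr = self._transition(rng, terminal=False)
        assert ddqn_target(tr, actor, value, gamma=0.0) == pytest.approx(0.5)

    def test_matches_manual_forward(self, nets, rng):
        actor, value = nets
        tr = self._transition(rng, terminal=False)
        pred = actor.forward(tr.next_features)
        qs = value.forward(tr.next_features, {k: v.data for k, v in pred.items()})
        expected = 0.5 + 0.7 * max(float(q.data[0]) for q in qs.values())
        assert ddqn_target(tr, actor, value, gamma=0.7) == pytest.approx(expected)

    def test_clip(self, nets, rng):
        actor, value = nets
        tr = self._transition(rng, terminal=True, r=100.0)
        assert ddqn_target(tr, actor, value, 0.9, clip=(-1.0, 1.0)) == 1.0

    def test_nonfinite_reward_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            Transition(np.zeros((2, 3)), "translation", np.zeros(3), np.nan, np.zeros((2, 3)), False)


class TestEpsilonGreedy:
    def test_uniform_at_eps_one(self):
        rng = np.random.default_rng(0)
        qs = {"translation": 1.0, "scale": -1.0, "rotation": 0.0, "deformation": 0.5}
        counts = {k: 0 for k in qs}
        n = 10_000
        for _ in range(n):
            counts[select_action(qs, eps=1.0, rng=rng)] += 1
        # binomial CI: p=0.25, 4 sigma
        sigma = np.sqrt(0.25 * 0.75 / n)
        for k in counts:
            assert abs(counts[k] / n - 0.25) < 4 * sigma

    def test_greedy_at_eps_zero(self):
        rng = np.random.default_rng(0)
        qs = {"translation": 1.0, "scale": -1.0}
        assert select_action(qs, 0.0, rng) == "translation"


class TestAugmentImageFeatures:
    def test_sigma_zero_unchanged(self, seg_env, rng):
        obs = seg_env.observe()
        out = augment_image_features(obs, 0.0, rng)
        assert np.array_equal(out.image_features, obs.image_features)

    def test_noise_statistics(self, rng):
        from actseg.observation import Observation

        img = np.zeros((1000, 1000))
        obs = Observation(img, np.zeros((1000, 3)), np.zeros(3), 1.0, 0.0, 1.0)
        out = augment_image_features(obs, 0.1, rng)
        assert (out.image_features - img).std() == pytest.approx(0.1, rel=0.01)

    def test_point_features_untouched(self, seg_env, rng):
        obs = seg_env.observe()
        out = augment_image_features(obs, 0.3, rng)
        assert np.array_equal(out.point_features, obs.point_features)


class TestReplayBuffer:
    def test_capacity(self, rng):
        buf = ReplayBuffer(5)
        for i in range(9):
            buf.push(Transition(np.zeros((1, 2)), "scale", np.zeros(3), float(i), np.zeros((1, 2)), False))
        assert len(buf) == 5
        assert buf.buf[0].reward == 4.0


def _line_env_factory(rng: np.random.Generator) -> AgentEnv:
    """1-D toy: line cloud on an x-ramp volume, translation only."""
    n = 40
    idx = np.arange(n) * 2.0
    data = np.broadcast_to(np.sin(idx / 8.0)[:, None, None], (n, n, n)).copy()
    vol = Volume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
    base = np.stack([np.full(8, 40.0), np.linspace(20, 60, 8), np.full(8, 40.0)], axis=1)
    mesh = icosphere(1, radius=12.0, center=(40.0, 40.0, 40.0))
    shift = np.array([rng.uniform(-10, 10), 0.0, 0.0])
    v0 = mesh.with_points(mesh.points + shift)
    return AgentEnv(vol, mesh, v0, ObservationConfig(n_samples=21), ActionScale(step_mm=3.0))


class TestDagger:
    @pytest.fixture(scope="class")
    def result(self):
        cfg = TrainConfig(
            seed=0,
            beta=1.0,
            step_mm=3.0,
            dagger_iterations=4,
            rollouts_per_iteration=2,
            steps_per_rollout=5,
            epochs=12,
            batch_size=4,
            lr=3e-3,
            lam2=0.0,
            val_rollouts=2,
        )
        demo = Demonstrator(ActionScale(step_mm=3.0), beta=1.0, action_types=("translation",))
        obs_cfg = ObservationConfig(n_samples=21)
        actor = ActorNetwork(
            NetConfig(21 + 6, base=8, action_types=("translation",), seed=0)
        )
        hist = dagger_train(demo, _line_env_factory, actor, cfg)
        return cfg, hist

    def test_dataset_aggregation_bookkeeping(self, result):
        cfg, hist = result
        m = cfg.rollouts_per_iteration * cfg.steps_per_rollout
        expected = [m * (k + 1) for k in range(cfg.dagger_iterations)]
        assert hist["dataset_size"] == expected

    def test_validation_loss_decreases(self, result):
        _, hist = result
        losses = hist["val_action_loss"]
        assert losses[-1] < losses[0]
        # decreasing trend over >= 3 iterations
        assert sum(b < a for a, b in zip(losses, losses[1:])) >= 2

    def test_targets_have_beta_norm(self):
        demo = Demonstrator(ActionScale(step_mm=3.0), beta=1.0, action_types=("translation",))
        rng = np.random.default_rng(4)
        env = _line_env_factory(rng)
        tgt = demo.targets(env.estimate, env.truth)
        assert np.linalg.norm(tgt.translation) == pytest.approx(1.0)
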