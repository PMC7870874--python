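"""Actor and value networks plus their losses.

Both networks share the same PointNet-style trunk: three per-vertex dense
blocks (widths base, 2*base, 4*base) followed by a max-pool over vertices
yielding a permutation-invariant global feature.  The actor concatenates the
global feature back onto the per-vertex features (skip connection) and emits
a per-vertex deformation head plus pooled 3-vector heads for translation,
scale and rotation (9 affine degrees of freedom).  The value network takes a
candidate action as additional input, concatenated onto every vertex row
together with a one-hot action-type code, and scores a scalar Q per action.

Max-pooling (rather than mean) makes both networks invariant to duplicated
vertex rows, which is what allows landmark-duplication padding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from actseg.actions import ACTION_TYPES, ActionSet
from actseg.autodiff import Tensor, concat
from actseg.geometry import InvalidInputError
from actseg.observation import Observation

__all__ = [
    "NetConfig",
    "ActorNetwork",
    "ValueNetwork",
    "action_loss",
    "distance_loss",
    "LossReport",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetConfig:
    feature_width: int
    base: int = 64
    action_types: tuple = ACTION_TYPES
    seed: int = 0


@dataclass
class LossReport:
    """Combined actor loss bookkeeping: L_total = L_action + L_distance."""

    action_loss: float
    distance_loss: float

    @property
    def combined(self) -> float:
        return self.action_loss + self.distance_loss

    @property
    def mean_action_loss(self) -> float:
        """Running approximation L_bar = combined / 2 used for the Q bounds."""
        return 0.5 * self.combined


def _init_dense(rng: np.random.Generator, n_in: int, n_out: int):
    # He-style init for relu blocks
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
    b = np.zeros(n_out)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


class _Net:
    """Shared trunk + parameter bookkeeping."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        self.params: dict = {}
        self._rng = np.random.default_rng(cfg.seed)

    def _dense(self, name: str, n_in: int, n_out: int) -> None:
        w, b = _init_dense(self._rng, n_in, n_out)
        self.params[name + ".w"] = w
        self.params[name + ".b"] = b

    def _apply(self, name: str, x: Tensor, activation: str = "relu") -> Tensor:
        y = x.matmul(self.params[name + ".w"]) + self.params[name + ".b"]
        if activation == "relu":
            return y.relu()
        if activation == "linear":
            return y
        raise ValueError(activation)

    def _trunk(self, feats: Tensor):
        """Returns (local (B,N,4b), global (B,4b))."""
        h = self._apply("enc1", feats)
        h = self._apply("enc2", h)
        local = self._apply("enc3", h)
        glob = local.max(axis=1)
        return local, glob

    @staticmethod
    def _as_batched(features) -> Tensor:
        t = Tensor.as_tensor(features)
        if t.data.ndim == 2:
            t = t.reshape(1, *t.data.shape)
        if t.data.ndim != 3:
            raise InvalidInputError("observation features must be (N,F) or (B,N,F)")
        return t

    def _check_width(self, t: Tensor) -> None:
        if t.data.shape[-1] != self.cfg.feature_width:
            raise InvalidInputError(
                f"feature width {t.data.shape[-1]} != configured {self.cfg.feature_width}"
            )

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise InvalidInputError(f"unexpected parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise InvalidInputError(f"shape mismatch for {k!r}")
            self.params[k].data = np.array(v, dtype=np.float64)


class ActorNetwork(_Net):
    def __init__(self, cfg: NetConfig):
        super().__init__(cfg)
        b = cfg.base
        self._dense("enc1", cfg.feature_width, b)
        self._dense("enc2", b, 2 * b)
        self._dense("enc3", 2 * b, 4 * b)
        if "deformation" in cfg.action_types:
            self._dense("def1", 8 * b, 2 * b)
            self._dense("def2", 2 * b, 3)
        for t in ("translation", "scale", "rotation"):
            if t in cfg.action_types:
                self._dense(t + "1", 8 * b, 2 * b)
                self._dense(t + "2", 2 * b, 3)

    def forward(self, features) -> dict:
        """Map (B,N,F) observation features to a dict of action Tensors.

        Deformation is (B,N,3); rigid heads are (B,3).
        """
        feats = self._as_batched(features)
        self._check_width(feats)
        local, glob = self._trunk(feats)
        B, N, C = local.data.shape
        skip = concat([local, glob.reshape(B, 1, C).broadcast_to((B, N, C))], axis=-1)
        out: dict = {}
        if "deformation" in self.cfg.action_types:
            h = self._apply("def1", skip)
            out["deformation"] = self._apply("def2", h, activation="linear")
        for t in ("translation", "scale", "rotation"):
            if t in self.cfg.action_types:
                h = self._apply(t + "1", skip).max(axis=1)  # pooled head (duplication-safe)
                out[t] = self._apply(t + "2", h, activation="linear")
        return out

    def propose(self, obs: Observation) -> ActionSet:
        """Numpy convenience wrapper for a single observation."""
        out = self.forward(obs.features)
        kw = {k: np.asarray(v.data[0]) for k, v in out.items()}
        return ActionSet(stage="normalized", **kw)


class ValueNetwork(_Net):
    """Q(o, a) per action: the action is concatenated onto every vertex row
    (rigid 3-vectors broadcast, deformation rows as-is) together with a
    one-hot type code before the shared trunk, so action/observation
    alignment is judged at vertex resolution before pooling."""

    def __init__(self, cfg: NetConfig):
        super().__init__(cfg)
        b = cfg.base
        self._dense("enc1", cfg.feature_width + 3 + len(ACTION_TYPES), b)
        self._dense("enc2", b, 2 * b)
        self._dense("enc3", 2 * b, 4 * b)
        self._dense("q1", 4 * b, 2 * b)
        self._dense("q2", 2 * b, 1)

    def forward(self, features, actions: dict) -> dict:
        """Q value per supplied action; each Q is a (B,) Tensor."""
        feats = self._as_batched(features)
        self._check_width(feats)
        B, N, _ = feats.data.shape
        out = {}
        for t, v in actions.items():
            if t not in ACTION_TYPES:
                raise InvalidInputError(f"unknown action type {t!r}")
            vt = Tensor.as_tensor(v)
            if t == "deformation":
                if vt.data.ndim == 2:
                    vt = vt.reshape(1, *vt.data.shape)
                act_rows = vt
            else:
                if vt.data.ndim == 1:
                    vt = vt.reshape(1, 3)
                act_rows = vt.reshape(B, 1, 3).broadcast_to((B, N, 3))
            onehot = np.zeros((B, N, len(ACTION_TYPES)))
            onehot[:, :, ACTION_TYPES.index(t)] = 1.0
            x = concat([feats, act_rows, Tensor(onehot)], axis=-1)
            _, glob = self._trunk(x)
            h = self._apply("q1", glob)
            out[t] = self._apply("q2", h, activation="linear").reshape(B)
        return out

    def score(self, obs: Observation, actions: ActionSet) -> dict:
        """Numpy convenience wrapper: Q per action type for one observation."""
        avail = {t: actions.get(t) for t in actions.types()}
        out = self.forward(obs.features, avail)
        return {k: float(v.data[0]) for k, v in out.items()}


# ---------------------------------------------------------------------------
# losses


def action_loss(pred: dict, target: dict, lam1: float, beta: float) -> Tensor:
    """Imitation loss: squared error to the beta-scaled targets plus a
    regularizer pulling each predicted action's norm toward beta.

    ``pred`` maps action type -> Tensor ((B,3) or (B,N,3)); ``target`` maps
    action type -> numpy array of identical shape.
    """
    total = None
    for t, p in pred.items():
        if t not in target:
            continue
        tgt = np.asarray(target[t], dtype=np.float64)
        if tgt.shape != p.data.shape:
            raise InvalidInputError(f"target shape mismatch for {t!r}")
        axes = tuple(range(1, p.data.ndim))
        sq = (p - Tensor(tgt)).square().sum(axis=axes) if p.data.ndim > 1 else (p - Tensor(tgt)).square().sum()
        term = sq
        if lam1 != 0.0:
            if p.data.ndim == 3:
                # deformation: its normalized magnitude is the max row norm
                norm = p.square().sum(axis=-1).sqrt().max(axis=1)
            else:
                norm = p.square().sum(axis=axes).sqrt()
            term = term + lam1 * (norm - beta).square()
        total = term if total is None else total + term
    if total is None:
        raise InvalidInputError("no overlapping action types between pred and target")
    return total.mean() if total.data.ndim > 0 else total


def distance_loss(moved_vertices: Tensor, targets: np.ndarray, lam2: float) -> Tensor:
    """Auxiliary distance loss: mean distance of moved vertices to their
    (fixed) nearest ground-truth correspondences, scaled by lam2.

    ``moved_vertices`` is (B,N,3) or (N,3); ``targets`` the matching
    correspondence array.
    """
    v = moved_vertices if isinstance(moved_vertices, Tensor) else Tensor(moved_vertices)
    tgt = np.asarray(targets, dtype=np.float64)
    if tgt.shape != v.data.shape:
        raise InvalidInputError("correspondence shape mismatch")
    d = (v - Tensor(tgt)).square().sum(axis=-1).sqrt()
    return d.mean() * lam2


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, actor: ActorNetwork | None = None, value: ValueNetwork | None = None,
                    target_value: ValueNetwork | None = None, config: dict | None = None) -> None:
    """Self-describing npz archive with parameters and a config echo."""
    arrays = {}
    meta = {"format_version": 1, "config": config or {}}
    for prefix, net in (("actor", actor), ("value", value), ("target", target_value)):
        if net is None:
            continue
        meta[prefix + "_cfg"] = {
            "feature_width": net.cfg.feature_width,
            "base": net.cfg.base,
            "action_types": list(net.cfg.action_types),
            "seed": net.cfg.seed,
        }
        for k, v in net.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> dict:
    """Load a checkpoint archive -> dict with nets and the config echo."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        out = {"config": meta.get("config", {})}
        for prefix, cls, key in (
            ("actor", ActorNetwork, "actor"),
            ("value", ValueNetwork, "value"),
            ("target", ValueNetwork, "target_value"),
        ):
            cfg_meta = meta.get(prefix + "_cfg")
            if cfg_meta is None:
                continue
            cfg = NetConfig(
                feature_width=cfg_meta["feature_width"],
                base=cfg_meta["base"],
                action_types=tuple(cfg_meta["action_types"]),
                seed=cfg_meta["seed"],
            )
            net = cls(cfg)
            state = {
                k.split("/", 1)[1]: data[k]
                for k in data.files
                if k.startswith(prefix + "/")
            }
            net.load_state_dict(state)
            out[key] = net
    return out
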