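"""Analytic demonstrator: optimal actions toward the ground truth.

Given the current estimate cloud V and the ground-truth cloud G, the
demonstrator computes the optimal translation, per-axis scale, rotation and
smooth per-vertex deformation that move V toward G.  Because the symmetric
objective has no closed form, each action is solved with one-sided
nearest-neighbour correspondences refreshed ICP-style for a bounded number
of iterations.  No vertex correspondence between V and G is assumed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from actseg.actions import (
    ActionScale,
    ActionSet,
    apply_beta,
    euler_to_matrix,
    matrix_to_euler,
    normalize_action_set,
)
from actseg.geometry import InvalidInputError, PointCloud, one_sided_distance

__all__ = [
    "correspondences",
    "optimal_translation",
    "optimal_scale",
    "optimal_rotation",
    "optimal_deformation",
    "Demonstrator",
]

logger = logging.getLogger(__name__)

_MAX_ITER = 20
_TOL = 1e-6


def _points(X) -> np.ndarray:
    return X.points if isinstance(X, PointCloud) else np.atleast_2d(np.asarray(X, float))


def correspondences(V, G) -> np.ndarray:
    """For each v_i the nearest point of G (ties: lowest index)."""
    g = _points(G)
    if len(g) == 0:
        raise InvalidInputError("empty ground truth")
    _, idx = cKDTree(g).query(_points(V))
    return g[idx]


def _best_iterate(candidates: list, evaluate) -> int:
    """Index of the candidate with the lowest one-sided distance.

    The ICP-style solvers minimize a squared objective per iteration; keeping
    the best-seen iterate (the identity action is always a candidate) makes
    each optimal action non-increasing in the unsquared mean distance.
    """
    dists = [evaluate(c) for c in candidates]
    return int(np.argmin(dists))


def optimal_translation(V, G) -> np.ndarray:
    """Translation minimizing the one-sided V->G distance (ICP iterations)."""
    v = _points(V)
    t = np.zeros(3)
    cands = [t]
    for _ in range(_MAX_ITER):
        c = correspondences(v + t, G)
        step = (c - (v + t)).mean(axis=0)
        t = t + step
        cands.append(t)
        if np.linalg.norm(step) < _TOL:
            break
    best = _best_iterate(cands, lambda t_: one_sided_distance(v + t_, G))
    return cands[best]


def optimal_scale(V, G, clamp=(0.2, 5.0)) -> np.ndarray:
    """Per-axis scale about the centroid of V (least squares, ICP refresh)."""
    v = _points(V)
    center = v.mean(axis=0)
    vc = v - center
    s = np.ones(3)
    cands = [s]
    for _ in range(_MAX_ITER):
        cur = center + vc * s
        c = correspondences(cur, G) - center
        denom = np.sum(vc * vc, axis=0)
        num = np.sum(c * vc, axis=0)
        new_s = np.ones(3)
        flat = denom < 1e-12
        if np.any(flat):
            logger.warning("flat axis in optimal_scale; scale fixed to 1 there")
        new_s[~flat] = num[~flat] / denom[~flat]
        new_s = np.clip(new_s, clamp[0], clamp[1])
        converged = np.max(np.abs(new_s - s)) < _TOL
        s = new_s
        cands.append(s)
        if converged:
            break
    best = _best_iterate(cands, lambda s_: one_sided_distance(center + vc * s_, G))
    return cands[best]


def optimal_rotation(V, G) -> np.ndarray:
    """Euler angles (X.Y.Z) of the best rotation about the centroid of V."""
    v = _points(V)
    center = v.mean(axis=0)
    vc = v - center
    R_total = np.eye(3)
    cands = [R_total]
    for _ in range(_MAX_ITER):
        cur = center + vc @ R_total.T
        c = correspondences(cur, G) - center
        H = (vc @ R_total.T).T @ c
        U, S, Wt = np.linalg.svd(H)
        if S[1] < 1e-9:  # rank-deficient: rotation ill-determined
            logger.warning("degenerate configuration in optimal_rotation; identity returned")
            return np.zeros(3)
        d = np.sign(np.linalg.det(Wt.T @ U.T))
        R_step = Wt.T @ np.diag([1.0, 1.0, d]) @ U.T
        R_total = R_step @ R_total
        cands.append(R_total)
        # incremental angle
        ang = np.arccos(np.clip((np.trace(R_step) - 1.0) / 2.0, -1.0, 1.0))
        if ang < 1e-7:
            break
    best = _best_iterate(cands, lambda R: one_sided_distance(center + vc @ R.T, G))
    return matrix_to_euler(cands[best])


def graph_laplacian(neighbors: list, n: int) -> sparse.csr_matrix:
    """Combinatorial Laplacian L = D - A of a symmetric neighborhood graph."""
    rows, cols = [], []
    for i, nb in enumerate(neighbors):
        for j in nb:
            rows.append(i)
            cols.append(int(j))
    data = np.ones(len(rows))
    A = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # enforce symmetry
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sparse.diags(deg) - A


def optimal_deformation(V, G, lam: float, neighbors: list | None = None) -> np.ndarray:
    """Smooth per-vertex displacement field toward G.

    With fixed nearest-point correspondences C, minimizes
    ``sum_i ||d_i + v_i - c_i||^2 + lam * sum_i sum_{j in N(i)} ||d_j - d_i||^2``
    exactly per coordinate by solving ``(I + 2*lam*L) d = (C - V)`` where L is
    the graph Laplacian (each unordered edge appears in both directed sums).
    One correspondence refresh pass is performed (2 solves total).
    """
    if lam < 0:
        raise InvalidInputError("lambda must be >= 0")
    v = _points(V)
    if neighbors is None:
        neighbors = getattr(V, "neighbors", None)
    n = len(v)
    D = np.zeros_like(v)
    if lam == 0 or neighbors is None:
        for _ in range(2):
            D = correspondences(v + D, G) - v
        return D
    L = graph_laplacian(neighbors, n)
    A = (sparse.identity(n) + 2.0 * lam * L).tocsc()
    for _ in range(2):
        rhs = correspondences(v + D, G) - v
        D = np.column_stack([spsolve(A, rhs[:, k]) for k in range(3)])
    return D


class Demonstrator:
    """Supervision source producing raw, normalized and beta-scaled targets."""

    def __init__(
        self,
        scale_cfg: ActionScale | None = None,
        lam: float = 1.0,
        beta: float = 1.0,
        action_types: tuple = ("translation", "scale", "rotation", "deformation"),
    ) -> None:
        self.scale_cfg = scale_cfg or ActionScale()
        self.lam = float(lam)
        self.beta = float(beta)
        self.action_types = tuple(action_types)

    def optimal_actions(self, V: PointCloud, G) -> ActionSet:
        kw = {}
        if "translation" in self.action_types:
            kw["translation"] = optimal_translation(V, G)
        if "scale" in self.action_types:
            kw["scale"] = optimal_scale(V, G)
        if "rotation" in self.action_types:
            kw["rotation"] = optimal_rotation(V, G)
        if "deformation" in self.action_types:
            kw["deformation"] = optimal_deformation(V, G, self.lam, getattr(V, "neighbors", None))
        return ActionSet(stage="raw", **kw)

    def targets(self, V: PointCloud, G) -> ActionSet:
        """Beta-scaled normalized optimal actions (the imitation targets)."""
        raw = self.optimal_actions(V, G)
        return apply_beta(normalize_action_set(raw, self.scale_cfg), self.beta)


def rotation_matrix_from_action(angles) -> np.ndarray:
    """Convenience re-export used by tests."""
    return euler_to_matrix(angles)
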