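"""Statistical shape model built by iterative CPD template registration,
plus the mesh augmentation pipeline used to generate training estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from actseg.actions import euler_to_matrix
from actseg.geometry import InvalidInputError, PointCloud, SurfaceMesh

__all__ = [
    "ShapeModel",
    "cpd_nonrigid",
    "build_ssm",
    "AugmentConfig",
    "augment_mesh",
    "random_initial_placement",
]

logger = logging.getLogger(__name__)


def _pts(X) -> np.ndarray:
    return X.points if isinstance(X, PointCloud) else np.atleast_2d(np.asarray(X, float))


def cpd_nonrigid(
    template,
    sample,
    w_outlier: float = 0.1,
    beta_cpd: float | None = None,
    lam_cpd: float = 3.0,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Coherent point drift: move the template onto the sample.

    Standard nonrigid CPD EM (Gaussian mixture with annealed variance; the
    displacement field is a Gaussian kernel of width ``beta_cpd`` times
    weights solving the ``lam_cpd``-regularized M-step system).  Vertex count
    and ordering of the template are preserved.  ``beta_cpd`` defaults to
    twice the template's mean nearest-neighbour spacing.
    """
    Y = _pts(template)
    X = _pts(sample)
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(X))):
        raise InvalidInputError("non-finite coordinates in CPD input")
    N, M = len(Y), len(X)
    if beta_cpd is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(Y).query(Y, k=min(2, N))
        spacing = float(np.mean(d[:, -1])) if N > 1 else 1.0
        beta_cpd = 2.0 * spacing

    diff_yy = Y[:, None, :] - Y[None, :, :]
    Gk = np.exp(-np.sum(diff_yy**2, axis=-1) / (2.0 * beta_cpd**2))
    W = np.zeros((N, 3))
    sigma2 = np.sum((X[None, :, :] - Y[:, None, :]) ** 2) / (3.0 * M * N)

    prev_sigma2 = np.inf
    for _ in range(max_iter):
        T = Y + Gk @ W
        d2 = np.sum((X[None, :, :] - T[:, None, :]) ** 2, axis=-1)  # (N, M)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** 1.5 * w_outlier / max(1.0 - w_outlier, 1e-12) * N / M
        denom = num.sum(axis=0) + c
        P = num / np.maximum(denom, 1e-300)[None, :]
        P1 = P.sum(axis=1)
        Np = P1.sum()
        if Np < 1e-12:
            break
        PX = P @ X
        A = Gk * P1[:, None] + lam_cpd * sigma2 * np.eye(N)
        W = np.linalg.solve(A, PX - P1[:, None] * Y)
        T = Y + Gk @ W
        Pt1 = P.sum(axis=0)
        xPx = float(Pt1 @ np.sum(X * X, axis=1))
        trPXT = float(np.sum(PX * T))
        tTt = float(P1 @ np.sum(T * T, axis=1))
        sigma2 = max((xPx - 2.0 * trPXT + tTt) / (3.0 * Np), 1e-10)
        if abs(prev_sigma2 - sigma2) < tol:
            break
        prev_sigma2 = sigma2

    moved = Y + Gk @ W
    if isinstance(template, PointCloud):
        return template.with_points(moved)
    return moved


@dataclass
class ShapeModel:
    """Mean shape + orthonormal modes of variation (columns of ``modes``)."""

    mean_mesh: SurfaceMesh
    modes: np.ndarray  # (3N, K), unit columns, mutually orthogonal
    mode_scales: np.ndarray  # (K,) standard deviations, non-increasing

    def sample_displacement(self, z: np.ndarray) -> np.ndarray:
        """Vertex displacement field for standardized coefficients z (K,)."""
        z = np.asarray(z, dtype=np.float64)
        disp = self.modes @ (z * self.mode_scales)
        return disp.reshape(-1, 3)


def build_ssm(samples: list, n_outer: int = 3, variance_kept: float = 0.95, **cpd_kwargs) -> ShapeModel:
    """Iterative template-to-sample CPD registration, then PCA of shapes.

    The first sample serves as the initial template; each outer round
    registers the current template to every sample and replaces the template
    vertices by the mean of the registered results.  Modes covering at least
    ``variance_kept`` of the variance are retained.
    """
    if len(samples) < 3:
        raise InvalidInputError("SSM needs at least 3 samples")
    template = samples[0].copy()
    registered = None
    for _ in range(n_outer):
        registered = [cpd_nonrigid(template, s, **cpd_kwargs).points for s in samples]
        template = template.with_points(np.mean(registered, axis=0))
    data = np.stack([r.reshape(-1) for r in registered])  # (S, 3N)
    mean = data.mean(axis=0)
    centered = data - mean
    U, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    scales = svals / np.sqrt(max(len(samples) - 1, 1))
    var = scales**2
    total = var.sum()
    if total < 1e-18:
        keep = 1
    else:
        keep = int(np.searchsorted(np.cumsum(var) / total, variance_kept) + 1)
        keep = min(keep, len(scales))
    mean_mesh = template.with_points(mean.reshape(-1, 3))
    return ShapeModel(mean_mesh, Vt[:keep].T.copy(), scales[:keep].copy())


@dataclass
class AugmentConfig:
    mode_trunc: float = 3.0
    translation_mm: float = 10.0
    scale_range: tuple = (0.9, 1.1)
    rotation_deg: float = 10.0
    jitter_mm: float = 0.5
    smooth_strength: float = 0.5
    smooth_passes: int = 1


def _laplacian_smooth(mesh: SurfaceMesh, strength: float, passes: int) -> np.ndarray:
    pts = mesh.points.copy()
    for _ in range(passes):
        avg = np.stack([pts[nb].mean(axis=0) if len(nb) else pts[i] for i, nb in enumerate(mesh.neighbors)])
        pts = (1.0 - strength) * pts + strength * avg
    return pts


def augment_mesh(
    G: SurfaceMesh,
    ssm: ShapeModel | None,
    rng: np.random.Generator,
    cfg: AugmentConfig | None = None,
) -> SurfaceMesh:
    """Training-estimate generator: modes + random affine + jitter + smoothing."""
    cfg = cfg or AugmentConfig()
    pts = G.points.copy()
    if ssm is not None:
        if ssm.modes.shape[0] != pts.size:
            raise InvalidInputError("shape model topology does not match mesh")
        z = np.clip(rng.standard_normal(len(ssm.mode_scales)), -cfg.mode_trunc, cfg.mode_trunc)
        pts = pts + ssm.sample_displacement(z)
    # random affine about the centroid
    c = pts.mean(axis=0)
    s = rng.uniform(cfg.scale_range[0], cfg.scale_range[1], size=3)
    angles = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, size=3))
    t = rng.uniform(-cfg.translation_mm, cfg.translation_mm, size=3)
    pts = c + (pts - c) * s
    pts = c + (pts - c) @ euler_to_matrix(angles).T
    pts = pts + t
    if cfg.jitter_mm > 0:
        pts = pts + rng.normal(0.0, cfg.jitter_mm, size=pts.shape)
    out = G.with_points(pts)
    if cfg.smooth_passes > 0 and cfg.smooth_strength > 0:
        out = out.with_points(_laplacian_smooth(out, cfg.smooth_strength, cfg.smooth_passes))
    return out


def random_initial_placement(
    template: SurfaceMesh,
    rng: np.random.Generator,
    max_shift_mm: float = 40.0,
    ssm: ShapeModel | None = None,
) -> SurfaceMesh:
    """Template reshaped by random modes, shifted uniformly in a cube."""
    pts = template.points.copy()
    if ssm is not None and len(ssm.mode_scales) > 0:
        z = rng.standard_normal(len(ssm.mode_scales))
        pts = pts + ssm.sample_displacement(np.clip(z, -3, 3))
    shift = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    return template.with_points(pts + shift)
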