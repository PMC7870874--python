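"""Per-step observation encoding: image features + point features per vertex.

Two modes are provided.  Surface mode samples intensities at equidistant
positions along each vertex normal (default 61 samples, 1 mm apart).  Patch
mode samples an axis-aligned sub-volume of world-mm-spaced positions centered
at each point (default 7x7x7), used for unstructured landmark clouds.

Image features are normalized to zero mean / unit standard deviation; point
positions are normalized into the unit sphere.  Patch mode normalizes image
features per point and centers positions at the bounding-box center so that
duplicating input points leaves the rows of the original points unchanged
(required for landmark-duplication padding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from actseg.geometry import (
    InvalidInputError,
    PointCloud,
    SurfaceMesh,
    Volume,
    compute_normals,
    sample_trilinear,
)

__all__ = [
    "Observation",
    "encode_surface_observation",
    "encode_pointcloud_observation",
    "normalize_points_unit_sphere",
]

logger = logging.getLogger(__name__)


@dataclass
class Observation:
    """Per-vertex features: ``image_features`` (N x K) and ``point_features``.

    ``point_features`` is N x 3 (unit-sphere positions) or N x 6 when vertex
    normals are appended.  ``center``/``radius`` undo the point normalization;
    ``img_mean``/``img_std`` record the image-feature normalization.
    """

    image_features: np.ndarray
    point_features: np.ndarray
    center: np.ndarray
    radius: float
    img_mean: float
    img_std: float

    @property
    def features(self) -> np.ndarray:
        """Full per-vertex feature block (N x (K + 3 or 6))."""
        return np.concatenate([self.image_features, self.point_features], axis=1)

    @property
    def n_vertices(self) -> int:
        return self.image_features.shape[0]

    @property
    def width(self) -> int:
        return self.image_features.shape[1] + self.point_features.shape[1]


def normalize_points_unit_sphere(points: np.ndarray, method: str = "centroid"):
    """Scale points into the closed unit ball.

    Returns ``(normalized, center, radius)`` with
    ``normalized = (points - center) / radius`` and
    ``radius = max_i ||p_i - center||`` (1 if all points coincide).
    ``method='bbox'`` uses the bounding-box center, which is invariant to
    duplicated points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if method == "bbox":
        center = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    elif method == "centroid":
        center = pts.mean(axis=0)
    else:
        raise InvalidInputError(f"unknown normalization method {method!r}")
    shifted = pts - center
    radius = float(np.max(np.linalg.norm(shifted, axis=1)))
    if radius <= 0.0:
        radius = 1.0
    return shifted / radius, center, radius


def _normalize_image_block(raw: np.ndarray, per_vertex: bool):
    """Zero-mean / unit-std normalization with a zero-variance guard."""
    if per_vertex:
        mean = raw.mean(axis=1, keepdims=True)
        std = raw.std(axis=1, keepdims=True)
        dead = std[:, 0] < 1e-12
        if np.any(dead):
            logger.warning("zero-variance image features for %d points", int(dead.sum()))
            std = np.where(std < 1e-12, 1.0, std)
            out = (raw - mean) / std
            out[dead] = 0.0
        else:
            out = (raw - mean) / std
        return out, float(raw.mean()), float(raw.std())
    mean, std = float(raw.mean()), float(raw.std())
    if std < 1e-12:
        logger.warning("zero-variance image features; observation zeroed")
        return np.zeros_like(raw), mean, 0.0
    return (raw - mean) / std, mean, std


def encode_surface_observation(
    mesh: SurfaceMesh,
    vol: Volume,
    n_samples: int = 61,
    spacing_mm: float = 1.0,
) -> Observation:
    """Observation for a surface mesh: ray samples along each vertex normal.

    Per vertex, intensities are sampled at ``v_i + j * spacing_mm * n_i`` for
    ``j in {-(n-1)/2 .. (n-1)/2}``; the vertex itself is the central sample.
    Point features are unit-sphere positions concatenated with normals, so
    the per-vertex feature width is ``n_samples + 6``.
    """
    if n_samples % 2 != 1:
        raise InvalidInputError("n_samples must be odd so the vertex is a sample")
    if mesh.normals is None:
        mesh = compute_normals(mesh)
    n = len(mesh)
    half = (n_samples - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64) * spacing_mm
    # (N, K, 3) sample positions
    positions = mesh.points[:, None, :] + offsets[None, :, None] * mesh.normals[:, None, :]
    vals, _ = sample_trilinear(vol, positions.reshape(-1, 3))
    raw = vals.reshape(n, n_samples)
    img, mean, std = _normalize_image_block(raw, per_vertex=False)
    npts, center, radius = normalize_points_unit_sphere(mesh.points, method="centroid")
    point_features = np.concatenate([npts, mesh.normals], axis=1)
    return Observation(img, point_features, center, radius, mean, std)


def encode_pointcloud_observation(
    cloud: PointCloud,
    vol: Volume,
    patch: tuple = (7, 7, 7),
    step_mm: float = 1.0,
) -> Observation:
    """Observation for an unstructured cloud: a world-axis patch per point.

    The patch is a ``patch[0] x patch[1] x patch[2]`` grid of trilinear
    samples spaced ``step_mm`` apart and centered on the point, vectorized
    to one row.  No normals are used.
    """
    patch = tuple(int(p) for p in patch)
    if any(p < 1 or p % 2 != 1 for p in patch):
        raise InvalidInputError("patch dims must be odd and >= 1")
    n = len(cloud)
    axes = [np.arange(-(p - 1) // 2, (p - 1) // 2 + 1, dtype=np.float64) * step_mm for p in patch]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    stencil = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)  # (K, 3)
    positions = cloud.points[:, None, :] + stencil[None, :, :]
    vals, _ = sample_trilinear(vol, positions.reshape(-1, 3))
    raw = vals.reshape(n, len(stencil))
    img, mean, std = _normalize_image_block(raw, per_vertex=True)
    npts, center, radius = normalize_points_unit_sphere(cloud.points, method="bbox")
    return Observation(img, npts, center, radius, mean, std)
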