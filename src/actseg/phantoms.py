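"""Seeded synthetic phantoms: volumes, ground-truth meshes, labels, landmarks.

The "organ" is a star-convex blob: a sphere whose radius is modulated by a
smooth band-limited function of direction (linear + traceless quadratic
form), guaranteeing a watertight mesh and exact voxel inside-tests.
Modality variants change appearance (contrast inversion, bias field) without
moving the boundary.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from actseg.geometry import InvalidInputError, SurfaceMesh, Volume, compute_normals, icosphere

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "log_filter",
    "DeformationFixture",
    "generate_deformation_fixture",
]

MODALITIES = ("ct_like", "cect_like", "mr_like")


@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    spacing: tuple = (2.0, 2.0, 2.0)
    center_mm: tuple | None = None  # default: volume center
    radius_mm: float = 25.0
    perturb_amp_mm: float = 3.0
    interior: float = 0.75
    exterior: float = 0.25
    noise_sigma: float = 0.03
    gradient: float = 0.05  # fraction of contrast added as a z ramp
    modality: str = "ct_like"
    mesh_subdivisions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InvalidInputError(f"modality must be one of {MODALITIES}")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        if self.radius_mm + self.perturb_amp_mm >= extent.min() / 2:
            raise InvalidInputError("organ radius must fit inside half the volume extent")

    @property
    def center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=np.float64)
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0


def _radial_modulation(rng: np.random.Generator):
    """Smooth band-limited direction function g(u) with max |g| = 1."""
    a = rng.normal(size=3)
    B = rng.normal(size=(3, 3))
    B = 0.5 * (B + B.T)
    B -= np.eye(3) * np.trace(B) / 3.0

    def g(u: np.ndarray) -> np.ndarray:
        lin = u @ a
        quad = np.einsum("...i,ij,...j->...", u, B, u)
        return lin + quad

    # normalize by the max over a dense direction sample (deterministic)
    probe = icosphere(3).points
    scale = float(np.max(np.abs(g(probe))))
    if scale < 1e-9:
        scale = 1.0
    return lambda u: g(u) / scale


def _boundary_radius(spec: PhantomSpec, g) -> callable:
    return lambda u: spec.radius_mm + spec.perturb_amp_mm * g(u)


def generate_phantom(spec: PhantomSpec):
    """Return ``(volume, ground_truth_mesh, label_volume)``."""
    rng = np.random.default_rng(spec.seed)
    g = _radial_modulation(rng)
    rad = _boundary_radius(spec, g)

    affine = np.eye(4)
    affine[:3, :3] = np.diag(spec.spacing)
    center = spec.center

    # voxel-center world coordinates
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij"),
        axis=-1,
    )
    world = grid * np.asarray(spec.spacing)
    delta = world - center
    dist = np.linalg.norm(delta, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dist[..., None] > 1e-9, delta / np.maximum(dist, 1e-9)[..., None], 0.0)
    inside = dist <= rad(u)

    labels = Volume(inside.astype(np.float64), affine)

    contrast = spec.interior - spec.exterior
    data = np.where(inside, spec.interior, spec.exterior)
    ramp = (world[..., 2] - world[..., 2].mean()) / max(np.ptp(world[..., 2]), 1e-9)
    data = data + spec.gradient * contrast * ramp
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    if spec.modality == "mr_like":
        # inverted contrast + smooth multiplicative bias field
        data = data.max() + data.min() - data
        bias = 1.0 + 0.2 * np.sin(world[..., 0] / 40.0) * np.cos(world[..., 1] / 50.0)
        data = data * bias
    elif spec.modality == "cect_like":
        data = np.where(inside, data + 0.5 * contrast, data)

    vol = Volume(data, affine)

    sphere = icosphere(spec.mesh_subdivisions)
    dirs = sphere.points  # unit vectors
    pts = center + dirs * rad(dirs)[:, None]
    mesh = compute_normals(SurfaceMesh(pts, None, sphere.faces))
    return vol, mesh, labels


def log_filter(vol: Volume, sigma_mm: float) -> Volume:
    """Laplacian-of-Gaussian with physical sigma, then zero-mean/unit-var."""
    if sigma_mm <= 0:
        raise InvalidInputError("sigma must be > 0")
    sigma_vox = sigma_mm / vol.spacing
    out = ndimage.gaussian_laplace(vol.data, sigma=sigma_vox)
    std = out.std()
    if std < 1e-12:
        return Volume(np.zeros_like(out), vol.affine.copy())
    return Volume((out - out.mean()) / std, vol.affine.copy())


# ---------------------------------------------------------------------------
# smooth deformation fixtures (registration test bed)


@dataclass
class DeformationFixture:
    volume: Volume
    deformed_volume: Volume
    fixed_landmarks: np.ndarray  # true positions (n, 3)
    moving_landmarks: np.ndarray  # displaced initial positions (n, 3)
    field: callable = field(repr=False, default=None)
    max_magnitude_mm: float = 0.0
    lipschitz_bound: float = 0.0


def generate_deformation_fixture(
    spec: PhantomSpec | None = None,
    n_landmarks: int = 15,
    n_bumps: int = 4,
    magnitude_mm: float = 10.0,
    bump_width_mm: tuple = (35.0, 60.0),
    min_separation_mm: float = 18.0,
    feature_sigma_mm: float = 2.5,
    feature_amp: float = 0.6,
    seed: int = 0,
) -> DeformationFixture:
    """Landmark pairs under a smooth random displacement field.

    The field is a sum of <= 5 wide Gaussian bumps, rescaled so its maximum
    magnitude over the volume equals ``magnitude_mm``.  Landmarks are
    well-separated random positions, each marked by a small bright Gaussian
    feature stamped into the volume (standing in for the distinctive
    anatomical features that clinical landmark sets annotate) so that local
    patches identify the landmark offset in all three directions;
    ``moving = fixed + field(fixed)``.  A copy of the phantom volume with the
    field baked in (backward warp) is also produced.
    """
    if n_bumps < 1 or n_bumps > 5:
        raise InvalidInputError("n_bumps must be in 1..5")
    spec = spec or PhantomSpec(seed=seed)
    vol, mesh, _ = generate_phantom(spec)
    rng = np.random.default_rng(seed + 17)

    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    centers = rng.uniform(0.2, 0.8, size=(n_bumps, 3)) * extent
    widths = rng.uniform(*bump_width_mm, size=n_bumps)
    amps = rng.normal(size=(n_bumps, 3))

    def raw_field(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        out = np.zeros_like(x)
        for c, w, a in zip(centers, widths, amps):
            r2 = np.sum((x - c) ** 2, axis=1)
            out += np.exp(-r2 / (2 * w * w))[:, None] * a
        return out

    # normalize the max magnitude over the voxel grid
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3) * np.asarray(spec.spacing)
    mags = np.linalg.norm(raw_field(grid), axis=1)
    scale = magnitude_mm / max(float(mags.max()), 1e-12)

    def fld(x: np.ndarray) -> np.ndarray:
        return raw_field(x) * scale

    lip = float(scale * np.sum(np.linalg.norm(amps, axis=1) / (widths * np.sqrt(np.e))))

    # landmark positions: rejection-sampled for pairwise separation
    fixed = []
    margin = 0.18 * extent
    for _ in range(10_000):
        if len(fixed) == n_landmarks:
            break
        cand = rng.uniform(margin, extent - margin)
        if all(np.linalg.norm(cand - f) >= min_separation_mm for f in fixed):
            fixed.append(cand)
    if len(fixed) < n_landmarks:
        raise InvalidInputError("could not place landmarks with requested separation")
    fixed = np.array(fixed)

    # stamp a bright feature at each fixed landmark
    grid3 = None
    if feature_amp != 0.0:
        data = vol.data.copy()
        grid3 = np.stack(
            np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij"),
            axis=-1,
        ) * np.asarray(spec.spacing)
        for f in fixed:
            r2 = np.sum((grid3 - f) ** 2, axis=-1)
            data += feature_amp * np.exp(-r2 / (2 * feature_sigma_mm**2))
        vol = Volume(data, vol.affine)

    if magnitude_mm > 0:
        warped = ndimage.map_coordinates(
            vol.data,
            ((grid - fld(grid)) / np.asarray(spec.spacing)).T,
            order=1,
            mode="nearest",
        ).reshape(spec.shape)
    else:
        warped = vol.data.copy()
    deformed = Volume(warped, vol.affine.copy())

    moving = fixed + fld(fixed)
    return DeformationFixture(vol, deformed, fixed, moving, fld, magnitude_mm, lip)
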