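"""Point-cloud / mesh data model, coordinate transforms, distances, neighborhoods.

All public coordinates are world millimetres in a RAS+ frame; voxel indices
only appear inside :class:`Volume` helpers.  Meshes are triangle meshes; the
neighborhood of a mesh vertex is the set of vertices sharing a face with it,
while unstructured clouds use a symmetrized k-nearest-neighbour graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Volume",
    "PointCloud",
    "SurfaceMesh",
    "symmetric_distance",
    "one_sided_distance",
    "point_distance",
    "build_knn_neighborhood",
    "face_neighborhood",
    "compute_normals",
    "world_to_voxel",
    "voxel_to_world",
    "sample_trilinear",
    "icosphere",
]


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# types


@dataclass
class Volume:
    """A 3D intensity grid with a voxel-to-world (RAS+) affine.

    Parameters
    ----------
    data:
        3D array of intensities, indexed ``[i, j, k]``.
    affine:
        4x4 matrix mapping homogeneous voxel indices to world mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise InvalidInputError("volume data must be 3D")
        if self.affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InvalidInputError("volume affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class PointCloud:
    """N points in world mm, with an optional symmetric neighborhood graph."""

    points: np.ndarray
    neighbors: list | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("points must be N x 3")
        if len(self.points) < 1:
            raise InvalidInputError("point cloud must be non-empty")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def copy(self) -> "PointCloud":
        nb = None if self.neighbors is None else [np.array(n) for n in self.neighbors]
        return PointCloud(self.points.copy(), nb)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same connectivity, new coordinates."""
        out = self.copy()
        out.points = np.array(points, dtype=np.float64)
        if out.points.shape != self.points.shape:
            raise InvalidInputError("replacement points must keep shape")
        return out


@dataclass
class SurfaceMesh(PointCloud):
    """Triangle mesh: a point cloud plus faces and (optional) vertex normals."""

    faces: np.ndarray = field(default=None)
    normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.faces is None:
            raise InvalidInputError("mesh requires faces")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidInputError("faces must be F x 3")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.points):
            raise InvalidInputError("face indices out of range")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
        if self.neighbors is None:
            self.neighbors = face_neighborhood(self.faces, len(self.points))

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.points.copy(),
            [np.array(n) for n in self.neighbors] if self.neighbors else None,
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )

    def with_points(self, points: np.ndarray) -> "SurfaceMesh":
        out = self.copy()
        pts = np.array(points, dtype=np.float64)
        if pts.shape != self.points.shape:
            raise InvalidInputError("replacement points must keep shape")
        out.points = pts
        out.normals = None  # stale after motion
        return out

    def is_watertight(self) -> bool:
        """Every undirected edge is shared by exactly two faces."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


# ---------------------------------------------------------------------------
# distances


def _check_cloud(P) -> np.ndarray:
    pts = P.points if isinstance(P, PointCloud) else np.atleast_2d(np.asarray(P, float))
    if len(pts) == 0:
        raise InvalidInputError("empty point cloud")
    return pts


def one_sided_distance(A, B) -> float:
    """Mean over a in A of the distance to the nearest point of B (mm)."""
    a, b = _check_cloud(A), _check_cloud(B)
    d, _ = cKDTree(b).query(a)
    return float(np.mean(d))


def symmetric_distance(A, B) -> float:
    """Average symmetric nearest-neighbour distance between two clouds (mm)."""
    return 0.5 * (one_sided_distance(A, B) + one_sided_distance(B, A))


def point_distance(p, B) -> tuple:
    """Distance of one point to its nearest neighbour in B, with the index.

    Ties are broken toward the lowest index.
    """
    b = _check_cloud(B)
    p = np.asarray(p, dtype=np.float64)
    d = np.linalg.norm(b - p[None, :], axis=1)
    idx = int(np.argmin(d))  # argmin returns the first (lowest) minimiser
    return float(d[idx]), idx


# ---------------------------------------------------------------------------
# neighborhoods


def build_knn_neighborhood(P: PointCloud, k: int) -> PointCloud:
    """Attach a symmetrized k-nearest-neighbour graph to a cloud."""
    pts = P.points
    n = len(pts)
    if k >= n:
        raise InvalidInputError(f"k={k} must be < number of points ({n})")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    idx = np.atleast_2d(idx)
    sets = [set() for _ in range(n)]
    for i in range(n):
        for j in idx[i]:
            if j != i:
                sets[i].add(int(j))
    # symmetrize: j in N(i) => i in N(j)
    for i in range(n):
        for j in list(sets[i]):
            sets[j].add(i)
    out = P.copy()
    out.neighbors = [np.array(sorted(s), dtype=np.int64) for s in sets]
    return out


def face_neighborhood(faces: np.ndarray, n_vertices: int) -> list:
    """Vertex neighborhood induced by shared faces (symmetric by construction)."""
    sets = [set() for _ in range(n_vertices)]
    for a, b, c in np.asarray(faces, dtype=np.int64):
        sets[a].update((b, c))
        sets[b].update((a, c))
        sets[c].update((a, b))
    return [np.array(sorted(s), dtype=np.int64) for s in sets]


# ---------------------------------------------------------------------------
# normals


def compute_normals(mesh: SurfaceMesh) -> SurfaceMesh:
    """Per-vertex outward normals from area-weighted adjacent-face normals.

    Zero-area faces are skipped.  Orientation is fixed per vertex by
    requiring a positive dot product with the centroid-to-vertex direction.
    """
    pts, faces = mesh.points, mesh.faces
    v0, v1, v2 = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)  # norm = 2 * area
    areas = np.linalg.norm(fn, axis=1)
    ok = areas > 1e-12
    acc = np.zeros_like(pts)
    counts = np.zeros(len(pts), dtype=np.int64)
    for col in range(3):
        np.add.at(acc, faces[ok, col], fn[ok])
        np.add.at(counts, faces[ok, col], 1)
    if np.any(counts == 0):
        raise InvalidInputError("mesh has isolated vertices (no non-degenerate face)")
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidInputError("degenerate vertex normal (cancelling faces)")
    normals = acc / norms[:, None]
    outward = pts - pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    out = mesh.copy()
    out.normals = normals
    return out


# ---------------------------------------------------------------------------
# world <-> voxel

def world_to_voxel(vol: Volume, pts: np.ndarray) -> np.ndarray:
    """Map world-mm coordinates to continuous voxel indices."""
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    inv = np.linalg.inv(vol.affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(vol: Volume, idx: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world-mm coordinates."""
    idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
    return idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]


def sample_trilinear(vol: Volume, pts: np.ndarray) -> tuple:
    """Trilinear samples of the volume at world positions.

    Positions outside the voxel grid return the volume minimum (background
    fill).  Returns ``(values, out_of_bounds_mask)``.
    """
    vox = world_to_voxel(vol, pts)
    shape = np.array(vol.data.shape, dtype=np.float64)
    oob = np.any((vox < 0) | (vox > shape - 1), axis=1)
    vals = ndimage.map_coordinates(vol.data, vox.T, order=1, mode="nearest")
    if np.any(oob):
        vals = np.where(oob, float(vol.data.min()), vals)
    return vals, oob


# ---------------------------------------------------------------------------
# primitive meshes


def icosphere(subdivisions: int = 2, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Unit icosahedron subdivided ``subdivisions`` times, projected to a sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    pts = verts * radius + np.asarray(center, dtype=np.float64)
    return SurfaceMesh(pts, None, faces)
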