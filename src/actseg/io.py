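"""File I/O: NIfTI volumes, PLY/OBJ meshes, CSV landmarks, YAML config.

All coordinates crossing this boundary are world mm (RAS+); the NIfTI affine
is the single source of geometric truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from actseg.geometry import InvalidInputError, SurfaceMesh, Volume, compute_normals

__all__ = [
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "load_config",
    "merge_config",
    "write_run_manifest",
]


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=np.float64)
    if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InvalidInputError(
            f"{path}: voxel-to-world affine is missing or misleading "
            "(singular/non-finite); cannot place the volume in world mm"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data, affine)


def write_volume(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


# ---------------------------------------------------------------------------
# meshes


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    has_normals = mesh.normals is not None
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(mesh)}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        if has_normals:
            f.write("property double nx\nproperty double ny\nproperty double nz\n")
        f.write(f"element face {len(mesh.faces)}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for i, p in enumerate(mesh.points):
            row = list(p) + (list(mesh.normals[i]) if has_normals else [])
            f.write(" ".join(repr(float(x)) for x in row) + "\n")
        for face in mesh.faces:
            f.write("3 " + " ".join(str(int(v)) for v in face) + "\n")


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path) as f:
        line = f.readline().strip()
        if line != "ply":
            raise InvalidInputError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        props: list = []
        element = None
        while True:
            line = f.readline()
            if not line:
                raise InvalidInputError(f"{path}: truncated PLY header")
            tok = line.split()
            if tok[0] == "format" and tok[1] != "ascii":
                raise InvalidInputError(f"{path}: only ASCII PLY supported")
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        rows = [f.readline().split() for _ in range(n_vert)]
        data = np.array(rows, dtype=np.float64)
        cols = {name: i for i, name in enumerate(props)}
        pts = data[:, [cols["x"], cols["y"], cols["z"]]]
        normals = None
        if all(k in cols for k in ("nx", "ny", "nz")):
            normals = data[:, [cols["nx"], cols["ny"], cols["nz"]]]
        faces = []
        for _ in range(n_face):
            tok = f.readline().split()
            if int(tok[0]) != 3:
                raise InvalidInputError(f"{path}: only triangle faces supported")
            faces.append([int(t) for t in tok[1:4]])
    return SurfaceMesh(pts, None, np.array(faces, dtype=np.int64), normals)


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as f:
        for p in mesh.points:
            f.write("v " + " ".join(repr(float(x)) for x in p) + "\n")
        if mesh.normals is not None:
            for n in mesh.normals:
                f.write("vn " + " ".join(repr(float(x)) for x in n) + "\n")
        for face in mesh.faces:
            f.write("f " + " ".join(str(int(v) + 1) for v in face) + "\n")


def _read_obj(path: Path) -> SurfaceMesh:
    pts, normals, faces = [], [], []
    with open(path) as f:
        for line in f:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "v":
                pts.append([float(t) for t in tok[1:4]])
            elif tok[0] == "vn":
                normals.append([float(t) for t in tok[1:4]])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                if len(idx) != 3:
                    raise InvalidInputError(f"{path}: only triangle faces supported")
                faces.append(idx)
    return SurfaceMesh(
        np.array(pts),
        None,
        np.array(faces, dtype=np.int64),
        np.array(normals) if len(normals) == len(pts) else None,
    )


def read_mesh(path, regenerate_normals: bool = True) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        mesh = _read_ply(path)
    elif path.suffix.lower() == ".obj":
        mesh = _read_obj(path)
    else:
        raise InvalidInputError(f"unsupported mesh format: {path.suffix}")
    if mesh.normals is None and regenerate_normals:
        mesh = compute_normals(mesh)
    return mesh


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply(mesh, path)
    elif path.suffix.lower() == ".obj":
        _write_obj(mesh, path)
    else:
        raise InvalidInputError(f"unsupported mesh format: {path.suffix}")


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path) -> pd.DataFrame:
    """CSV with columns id,x,y,z (world mm); stable ordering preserved."""
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["id", "x", "y", "z"])
    missing = {"id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing landmark columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            raise InvalidInputError(
                f"{path}: malformed value in column {col!r} at line {int(bad.idxmax()) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    if df[["x", "y", "z"]].isna().any().any():
        row = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax()) + 2
        raise InvalidInputError(f"{path}: missing coordinate at line {row}")
    return df[["id", "x", "y", "z"]]


def write_landmarks(points: np.ndarray, path, ids=None) -> None:
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if ids is None:
        ids = [str(i) for i in range(len(points))]
    pd.DataFrame(
        {"id": ids, "x": points[:, 0], "y": points[:, 1], "z": points[:, 2]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def merge_config(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        elif v is not None:
            out[k] = v
    return out


def write_run_manifest(out_dir, config: dict, seed: int) -> None:
    """Echo config + seed + versions so a run can be reproduced bitwise."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import actseg

    manifest = {
        "seed": int(seed),
        "config": config,
        "versions": {"actseg": actseg.__version__, "numpy": np.__version__},
    }
    with open(out_dir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
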