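"""File plumbing: meshes (STL/PLY via trimesh), scalar volumes (NRRD),
measurement tables (CSV) and transforms (JSON).

The NRRD support is a deliberately small reader/writer for the subset
this package produces: 3-D single-scalar volumes, ASCII header, raw
little-endian data, axis-aligned with per-axis spacing and an origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

MEASUREMENT_COLUMNS = ["tooth_id", "method", "parameter", "value_mm"]


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def save_mesh(mesh: trimesh.Trimesh, path, signed_distance=None) -> None:
    """Write STL (binary) or PLY; PLY may carry a per-vertex scalar.

    ``signed_distance``: optional per-vertex values exported to PLY as a
    diverging vertex colour (warm = positive/excess, cold = negative).
    """
    path = Path(path)
    if signed_distance is not None and path.suffix.lower() == ".ply":
        import matplotlib.cm as cm

        d = np.asarray(signed_distance, dtype=float)
        lim = max(np.abs(d).max(), 1e-12)
        rgba = cm.coolwarm(0.5 + d / (2 * lim))
        mesh = mesh.copy()
        mesh.visual.vertex_colors = (rgba * 255).astype(np.uint8)
    mesh.export(path)


def load_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    mesh = trimesh.load_mesh(path, process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"not a triangle mesh: {path}")
    mesh.merge_vertices()
    return mesh


# ---------------------------------------------------------------------------
# NRRD volumes
# ---------------------------------------------------------------------------

def save_nrrd(path, values: np.ndarray, spacing, origin) -> None:
    """Write a 3-D scalar volume as NRRD (raw little-endian float32)."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError("NRRD writer expects a 3-D array")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    header = [
        "NRRD0004",
        "# dentiform scalar volume",
        "type: float",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {values.shape[0]} {values.shape[1]} {values.shape[2]}",
        "space directions: ({},0,0) (0,{},0) (0,0,{})".format(*spacing),
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        "space origin: ({},{},{})".format(*origin),
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(values.astype("<f4").tobytes(order="F"))


def load_nrrd(path):
    """Read a volume written by :func:`save_nrrd`.

    Returns ``(values, spacing, origin)``.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, data = raw.partition(b"\n\n")
    fields = {}
    for line in head.decode("ascii").splitlines():
        if ":" in line and not line.startswith("#"):
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    sizes = tuple(int(s) for s in fields["sizes"].split())
    dirs = fields["space directions"].replace("(", " ").replace(")", " ").replace(",", " ").split()
    dirs = np.array([float(x) for x in dirs]).reshape(3, 3)
    spacing = np.diag(dirs).copy()
    org = fields.get("space origin", "(0,0,0)")
    origin = np.array([float(x) for x in
                       org.replace("(", "").replace(")", "").split(",")])
    dtype = {"float": "<f4", "double": "<f8"}[fields["type"]]
    values = np.frombuffer(data, dtype=dtype, count=int(np.prod(sizes)))
    values = values.reshape(sizes, order="F").astype(float)
    return values, spacing, origin


# ---------------------------------------------------------------------------
# tables and transforms
# ---------------------------------------------------------------------------

def save_measurements(table: pd.DataFrame, path) -> None:
    """CSV with columns tooth_id, method, parameter, value_mm (+extras)."""
    cols = MEASUREMENT_COLUMNS + [c for c in table.columns
                                  if c not in MEASUREMENT_COLUMNS]
    table[cols].to_csv(path, index=False)


def load_measurements(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"measurement table not found: {path}")
    table = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return table


def save_transform(path, rotation: np.ndarray, translation: np.ndarray,
                   **extra) -> None:
    payload = {"rotation": np.asarray(rotation).tolist(),
               "translation": np.asarray(translation).tolist(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_transform(path):
    payload = json.loads(Path(path).read_text())
    return np.asarray(payload["rotation"], dtype=float), \
        np.asarray(payload["translation"], dtype=float)
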