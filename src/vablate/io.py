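"""Mesh, landmark and result I/O.

Surface meshes are read from STL/PLY/OBJ (via trimesh) and legacy ASCII VTK
polydata; simulation fields are written as XML VTU (unstructured-grid) files
readable by ParaView.  Landmark specifications map the eight canonical
landmark names to either explicit node-index lists or xyz seed points that
are snapped to the nearest vertex and grown to a small geodesic disk.

Conventions: coordinates in mm, node indices 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .geometry import (
    LANDMARK_NAMES,
    MeshValidationError,
    SurfaceMesh,
    _geodesic_disk,
)

LANDMARK_SEED_RADIUS_MM = 2.0


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------


def _read_legacy_vtk(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal ASCII legacy-VTK POLYDATA/UNSTRUCTURED_GRID triangle reader."""
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.extend(line.split())
    tok = [t.upper() for t in tokens]
    if "ASCII" not in tok:
        raise MeshValidationError(f"{path}: only ASCII legacy VTK is supported")

    def _after(kw: str) -> int:
        try:
            return tok.index(kw)
        except ValueError:
            raise MeshValidationError(f"{path}: missing {kw} section") from None

    i = _after("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    if "POLYGONS" in tok:
        i = _after("POLYGONS")
    else:
        i = _after("CELLS")
    n_cells = int(tokens[i + 1])
    total = int(tokens[i + 2])
    flat = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
    tris = []
    k = 0
    for _ in range(n_cells):
        cnt = int(flat[k])
        if cnt == 3:
            tris.append(flat[k + 1 : k + 4])
        k += cnt + 1
    if not tris:
        raise MeshValidationError(f"{path}: no triangles found")
    return coords, np.vstack(tris)


def _resolve_landmarks(
    vertices: np.ndarray,
    graph,
    spec: dict,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, value in spec.items():
        arr = np.asarray(value)
        if arr.ndim == 1 and arr.shape == (3,) and arr.dtype.kind == "f":
            seed = int(np.argmin(np.linalg.norm(vertices - arr, axis=1)))
            out[name] = _geodesic_disk(graph, seed, LANDMARK_SEED_RADIUS_MM)
        else:
            idx = arr.astype(np.int64).ravel()
            if len(idx) == 0:
                raise MeshValidationError(f"landmark '{name}' resolves to no nodes")
            out[name] = np.unique(idx)
    return out


def load_landmark_spec(path: str | Path) -> dict:
    """Landmark spec from JSON or YAML: name -> node list or xyz seed point."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_surface_mesh(path: str | Path, landmark_spec: dict | str | Path) -> SurfaceMesh:
    """Read a triangulated surface and resolve all eight canonical landmarks.

    ``landmark_spec`` is a mapping (or path to a JSON/YAML file) from
    landmark names to node-index lists or xyz seed points; seed points snap
    to the nearest vertex and grow to a 2 mm geodesic disk.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        vertices, triangles = _read_legacy_vtk(path)
    elif suffix in (".stl", ".ply", ".obj"):
        tm = trimesh.load(str(path), force="mesh", process=False)
        vertices = np.asarray(tm.vertices, dtype=float)
        triangles = np.asarray(tm.faces, dtype=np.int64)
    else:
        raise MeshValidationError(f"unsupported mesh format '{suffix}'")
    if not isinstance(landmark_spec, dict):
        landmark_spec = load_landmark_spec(landmark_spec)
    missing = [n for n in LANDMARK_NAMES if n not in landmark_spec]
    if missing:
        raise MeshValidationError(f"landmark spec missing names: {missing}")
    mesh = SurfaceMesh(vertices, triangles, {})
    graph = mesh.adjacency_graph()
    mesh.landmark_sets = _resolve_landmarks(mesh.vertices, graph, landmark_spec)
    mesh.validate()
    return mesh


def save_surface_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write the surface (STL/PLY/OBJ) plus a sidecar JSON landmark spec."""
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    tm.export(str(path))
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    sidecar.write_text(
        json.dumps({k: v.tolist() for k, v in mesh.landmark_sets.items()}, indent=1)
    )
    return path


# ---------------------------------------------------------------------------
# VTU output
# ---------------------------------------------------------------------------


def write_vtu(
    path: str | Path,
    mesh: SurfaceMesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """ASCII XML VTU file of the triangulated surface with per-node scalars."""
    path = Path(path)
    v = mesh.vertices
    t = mesh.triangles
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(v)}" NumberOfCells="{len(t)}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{x:.6g}" for x in row) for row in v),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in row) for row in t),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(3 * (i + 1)) for i in range(len(t))),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("5" for _ in range(len(t))),
        "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float).ravel()
            if len(arr) != len(v):
                raise ValueError(f"point_data '{name}' length {len(arr)} != {len(v)}")
            lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(" ".join(f"{x:.6g}" for x in arr))
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_metrics_csv(recording, path: str | Path) -> Path:
    """Global activity trace (time, max Vm, depolarized-node count) as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {
            "time_ms": recording.times,
            "vmax_mV": recording.vmax,
            "n_depolarized": recording.n_depolarized,
        }
    ).to_csv(path, index=False)
    return path


def write_cfae_csv(cfae_map, path: str | Path) -> Path:
    """Per-node CFAE cycle lengths as CSV (undefined nodes left blank)."""
    import pandas as pd

    path = Path(path)
    cl = cfae_map.cycle_length
    pd.DataFrame(
        {
            "node": np.arange(len(cl)),
            "cycle_length_ms": np.where(np.isfinite(cl), cl, np.nan),
            "activation_count": cfae_map.activation_count,
        }
    ).to_csv(path, index=False)
    return path


def write_results(results: list, out_dir: str | Path) -> tuple[Path, Path]:
    """results.json and results.csv (one row per protocol) for a ranked run."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [r.to_dict() for r in results]
    jpath = out_dir / "results.json"
    jpath.write_text(json.dumps(rows, indent=1))
    cpath = out_dir / "results.csv"
    pd.DataFrame(rows).to_csv(cpath, index=False)
    return jpath, cpath
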