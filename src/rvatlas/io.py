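"""Reading and writing meshes, motion tables and reports.

Meshes travel as VTK legacy ASCII polydata (with optional per-vertex scalar
fields for visualisation) or PLY; landmarks and the four-chamber plane live
in a YAML sidecar next to the mesh.  Cohort tables (motion, covariates,
markers) are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import MeshGeometry

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_ply",
    "write_mesh_sidecar",
    "read_mesh",
    "write_cohort",
    "read_cohort_tables",
    "write_json",
]


def write_vtk(
    path: str | Path,
    vertices: np.ndarray,
    faces: np.ndarray,
    point_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangulated surface as VTK legacy ASCII polydata."""
    path = Path(path)
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "rvatlas surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {v.shape[0]} float",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in v]
    lines.append(f"POLYGONS {f.shape[0]} {4 * f.shape[0]}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    if point_scalars:
        lines.append(f"POINT_DATA {v.shape[0]}")
        for name, arr in point_scalars.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.9g}" for x in arr]
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read vertices and faces from VTK legacy ASCII polydata."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts = faces = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            vals: list[float] = []
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in next(it).split())
            verts = np.asarray(vals, dtype=float).reshape(n, 3)
        elif parts[0] == "POLYGONS":
            m = int(parts[1])
            rows = []
            for _ in range(m):
                row = [int(x) for x in next(it).split()]
                if row[0] != 3:
                    raise ValueError("only triangulated polydata is supported")
                rows.append(row[1:])
            faces = np.asarray(rows, dtype=np.int64)
    if verts is None or faces is None:
        raise ValueError(f"{path} is not a triangulated VTK polydata file")
    return verts, faces


def write_ply(path: str | Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    import trimesh

    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(
        str(path), encoding="ascii"
    )


def write_mesh_sidecar(path: str | Path, mesh: MeshGeometry) -> None:
    """YAML sidecar carrying landmarks and the scanning plane."""
    doc = {
        "landmark_apex": int(mesh.landmark_apex),
        "landmark_annulus": [int(i) for i in mesh.landmark_annulus],
        "plane": {
            "name": mesh.plane_name,
            "point": [float(x) for x in mesh.plane_point],
            "normal": [float(x) for x in mesh.plane_normal],
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_mesh(mesh_path: str | Path, sidecar_path: str | Path) -> MeshGeometry:
    """Mesh from VTK polydata plus its landmark/plane YAML sidecar."""
    verts, faces = read_vtk(mesh_path)
    doc = yaml.safe_load(Path(sidecar_path).read_text())
    return MeshGeometry(
        vertex_positions=verts,
        faces=faces,
        landmark_apex=int(doc["landmark_apex"]),
        landmark_annulus=np.asarray(doc["landmark_annulus"], dtype=np.int64),
        plane_point=np.asarray(doc["plane"]["point"], dtype=float),
        plane_normal=np.asarray(doc["plane"]["normal"], dtype=float),
        plane_name=str(doc["plane"].get("name", "four-chamber")),
    )


def write_cohort(outdir: str | Path, dataset) -> None:
    """Emit mesh (VTK + sidecar), excursion matrix and subject tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vtk(out / "mesh.vtk", dataset.mesh.vertex_positions, dataset.mesh.faces)
    write_mesh_sidecar(out / "mesh.yaml", dataset.mesh)
    pd.DataFrame(dataset.excursion).to_csv(out / "excursion.csv", index_label="subject")
    tab = dataset.covariates.copy()
    tab["rvef"] = dataset.rvef
    tab["edv"] = dataset.edv
    tab.to_csv(out / "subjects.csv", index_label="subject")
    dataset.markers.to_csv(out / "markers.csv", index_label="subject")
    if dataset.patch_vertices is not None:
        write_json(out / "planted_patch.json",
                   {"vertices": [int(v) for v in dataset.patch_vertices]})


def read_cohort_tables(
    indir: str | Path,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Read (excursion, covariates, rvef, edv, markers) written by write_cohort."""
    ind = Path(indir)
    exc = pd.read_csv(ind / "excursion.csv", index_col="subject").to_numpy()
    subj = pd.read_csv(ind / "subjects.csv", index_col="subject")
    markers = pd.read_csv(ind / "markers.csv", index_col="subject")
    rvef = subj.pop("rvef").to_numpy()
    edv = subj.pop("edv").to_numpy()
    return exc, subj, rvef, edv, markers


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
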