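"""Reading and writing aneurysm geometries and cohort feature tables.

A geometry on disk is a mesh file (STL/OBJ/PLY, handled by trimesh) plus a
JSON annotation sidecar carrying everything the mesh cannot: the neck
contour, flow and vessel directions, the parent-vessel and outlet diameters
and the clinical fields.  Feature tables are plain CSV with a fixed,
documented column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import trimesh

from .datatypes import (
    MORPH_FIELDS,
    AneurysmGeometry,
    MorphometricsRecord,
    NeckContour,
    SurfaceMesh,
)
from .errors import InputError, SchemaError, ValidationError

PathLike = Union[str, Path]

SUPPORTED_MESH_SUFFIXES = (".stl", ".obj", ".ply")

#: JSON annotation keys (see the methods note for semantics).
ANNOTATION_KEYS = (
    "neck_points", "inlet_dir", "vessel_axis", "dpvi_mm",
    "outlet_diameters_mm", "lb_status", "irregular", "location",
    "sex", "age", "ruptured",
)

#: Canonical feature-table column order: 35 morphological parameters,
#: 3 clinical fields, then the optional rupture label.
CLINICAL_COLUMNS = ("age", "sex", "location")
TABLE_COLUMNS = MORPH_FIELDS + CLINICAL_COLUMNS + ("ruptured",)


def read_mesh(path: PathLike) -> SurfaceMesh:
    """Load a triangulated surface from STL/OBJ/PLY via trimesh."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mesh file not found: {path}")
    if path.suffix.lower() not in SUPPORTED_MESH_SUFFIXES:
        raise InputError(f"unsupported mesh format: {path.suffix}")
    try:
        tm = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"unparseable mesh file {path}: {exc}") from exc
    if tm.faces.shape[1] != 3:
        raise InputError("mesh is not triangulated")
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def write_mesh(mesh: SurfaceMesh, path: PathLike) -> Path:
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
    return path


def read_geometry(mesh_path: PathLike, annotation_path: PathLike) -> AneurysmGeometry:
    """Load and validate a full AneurysmGeometry from mesh + JSON sidecar."""
    sac = read_mesh(mesh_path)
    annotation_path = Path(annotation_path)
    if not annotation_path.exists():
        raise InputError(f"annotation file not found: {annotation_path}")
    try:
        ann = json.loads(annotation_path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"unparseable annotation JSON: {exc}") from exc
    if "neck_points" not in ann:
        raise ValidationError("neck", "annotation lacks the neck contour")
    for key in ("inlet_dir", "vessel_axis", "dpvi_mm", "outlet_diameters_mm",
                "lb_status"):
        if key not in ann:
            raise ValidationError(key, "missing required annotation key")
    geom = AneurysmGeometry(
        sac=sac,
        neck=NeckContour(points=np.asarray(ann["neck_points"], dtype=float)),
        inlet_dir=np.asarray(ann["inlet_dir"], dtype=float),
        vessel_axis=np.asarray(ann["vessel_axis"], dtype=float),
        dpvi=float(ann["dpvi_mm"]),
        outlet_diameters=[float(d) for d in ann["outlet_diameters_mm"]],
        lb_status=ann["lb_status"],
        irregular=ann.get("irregular"),
        location=ann.get("location", "other"),
        sex=ann.get("sex", "F"),
        age=float(ann.get("age", 55.0)),
        ruptured=ann.get("ruptured"),
    )
    return geom.validate()


def write_geometry(
    geometry: AneurysmGeometry, mesh_path: PathLike, annotation_path: PathLike
) -> None:
    """Write the sac mesh and the JSON annotation sidecar."""
    write_mesh(geometry.sac, mesh_path)
    ann = {
        "neck_points": geometry.neck.points.tolist(),
        "inlet_dir": geometry.inlet_dir.tolist(),
        "vessel_axis": geometry.vessel_axis.tolist(),
        "dpvi_mm": geometry.dpvi,
        "outlet_diameters_mm": list(geometry.outlet_diameters),
        "lb_status": geometry.lb_status,
        "irregular": geometry.irregular,
        "location": geometry.location,
        "sex": geometry.sex,
        "age": geometry.age,
        "ruptured": geometry.ruptured,
    }
    Path(annotation_path).write_text(json.dumps(ann, indent=1))


def records_to_frame(
    records: Sequence[MorphometricsRecord],
    clinical: Sequence[dict],
    labels: Sequence[Optional[bool]],
) -> pd.DataFrame:
    """Assemble (record, clinical dict, label) triples into a feature table."""
    if not (len(records) == len(clinical) == len(labels)):
        raise SchemaError("records, clinical fields and labels differ in length")
    rows = []
    for rec, clin, lab in zip(records, clinical, labels):
        extra = set(clin) - set(CLINICAL_COLUMNS)
        missing = set(CLINICAL_COLUMNS) - set(clin)
        if extra or missing:
            raise SchemaError(
                f"clinical fields mismatch: extra={sorted(extra)} "
                f"missing={sorted(missing)}"
            )
        row = rec.as_dict()
        row.update(clin)
        row["ruptured"] = int(lab) if lab is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def write_feature_table(table: pd.DataFrame, path: PathLike) -> Path:
    """Write a feature table as UTF-8 CSV in the canonical column order."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    path = Path(path)
    table[list(TABLE_COLUMNS)].to_csv(path, index=False)
    return path


def read_feature_table(path: PathLike) -> pd.DataFrame:
    """Read a cohort CSV; all canonical columns must be present."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"feature table not found: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    return table[list(TABLE_COLUMNS)]
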