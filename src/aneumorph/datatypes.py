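"""Core domain containers for aneurysm sac morphometry.

Units are millimetres (lengths), mm^2 (areas), mm^3 (volumes) and degrees
(angles) throughout the package; these follow clinical convention since no
other convention is standard for medical-image-derived geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Area below which a triangle is considered degenerate (mm^2).
DEGENERATE_FACE_TOL = 1e-12

#: Vocabulary for the aneurysm location in the Circle of Willis.
LOCATIONS = ("ICA", "MCA", "ACA", "PCA", "BA/VA", "other")

#: Patient sex encoding used in tables ("F" maps to 1, "M" to 0).
SEXES = ("F", "M")

#: Lateral vs bifurcation status of the sac on the parent vessel.
LB_STATUSES = ("lateral", "bifurcation")


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64))

    def validate(self) -> "SurfaceMesh":
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 4:
            raise ValidationError("vertices", "need an (n>=4, 3) coordinate array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise ValidationError("faces", "need an (m>=1, 3) triangle index array")
        if f.min() < 0 or f.max() >= len(v):
            raise ValidationError("faces", "face index out of vertex range")
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if np.any(areas <= DEGENERATE_FACE_TOL):
            raise ValidationError("faces", "zero-area (degenerate) face present")
        return self

    @property
    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass(frozen=True)
class NeckContour:
    """Ordered closed 3D polyline bounding the ostium (first point not repeated)."""

    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    def validate(self) -> "NeckContour":
        p = self.points
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
            raise ValidationError("neck", "need >= 3 ordered 3D points")
        # Simplicity of the planar projection is checked in mesh_core where
        # the best-fit plane is available (polygon_metrics).
        return self


@dataclass(frozen=True)
class PlaneFrame:
    """Neck plane: origin at the contour centroid, normal toward the sac,
    plus an orthonormal in-plane basis (u, v)."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points to (u, v) coordinates relative to the origin."""
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.in_plane_u, rel @ self.in_plane_v])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal


@dataclass(frozen=True)
class HullResult:
    """Convex-hull volume (DV_CH, mm^3) and outer area (DA_CH, mm^2) of the
    closed sac; inputs to the ellipticity and undulation indices."""

    hull_volume: float
    hull_area: float


@dataclass(frozen=True)
class AneurysmGeometry:
    """One aneurysm: open sac mesh + neck contour + flow/vessel/clinical data."""

    sac: SurfaceMesh
    neck: NeckContour
    inlet_dir: np.ndarray
    vessel_axis: np.ndarray
    dpvi: float
    outlet_diameters: Sequence[float]
    lb_status: str
    irregular: Optional[bool] = None
    location: str = "other"
    sex: str = "F"
    age: float = 55.0
    ruptured: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "inlet_dir", np.asarray(self.inlet_dir, dtype=float))
        object.__setattr__(self, "vessel_axis", np.asarray(self.vessel_axis, dtype=float))
        object.__setattr__(
            self, "outlet_diameters", tuple(float(d) for d in self.outlet_diameters)
        )

    def validate(self) -> "AneurysmGeometry":
        self.sac.validate()
        self.neck.validate()
        if not self.dpvi > 0:
            raise ValidationError("dpvi", "parent-vessel inlet diameter must be > 0")
        if len(self.outlet_diameters) < 1:
            raise ValidationError("outlet_diameters", "at least one outlet required")
        if any(d <= 0 for d in self.outlet_diameters):
            raise ValidationError("outlet_diameters", "outlet diameters must be > 0")
        for name in ("inlet_dir", "vessel_axis"):
            vec = getattr(self, name)
            if vec.shape != (3,):
                raise ValidationError(name, "need a 3-vector")
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise ValidationError(name, "must have unit norm (tol 1e-9)")
        if self.lb_status not in LB_STATUSES:
            raise ValidationError("lb_status", f"must be one of {LB_STATUSES}")
        if self.location not in LOCATIONS:
            raise ValidationError("location", f"must be one of {LOCATIONS}")
        if self.sex not in SEXES:
            raise ValidationError("sex", f"must be one of {SEXES}")
        return self


#: Canonical order of the 35 morphological parameters (27 established + 8 novel).
MORPH_FIELDS = (
    "DV", "DA", "MD", "CPH", "ND", "NA", "DPVI", "MPH",
    "IMDA", "MDNA", "INA", "PL", "MDPN", "LB", "I",
    "AR", "BR", "NR", "SR", "DNR", "SF", "VOA",
    "EI", "NSI", "UI", "PR", "CP",
    "NC", "IR", "IRR", "IS", "ISR", "ON", "COD", "IOR",
)


@dataclass(frozen=True)
class MorphometricsRecord:
    """The 35 named morphological parameters of one aneurysm.

    Dimensions: DV mm^3; DA, NA mm^2; MD, CPH, ND, DPVI, MPH, PL, MDPN, NC,
    IR, IS, VOA, COD mm; IMDA, MDNA, INA degrees; SF mm^(2/3)/... retains the
    dimensional character of DA/DV^(2/3); LB, I binary; ON a count; the rest
    dimensionless ratios.
    """

    DV: float
    DA: float
    MD: float
    CPH: float
    ND: float
    NA: float
    DPVI: float
    MPH: float
    IMDA: float
    MDNA: float
    INA: float
    PL: float
    MDPN: float
    LB: int
    I: int
    AR: float
    BR: float
    NR: float
    SR: float
    DNR: float
    SF: float
    VOA: float
    EI: float
    NSI: float
    UI: float
    PR: float
    CP: float
    NC: float
    IR: float
    IRR: float
    IS: float
    ISR: float
    ON: int
    COD: float
    IOR: float

    def as_dict(self) -> dict:
        """Field -> value in canonical order."""
        return {name: getattr(self, name) for name in MORPH_FIELDS}

    def validate(self) -> "MorphometricsRecord":
        d = self.as_dict()
        positive = ("AR", "BR", "NR", "SR", "DNR", "VOA", "PR", "IOR")
        for name in positive:
            if not d[name] > 0:
                raise ValidationError(name, "must be > 0")
        if not (0.0 <= self.UI < 1.0):
            raise ValidationError("UI", "must lie in [0, 1)")
        if not (0.0 < self.IRR <= 1.0):
            raise ValidationError("IRR", "must lie in (0, 1]")
        if not (0.0 < self.ISR <= 1.0):
            raise ValidationError("ISR", "must lie in (0, 1]")
        if not self.EI < 1.0:
            raise ValidationError("EI", "must be < 1")
        if not self.NSI < 1.0:
            raise ValidationError("NSI", "must be < 1")
        if not (self.ON >= 1 and int(self.ON) == self.ON):
            raise ValidationError("ON", "must be an integer >= 1")
        if not self.CP <= 0.5:
            raise ValidationError("CP", "must be <= 0.5")
        return self


assert len(fields(MorphometricsRecord)) == 35 == len(MORPH_FIELDS)
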