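"""The 35-parameter morphological battery for one aneurysm.

Thirteen primitive quantities are measured on the mesh (volumes, areas,
lengths, heights, angles), two binary annotations are carried through
(lateral/bifurcation status and shape irregularity), and the remaining
twenty are ratio and isoperimetric indices:

    AR = CPH/ND            BR = MD/ND             NR = ND/DPVI
    SR = MD/DPVI           DNR = DA/NA            SF = DA/DV^(2/3)
    VOA = DV/NA            PR = MPH/DPVI          CP = 0.5 - MDPN/DPVI
    EI = 1 - (18*pi)^(1/3) * DV_CH^(2/3) / DA_CH
    NSI = 1 - (18*pi)^(1/3) * DV^(2/3) / DA
    UI = 1 - DV/DV_CH

and the flow-independent shape scores built on ideal (isoperimetric)
references:

    IR = sqrt(NA/pi)               IRR = 2*pi*IR/NC
    IS = (3*DV/(4*pi))^(1/3)       ISR = 4*pi*IS^2/(DA + NA)
    ON = #outlets                  COD = sum of outlet diameters
    IOR = DPVI/COD

IRR <= 1 because among planar shapes of equal area the circle has the
smallest perimeter; ISR <= 1 because among solids of equal volume the
sphere has the smallest surface (here the closed surface DA + NA).
"""

from __future__ import annotations

import math
from typing import Dict, Sequence, Tuple

import numpy as np

from . import mesh_core
from .datatypes import (
    AneurysmGeometry,
    HullResult,
    MorphometricsRecord,
    NeckContour,
    PlaneFrame,
)
from .errors import ComputationError, GeometryError

#: UI above this is used as the irregularity proxy when no annotation exists.
IRREGULARITY_UI_THRESHOLD = 0.05


def neck_diameter(
    neck: NeckContour, plane: PlaneFrame, inlet_dir: np.ndarray
) -> float:
    """ND: chord of the projected neck polygon through the neck centroid
    along the in-plane projection of the inlet flow direction (mm)."""
    f3 = np.asarray(inlet_dir, dtype=float)
    f2 = np.array([f3 @ plane.in_plane_u, f3 @ plane.in_plane_v])
    norm = np.linalg.norm(f2)
    if norm < 1e-9:
        raise GeometryError(
            "inlet direction is perpendicular to the neck plane; "
            "flow-parallel neck diameter undefined"
        )
    f2 /= norm
    uv = plane.to_plane_coords(neck.points)  # centroid projects to (0, 0)
    ts = []
    npts = len(uv)
    for i in range(npts):
        p, q = uv[i], uv[(i + 1) % npts]
        e = q - p
        denom = e[0] * (-f2[1]) + e[1] * f2[0]  # cross(e, f2) with sign
        if abs(denom) < 1e-14:
            continue
        # solve p + s e = t f2
        s = (p[0] * f2[1] - p[1] * f2[0]) / denom
        if -1e-12 <= s < 1.0:
            t = p[0] * f2[0] + p[1] * f2[1] + s * (e @ f2)
            ts.append(t)
    if len(ts) < 2:
        raise GeometryError("flow line through the neck centroid does not "
                            "cross the neck polygon twice")
    return float(max(ts) - min(ts))


def angle_metrics(
    inlet_dir: np.ndarray,
    md_endpoints: Tuple[np.ndarray, np.ndarray],
    plane: PlaneFrame,
) -> Tuple[float, float, float]:
    """(IMDA, MDNA, INA) in degrees.

    The MD vector points from the endpoint nearer the neck centroid to the
    farther one.  IMDA is the angle between the inlet flow and MD in
    [0, 180]; MDNA and INA are angles to the neck *plane* (90 deg minus the
    angle to its normal), each in [0, 90].
    """
    p, q = (np.asarray(e, dtype=float) for e in md_endpoints)
    if np.linalg.norm(q - plane.origin) < np.linalg.norm(p - plane.origin):
        p, q = q, p
    md_vec = q - p
    n = np.linalg.norm(md_vec)
    if n < 1e-12:
        raise GeometryError("zero-length MD vector")
    md_vec = md_vec / n
    f = np.asarray(inlet_dir, dtype=float)
    imda = math.degrees(math.acos(np.clip(f @ md_vec, -1.0, 1.0)))
    mdna = math.degrees(math.asin(np.clip(abs(md_vec @ plane.normal), 0.0, 1.0)))
    ina = math.degrees(math.asin(np.clip(abs(f @ plane.normal), 0.0, 1.0)))
    return imda, mdna, ina


def ratio_indices(
    DV: float,
    DA: float,
    MD: float,
    CPH: float,
    ND: float,
    NA: float,
    DPVI: float,
    MPH: float,
    MDPN: float,
    hull: HullResult,
) -> Dict[str, float]:
    """The 12 derived indices of the established battery (AR .. CP)."""
    for name, denom in (
        ("AR", ND), ("BR", ND), ("NR", DPVI), ("SR", DPVI), ("DNR", NA),
        ("SF", DV), ("VOA", NA), ("EI", hull.hull_area), ("NSI", DA),
        ("UI", hull.hull_volume), ("PR", DPVI), ("CP", DPVI),
    ):
        if denom == 0:
            raise ComputationError(name, "zero denominator")
    k = (18.0 * math.pi) ** (1.0 / 3.0)
    return {
        "AR": CPH / ND,
        "BR": MD / ND,
        "NR": ND / DPVI,
        "SR": MD / DPVI,
        "DNR": DA / NA,
        "SF": DA / DV ** (2.0 / 3.0),
        "VOA": DV / NA,
        "EI": 1.0 - k * hull.hull_volume ** (2.0 / 3.0) / hull.hull_area,
        "NSI": 1.0 - k * DV ** (2.0 / 3.0) / DA,
        # clamp: on exactly convex sacs round-off can push DV a hair past DV_CH
        "UI": max(0.0, 1.0 - DV / hull.hull_volume),
        "PR": MPH / DPVI,
        "CP": 0.5 - MDPN / DPVI,
    }


def novel_indices(
    NA: float,
    NC: float,
    DV: float,
    DA: float,
    outlet_diameters: Sequence[float],
    DPVI: float,
) -> Dict[str, float]:
    """The 8 new parameters: NC passthrough, IR/IRR, IS/ISR, ON/COD/IOR."""
    if len(outlet_diameters) == 0:
        raise ComputationError("ON", "empty outlet list")
    for name, val in (("IR", NA), ("IRR", NC), ("IS", DV), ("ISR", DA + NA)):
        if val <= 0:
            raise ComputationError(name, "non-positive input")
    ir = math.sqrt(NA / math.pi)
    is_ = (3.0 * DV / (4.0 * math.pi)) ** (1.0 / 3.0)
    cod = float(sum(outlet_diameters))
    return {
        "NC": NC,
        "IR": ir,
        "IRR": 2.0 * math.pi * ir / NC,
        "IS": is_,
        "ISR": 4.0 * math.pi * is_ ** 2 / (DA + NA),
        "ON": len(outlet_diameters),
        "COD": cod,
        "IOR": DPVI / cod,
    }


def compute_all(
    geometry: AneurysmGeometry, n_slices: int = 200
) -> MorphometricsRecord:
    """Measure the complete 35-parameter morphological record.

    Orchestrates the mesh primitives: neck-plane fit, ostium metrics,
    capping, volume/area, convex hull, heights, sections, projections and
    every derived index.  Deterministic for a fixed input.
    """
    geometry.validate()
    sac, neck = geometry.sac, geometry.neck
    sac_centroid = sac.vertices.mean(axis=0)
    plane = mesh_core.fit_neck_plane(neck, sac_centroid)
    na, nc, _ = mesh_core.polygon_metrics(neck, plane)
    closed = mesh_core.cap_neck(sac, neck)
    dv = mesh_core.enclosed_volume(closed)
    da = mesh_core.surface_area(sac)
    md, pair = mesh_core.max_pairwise_distance(sac.vertices)
    mph = mesh_core.max_plane_distance(sac, plane)
    cph = mesh_core.central_height(sac, plane)
    mdpn = mesh_core.largest_parallel_section(closed, plane, n_slices=n_slices)
    pl = mesh_core.projection_length(sac, geometry.vessel_axis)
    hull = mesh_core.convex_hull_metrics(closed)
    nd = neck_diameter(neck, plane, geometry.inlet_dir)
    imda, mdna, ina = angle_metrics(
        geometry.inlet_dir, (sac.vertices[pair[0]], sac.vertices[pair[1]]), plane
    )
    ratios = ratio_indices(
        DV=dv, DA=da, MD=md, CPH=cph, ND=nd, NA=na,
        DPVI=geometry.dpvi, MPH=mph, MDPN=mdpn, hull=hull,
    )
    novel = novel_indices(
        NA=na, NC=nc, DV=dv, DA=da,
        outlet_diameters=geometry.outlet_diameters, DPVI=geometry.dpvi,
    )
    irregular = geometry.irregular
    if irregular is None:
        irregular = ratios["UI"] > IRREGULARITY_UI_THRESHOLD
    return MorphometricsRecord(
        DV=dv, DA=da, MD=md, CPH=cph, ND=nd, NA=na, DPVI=geometry.dpvi,
        MPH=mph, IMDA=imda, MDNA=mdna, INA=ina, PL=pl, MDPN=mdpn,
        LB=int(geometry.lb_status == "bifurcation"), I=int(irregular),
        **ratios, **novel,
    )
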