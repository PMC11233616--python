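"""Parametric sac geometries with closed-form ground truth, randomized
fixture suites, and labelled synthetic cohorts.

Sac families are radial graphs r(theta, phi) over a polar cap, meshed on a
structured (n_theta x n_phi) grid with a single apex vertex; the last ring
is the neck contour, so capping is exact.  Families:

* ``hemisphere``       r constant, cut at the equator.
* ``spherical_cap``    sphere of radius R cut ``cap_offset`` below the
                       center (a sac that bulges past its widest section).
* ``half_ellipsoid``   semi-axes (a, b, c), cut at the equator.
* ``lobulated``        hemisphere with a Gaussian radial bump (non-convex).
* ``undulated``        radial ripple r0*(1 + a*sin(4*theta)*sin(4*phi)).

Cohorts emulate the study composition (253 ruptured / 456 unruptured by
default) with labels drawn from a planted logistic model on standardized
features and the exact class split enforced by case-control subsampling
from a larger generated pool — mirroring how a retrospective clinical
cohort fixes its case and control counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ellipe, expit

from .datatypes import AneurysmGeometry, NeckContour, SurfaceMesh
from .errors import ValidationError

FAMILIES = ("hemisphere", "spherical_cap", "half_ellipsoid", "lobulated",
            "undulated")

#: Default location frequencies: ICA, MCA and ACA are the most frequent
#: sites in the Circle of Willis; exact values are this package's choice.
DEFAULT_LOCATION_PROBS = {
    "ICA": 0.28, "MCA": 0.25, "ACA": 0.20,
    "PCA": 0.10, "BA/VA": 0.07, "other": 0.10,
}

#: Most aneurysm patients in multi-centric registries are female.
DEFAULT_FEMALE_PROB = 0.68

#: Planted log-odds weights on standardized features; chosen to make
#: importance-recovery tests decisive (magnitudes are this package's own).
DEFAULT_EFFECTS = {"EI": 1.2, "SR": 0.8, "I": 0.6}


@dataclass(frozen=True)
class SacSpec:
    """Parameters of one synthetic sac geometry."""

    family: str = "hemisphere"
    radius: float = 1.0
    semi_axes: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    cap_offset: float = 0.5
    undulation_amplitude: float = 0.2
    resolution: Tuple[int, int] = (64, 32)
    dpvi: float = 2.0
    seed: int = 0

    def validate(self) -> "SacSpec":
        if self.family not in FAMILIES:
            raise ValidationError("family", f"must be one of {FAMILIES}")
        if self.radius <= 0 or any(s <= 0 for s in self.semi_axes):
            raise ValidationError("radius", "radii/semi-axes must be > 0")
        if not (0.0 <= self.undulation_amplitude < 0.5):
            raise ValidationError(
                "undulation_amplitude", "must lie in [0, 0.5)")
        if self.family == "spherical_cap" and not (
            0.0 < self.cap_offset < self.radius
        ):
            raise ValidationError("cap_offset", "must lie in (0, radius)")
        if self.resolution[0] < 16 or self.resolution[1] < 8:
            raise ValidationError("resolution", "minimum grid is (16, 8)")
        return self


def _radial_function(spec: SacSpec) -> Tuple[Callable, float]:
    """(r(theta, phi), theta_max) for the spec's family, before any
    ellipsoidal stretch."""
    r0 = spec.radius
    if spec.family in ("hemisphere", "half_ellipsoid"):
        return (lambda th, ph: np.full_like(np.asarray(th, dtype=float), r0),
                math.pi / 2)
    if spec.family == "spherical_cap":
        theta_max = math.acos(-spec.cap_offset / r0)
        return (lambda th, ph: np.full_like(np.asarray(th, dtype=float), r0),
                theta_max)
    if spec.family == "undulated":
        a = spec.undulation_amplitude

        def r(th, ph):
            return r0 * (1.0 + a * np.sin(4 * np.asarray(th))
                         * np.sin(4 * np.asarray(ph)))

        return r, math.pi / 2
    # lobulated: Gaussian bump toward a fixed off-axis direction, tapered to
    # vanish at the apex and the neck so both stay exact
    a = spec.undulation_amplitude
    th0, ph0 = 0.9, 0.7
    bump_dir = np.array([
        math.sin(th0) * math.cos(ph0),
        math.sin(th0) * math.sin(ph0),
        math.cos(th0),
    ])

    def r(th, ph):
        th = np.asarray(th, dtype=float)
        ph = np.asarray(ph, dtype=float)
        d = np.stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)],
            axis=-1,
        )
        gamma = np.arccos(np.clip(d @ bump_dir, -1.0, 1.0))
        return r0 * (1.0 + a * np.exp(-((gamma / 0.35) ** 2)) * np.sin(2 * th))

    return r, math.pi / 2


def _stretch(spec: SacSpec) -> np.ndarray:
    if spec.family == "half_ellipsoid":
        return np.asarray(spec.semi_axes, dtype=float)
    return np.ones(3)


def _closed_form_truth(spec: SacSpec) -> Dict[str, float]:
    r = spec.radius
    if spec.family == "hemisphere":
        dv, da, na, nc = (
            2 * math.pi * r**3 / 3, 2 * math.pi * r**2,
            math.pi * r**2, 2 * math.pi * r,
        )
        is_ = (3 * dv / (4 * math.pi)) ** (1 / 3)
        return {
            "DV": dv, "DA": da, "NA": na, "NC": nc, "MD": 2 * r,
            "MPH": r, "CPH": r, "MDPN": 0.0, "ND": 2 * r, "PL": 2 * r,
            "NSI": 0.0, "UI": 0.0, "EI": 1 / 3, "IRR": 1.0,
            "AR": 0.5, "BR": 1.0, "DNR": 2.0, "VOA": 2 * r / 3,
            "IS": is_, "ISR": 4 * math.pi * is_**2 / (da + na),
        }
    if spec.family == "spherical_cap":
        h = spec.cap_offset
        H = r + h
        a = math.sqrt(r**2 - h**2)
        return {
            "DV": math.pi * H**2 * (3 * r - H) / 3,
            "DA": 2 * math.pi * r * H,
            "NA": math.pi * a**2, "NC": 2 * math.pi * a,
            "CPH": H, "MPH": H, "MDPN": h, "MD": 2 * r, "ND": 2 * a,
            "PL": 2 * r, "UI": 0.0, "IRR": 1.0,
        }
    if spec.family == "half_ellipsoid":
        a, b, c = spec.semi_axes
        big, small = max(a, b), min(a, b)
        m = 1.0 - (small / big) ** 2
        truth = {
            "DV": 2 * math.pi * a * b * c / 3,
            "NA": math.pi * a * b,
            "NC": 4 * big * float(ellipe(m)),
            "MPH": c, "CPH": c, "UI": 0.0,
        }
        if a == b:  # spheroid dome area has a closed form
            if c > a:
                e = math.sqrt(1 - (a / c) ** 2)
                full = 2 * math.pi * a**2 * (1 + (c / (a * e)) * math.asin(e))
            elif c < a:
                e = math.sqrt(1 - (c / a) ** 2)
                full = 2 * math.pi * a**2 + (
                    math.pi * c**2 / e) * math.log((1 + e) / (1 - e))
            else:
                full = 4 * math.pi * a**2
            truth["DA"] = full / 2
        return truth
    return {}


def make_sac(spec: SacSpec) -> Tuple[AneurysmGeometry, Dict[str, float]]:
    """Build the sac geometry and its closed-form ground truth (if any).

    Deterministic: the same spec yields a byte-identical mesh.
    """
    spec.validate()
    n_theta, n_phi = spec.resolution
    radial, theta_max = _radial_function(spec)
    stretch = _stretch(spec)
    thetas = np.linspace(0.0, theta_max, n_theta + 1)[1:]
    phis = np.arange(n_phi) * (2 * math.pi / n_phi)
    th, ph = np.meshgrid(thetas, phis, indexing="ij")
    rr = radial(th, ph)
    xyz = np.stack(
        [rr * np.sin(th) * np.cos(ph),
         rr * np.sin(th) * np.sin(ph),
         rr * np.cos(th)],
        axis=-1,
    ) * stretch
    apex = np.array([[0.0, 0.0, float(radial(0.0, 0.0)) * stretch[2]]])
    vertices = np.vstack([apex, xyz.reshape(-1, 3)])

    def vid(i, j):  # ring i (0-based), azimuth j
        return 1 + i * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):
        faces.append([0, vid(0, j), vid(0, j + 1)])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            faces.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)])
            faces.append([vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)])
    sac = SurfaceMesh(vertices=vertices, faces=np.asarray(faces)).validate()

    neck = NeckContour(points=xyz[-1].copy())
    z_neck = float(xyz[-1, 0, 2])
    geometry = AneurysmGeometry(
        sac=sac,
        neck=neck,
        inlet_dir=np.array([1.0, 0.0, 0.0]),
        vessel_axis=np.array([1.0, 0.0, 0.0]),
        dpvi=spec.dpvi,
        outlet_diameters=(spec.dpvi,),
        lb_status="lateral",
        irregular=spec.family in ("lobulated", "undulated"),
    ).validate()
    return geometry, _closed_form_truth(spec)


def ideal_contains(spec: SacSpec, points: np.ndarray) -> np.ndarray:
    """Membership of points in the *continuous* solid the mesh approximates.

    Exact (mesh-free) oracle used for rejection-sampling volume estimates.
    """
    spec.validate()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    stretch = _stretch(spec)
    p = pts / stretch
    radial, theta_max = _radial_function(spec)
    if spec.family == "spherical_cap":
        return (p[:, 2] >= -spec.cap_offset) & (
            np.linalg.norm(p, axis=1) <= spec.radius)
    norm = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        th = np.arccos(np.clip(np.where(norm > 0, p[:, 2] / norm, 1.0), -1, 1))
    ph = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2 * math.pi)
    return (p[:, 2] >= 0.0) & (norm <= radial(th, ph))


def ideal_bounds(spec: SacSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box guaranteed to contain the ideal solid."""
    spec.validate()
    rmax = spec.radius * (1.0 + spec.undulation_amplitude + 1e-9)
    stretch = _stretch(spec)
    lo = np.array([-rmax, -rmax,
                   -spec.cap_offset if spec.family == "spherical_cap" else 0.0])
    hi = np.array([rmax, rmax, rmax])
    return lo * stretch - 1e-9, hi * stretch + 1e-9


def random_sac_spec(rng: np.random.Generator,
                    resolution: Tuple[int, int] = (64, 32)) -> SacSpec:
    """Draw a random spec spanning all five families and realistic sizes."""
    family = FAMILIES[int(rng.integers(len(FAMILIES)))]
    r = float(rng.uniform(1.0, 5.0))
    kwargs = dict(family=family, radius=r, resolution=resolution,
                  dpvi=float(rng.uniform(1.5, 4.0)))
    if family == "spherical_cap":
        kwargs["cap_offset"] = float(rng.uniform(0.1, 0.9)) * r
    elif family == "half_ellipsoid":
        kwargs["radius"] = 1.0  # size lives in the semi-axes
        kwargs["semi_axes"] = (
            float(rng.uniform(1.0, 3.0)),
            float(rng.uniform(1.0, 3.0)),
            float(rng.uniform(1.0, 5.0)),
        )
    elif family == "lobulated":
        kwargs["undulation_amplitude"] = float(rng.uniform(0.1, 0.35))
    elif family == "undulated":
        kwargs["undulation_amplitude"] = float(rng.uniform(0.05, 0.3))
    return SacSpec(**kwargs)


def random_neck_contour(
    rng: np.random.Generator, n_points: Optional[int] = None
) -> NeckContour:
    """A random simple planar contour in general 3D position.

    Star-shaped by construction (radius a positive function of the polar
    angle), hence simple; never an exact circle: either a perturbed ellipse
    or a radius-jittered polygon.
    """
    if rng.random() < 0.5:
        n = n_points or int(rng.integers(48, 128))
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        sa = rng.uniform(1.0, 3.0)
        sb = rng.uniform(0.5, 0.92) * sa
        pert = np.ones_like(t)
        for k in range(2, 6):
            pert += rng.uniform(0.0, 0.03) * np.cos(k * t + rng.uniform(0, 2 * math.pi))
        x, y = sa * np.cos(t) * pert, sb * np.sin(t) * pert
    else:
        n = n_points or int(rng.integers(3, 10))
        # angular gaps must stay below pi for a star polygon to be simple
        while True:
            t = np.sort(rng.uniform(0.0, 2 * math.pi, n))
            gaps = np.diff(np.concatenate([t, [t[0] + 2 * math.pi]]))
            if gaps.min() >= 0.05 and gaps.max() <= 2.9:
                break
        rad = rng.uniform(0.7, 1.3, n) * rng.uniform(1.0, 3.0)
        x, y = rad * np.cos(t), rad * np.sin(t)
    planar = np.column_stack([x, y, np.zeros_like(x)])
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return NeckContour(points=planar @ q.T + rng.uniform(-10, 10, 3))


def transform_geometry(
    geometry: AneurysmGeometry,
    rotation: np.ndarray,
    translation: np.ndarray = np.zeros(3),
) -> AneurysmGeometry:
    """Rigidly move a geometry; directions co-rotate, clinical fields carry."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    return AneurysmGeometry(
        sac=SurfaceMesh(geometry.sac.vertices @ R.T + t, geometry.sac.faces),
        neck=NeckContour(geometry.neck.points @ R.T + t),
        inlet_dir=R @ geometry.inlet_dir,
        vessel_axis=R @ geometry.vessel_axis,
        dpvi=geometry.dpvi,
        outlet_diameters=geometry.outlet_diameters,
        lb_status=geometry.lb_status,
        irregular=geometry.irregular,
        location=geometry.location,
        sex=geometry.sex,
        age=geometry.age,
        ruptured=geometry.ruptured,
    )


def scale_geometry(geometry: AneurysmGeometry, factor: float) -> AneurysmGeometry:
    """Uniformly scale a geometry; all stored diameters scale with it."""
    return AneurysmGeometry(
        sac=SurfaceMesh(geometry.sac.vertices * factor, geometry.sac.faces),
        neck=NeckContour(geometry.neck.points * factor),
        inlet_dir=geometry.inlet_dir,
        vessel_axis=geometry.vessel_axis,
        dpvi=geometry.dpvi * factor,
        outlet_diameters=tuple(d * factor for d in geometry.outlet_diameters),
        lb_status=geometry.lb_status,
        irregular=geometry.irregular,
        location=geometry.location,
        sex=geometry.sex,
        age=geometry.age,
        ruptured=geometry.ruptured,
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Composition and planted signal of a synthetic cohort."""

    n_ruptured: int = 253
    n_unruptured: int = 456
    effect_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_ruptured < 0 or self.n_unruptured < 0:
            raise ValidationError("n_ruptured", "counts must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be >= 0")
        return self


def _sample_morphology_pool(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Draw n morphological records with plausible, mildly correlated marginals.

    Primitive lengths are independent log-normals around clinical values and
    the derived indices are computed from their defining formulas, so the
    algebraic identities of measured records hold.  The default planted
    features (EI, SR, I) are drawn as independent factors — EI directly
    (with the hull area back-derived for consistency), SR as an independent
    ratio with DPVI carrying enough spread that MD is only a weak proxy —
    which keeps importance-recovery experiments on planted cohorts decisive.
    """
    dpvi = np.exp(rng.normal(math.log(3.0), 0.5, n))         # mm
    sr = np.exp(rng.normal(math.log(1.9), 0.35, n))          # planted factor
    md = sr * dpvi
    nd = np.exp(rng.normal(math.log(3.2), 0.45, n))
    ar = np.exp(rng.normal(math.log(0.9), 0.3, n))
    cph = ar * nd
    mph = cph * rng.uniform(1.0, 1.15, n)
    na = math.pi * (nd / 2) ** 2 * rng.uniform(0.9, 1.3, n)
    irr = rng.uniform(0.72, 0.995, n)
    nc = 2 * math.pi * np.sqrt(na / math.pi) / irr
    dv = math.pi / 6 * md * nd * cph * rng.uniform(0.5, 1.0, n)
    ui = rng.beta(1.2, 8.0, n)
    dv_ch = dv / (1.0 - ui)
    isr = rng.uniform(0.55, 0.95, n)
    sphere_area = (36 * math.pi) ** (1 / 3) * dv ** (2 / 3)
    da = sphere_area / isr - na
    k = (18 * math.pi) ** (1 / 3)
    ei = rng.uniform(0.05, 0.45, n)                          # planted factor
    da_ch = k * dv_ch ** (2 / 3) / (1.0 - ei)
    mdpn = mph * rng.uniform(0.0, 0.5, n)
    lb = (rng.random(n) < 0.6).astype(int)
    on = np.where(lb == 1, rng.integers(2, 4, n), 1)
    cod = on * dpvi * rng.uniform(0.5, 0.95, n)
    ir = np.sqrt(na / math.pi)
    is_ = (3 * dv / (4 * math.pi)) ** (1 / 3)
    return pd.DataFrame({
        "DV": dv, "DA": da, "MD": md, "CPH": cph, "ND": nd, "NA": na,
        "DPVI": dpvi, "MPH": mph,
        "IMDA": rng.uniform(20, 160, n),
        "MDNA": rng.uniform(10, 90, n),
        "INA": rng.uniform(0, 60, n),
        "PL": md * rng.uniform(0.7, 1.2, n),
        "MDPN": mdpn,
        "LB": lb,
        "I": (rng.random(n) < 0.3).astype(int),
        "AR": cph / nd, "BR": md / nd, "NR": nd / dpvi, "SR": sr,
        "DNR": da / na, "SF": da / dv ** (2 / 3), "VOA": dv / na,
        "EI": ei,
        "NSI": 1 - k * dv ** (2 / 3) / da,
        "UI": ui,
        "PR": mph / dpvi,
        "CP": 0.5 - mdpn / dpvi,
        "NC": nc, "IR": ir, "IRR": irr, "IS": is_,
        "ISR": 4 * math.pi * is_ ** 2 / (da + na),
        "ON": on, "COD": cod, "IOR": dpvi / cod,
    })


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate a labelled cohort table with the exact requested class split.

    A feature pool several times the cohort size is drawn, the planted
    logistic model assigns each pool row a rupture probability on its
    standardized features, labels are sampled from those probabilities, and
    the first ``n_ruptured`` positives / ``n_unruptured`` negatives (in pool
    order) form the cohort.  Bit-reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    target = spec.n_ruptured + spec.n_unruptured
    n_pool = max(8 * target, 4000)
    for _attempt in range(3):
        pool = _sample_morphology_pool(rng, n_pool)
        pool["age"] = np.clip(rng.normal(55.0, 12.0, n_pool), 18, 95).round(1)
        pool["sex"] = np.where(
            rng.random(n_pool) < DEFAULT_FEMALE_PROB, "F", "M")
        locs = list(DEFAULT_LOCATION_PROBS)
        pool["location"] = rng.choice(
            locs, size=n_pool, p=list(DEFAULT_LOCATION_PROBS.values()))
        eta = np.zeros(n_pool)
        for name, coeff in spec.effect_coefficients.items():
            col = pd.to_numeric(pool[name], errors="raise").to_numpy(float)
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros(n_pool)
            eta += coeff * z
        if spec.noise_sd > 0:
            eta += rng.normal(0.0, spec.noise_sd, n_pool)
        labels = rng.random(n_pool) < expit(eta)
        pos = np.flatnonzero(labels)[: spec.n_ruptured]
        neg = np.flatnonzero(~labels)[: spec.n_unruptured]
        if len(pos) == spec.n_ruptured and len(neg) == spec.n_unruptured:
            keep = np.sort(np.concatenate([pos, neg]))
            out = pool.iloc[keep].reset_index(drop=True)
            out["ruptured"] = labels[keep].astype(int)
            return out
        n_pool *= 4
    raise ValidationError(
        "effect_coefficients",
        "planted model too extreme to realize the requested class counts",
    )
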