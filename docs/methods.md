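# Methods

This note records the measurement conventions, the numerical choices, the
design of the synthetic generators and the classification protocol, and
what the shipped tests do and do not demonstrate.

## Geometry model

An aneurysm is represented as an **open sac mesh** (the dome surface,
triangulated, no cap across the ostium) plus a **neck contour** (ordered
closed 3D polyline, first point not repeated) and scalar/vector metadata:
inlet flow direction, parent-vessel axis (both unit vectors), parent-vessel
inlet diameter DPVI, outlet diameters, lateral/bifurcation status,
irregularity flag, and the clinical fields (age, sex, location). Units are
millimetres and degrees throughout — the clinical convention; no other
convention is standard for image-derived vascular geometry.

Keeping the sac open makes the dome area DA unambiguous; closing the sac is
an explicit operation (`cap_neck`) that fan-triangulates from the contour
centroid and verifies watertightness (every edge in exactly two faces, no
repeated directed edge). Annotations travel in a JSON sidecar
(`neck_points`, `inlet_dir`, `vessel_axis`, `dpvi_mm`,
`outlet_diameters_mm`, `lb_status`, `irregular`, `location`, `sex`, `age`,
`ruptured`): human-editable and diffable, which matters for fixtures.

## Measurement conventions

Several quantities in the battery are named but not operationally defined
in common usage; the conventions adopted here are:

- **Neck plane** — total-least-squares fit to the contour points (smallest
  eigenvector of their covariance), origin at the contour centroid, normal
  oriented toward the sac centroid. TLS is rotation-equivariant, which the
  invariance tests rely on.
- **CPH** (central height) — distance from the neck centroid to the
  *farthest* intersection of the ray along the plane normal with the sac
  surface. For folded sacs "height above the neck center" is otherwise
  ambiguous; the farthest-hit rule is monotone under dome growth and
  satisfies CPH ≤ MPH by construction. A miss raises an error and flags a
  pathologically tilted sac.
- **MPH** — maximum signed vertex distance above the neck plane.
- **MD** — exact maximum pairwise distance over sac vertices (dome + rim;
  the synthetic cap vertex is excluded by construction). Hull-accelerated
  above 400 vertices; equals brute force, ties broken by the smallest index
  pair. Note that for symmetric sacs (circular rims, surfaces of
  revolution) the *diameter pair* is not unique, and the angle metrics that
  depend on its orientation are then defined only up to that degeneracy.
- **ND** — chord of the projected neck polygon through the neck centroid
  along the in-plane projection of the inlet direction (total extent
  between the extreme boundary crossings). A flow direction perpendicular
  to the neck plane leaves ND undefined and raises an error.
- **Angles** — the MD vector is oriented from the endpoint nearer the neck
  centroid to the farther one. IMDA = angle(inlet, MD) ∈ [0°, 180°];
  MDNA and INA are angles to the neck *plane* (90° minus the angle to the
  normal) ∈ [0°, 90°].
- **MDPN** — the closed sac is sliced parallel to the neck plane at 200
  uniform offsets in [0, MPH] (a hair inside the ends to avoid degenerate
  slices exactly on the cap or apex); the reported value is the offset of
  the largest cross-section, ties resolving toward the neck. Cross-section
  area uses directed plane–triangle intersection segments and an
  order-free shoelace sum, so no polygon assembly is needed.
- **NA vs NC** — the ostium area NA is measured on the planar projection of
  the contour (area is a planar property); the neck circumference NC on
  the original 3D polyline (perimeter is a curve property). For warped
  contours NC therefore exceeds the projected perimeter, and IRR remains
  below 1.
- **Convex hull** — taken of the *closed* (capped) sac; DA_CH includes the
  hull's cap-side surface. Consequence: for a hemisphere EI = 1/3 while
  NSI = 0. Had the hull area excluded the cap, EI of a hemisphere would be
  0 as well; the capped convention is used consistently and documented
  here because published definitions do not settle it.
- **UI** is clamped at 0: on exactly convex sacs floating-point round-off
  can push DV a few ulp past DV_CH.
- **SF** retains its dimensional character (DA/DV^(2/3)); it is not
  rescaled.
- **Irregularity I** is an annotation consumed as given (clinical databases
  provide it). When absent, the documented fallback proxy is
  I = (UI > 0.05).
- **LB** is encoded 0 = lateral, 1 = bifurcation.
- Degenerate-face tolerance 1e-12 mm²; boundary/contour matching tolerance
  1e-6 mm; unit-vector tolerance 1e-9.

Volume uses the divergence theorem (signed tetrahedra against the origin,
absolute value so global winding does not matter); area is the triangle
sum; hull quantities come from Qhull.

## Synthetic sacs

All five families are radial graphs r(θ, φ) over a polar cap on a
structured (n_θ × n_φ) grid with a single apex vertex; the last ring *is*
the neck contour, so capping is exact and deterministic (same spec ⇒
byte-identical mesh). Families and their closed-form truth:

- **hemisphere** (radius r): DV = 2πr³/3, DA = 2πr², NA = πr², NC = 2πr,
  MD = 2r, CPH = MPH = r, MDPN = 0, NSI = 0, UI = 0, IRR = 1, EI = 1/3.
- **spherical_cap** (R, offset h below center): DV = πH²(3R−H)/3 with
  H = R + h, DA = 2πRH, neck radius a = √(R²−h²), CPH = MPH = H,
  MDPN = h, MD = 2R.
- **half_ellipsoid** (a, b, c): DV = 2πabc/3, NA = πab, NC from the
  complete elliptic integral, CPH = MPH = c; DA closed-form for spheroids
  (a = b).
- **lobulated**: hemisphere with a Gaussian radial bump toward a fixed
  off-axis direction, tapered by sin 2θ so the apex and the neck stay
  exact. The bump breaks every symmetry (unique diameter pair) and makes
  the sac non-convex (UI > 0).
- **undulated**: r = r₀(1 + a·sin 4θ·sin 4φ); the ripple vanishes at the
  apex and the neck, and produces controllable undulation (UI ≈ 0.24 at
  a = 0.25).

Mesh refinement converges monotonically to the closed forms; at (128, 64)
every truth value is reproduced within 1%, at (32, 16) within 5% (tested).
For families without closed-form volume, the test oracle is rejection
sampling against the *continuous* solid (analytic radial membership),
which is independent of the divergence-theorem code path; those fixtures
are meshed at (192, 192) so discretization bias is negligible against the
Monte-Carlo band.

Random contours for the isoperimetric suite are star-shaped by
construction — perturbed ellipses (dense, Fourier radial perturbation) or
radius-jittered polygons with angular gaps kept below π, which guarantees
simplicity — embedded at random 3D orientations. None is an exact circle,
so IRR < 1 strictly.

## Synthetic cohorts

The default cohort emulates the composition of the open multi-centric
morphology registries the method targets: **253 ruptured / 456
unruptured** records, ICA/MCA/ACA as the most frequent locations
(frequencies 0.28/0.25/0.20, then PCA 0.10, BA/VA 0.07, other 0.10 — the
exact numbers are this package's choice), 68% female, age ≈ N(55, 12²).
(The registry literature variously counts 708 or 709 aneurysms for the
253 + 456 split; the generator follows the split.)

Features are sampled as independent log-normal primitive lengths around
clinical values, with every derived index computed from its defining
formula, so generated records obey the same algebraic identities as
measured ones (SR = MD/DPVI, IR = √(NA/π), CP = 0.5 − MDPN/DPVI, … —
tested). Labels come from a planted logistic model on standardized
features (default log-odds: EI +1.2, SR +0.8, I +0.6; magnitudes are this
package's choice, sized to make recovery experiments decisive); an
optional `noise_sd` adds Gaussian noise to the linear predictor. The exact
class split is enforced by case-control subsampling from a larger
generated pool — the same way a retrospective clinical cohort fixes its
case and control counts — which preserves "labels drawn from the planted
model" while making the composition deterministic.

Two generator-design points matter for interpreting the tests:

1. The planted features are constructed to be nearly independent of the
   rest of the battery (EI is drawn directly, with the hull area
   back-derived for consistency; SR is an independent ratio with DPVI
   carrying enough spread that MD is only a weak proxy). Real cohorts are
   more collinear, so attribution on real data will be harder than these
   tests suggest.
2. What the cohort does *not* emulate: the true feature covariance of any
   registry, location- or sex-dependent rupture rates, measurement error,
   or missing data. Passing pipeline tests demonstrates correctness of
   the protocol's mechanics and recoverability under the planted model —
   not clinical performance.

## Classification protocol

Stratified 80/20 train/test split (seeded), then per-family grid search
scored by stratified five-fold cross-validation on the training portion.
Standardization is fitted inside each training fold (scaler inside the
pipeline), so no test statistics leak into model selection; a canary test
(a feature equal to the label on held-out rows only) verifies CV scores do
not inflate. Default grids are deliberately compact: SVM kernel ∈
{linear, rbf} × C ∈ {0.1, 1, 10}; KNN k ∈ {3…15}; RF depth ∈
{None, 6, 12} at 200 trees; XGB depth ∈ {3, 6} × learning rate ∈
{0.1, 0.3} at 200 trees; MLP hidden sizes ∈ {(32,16,8), (64,32,16)}. The
MLP uses three hidden layers with the **identity activation** and an
adaptive SGD learning rate — taken literally, which makes the network a
composed linear map (unusual, but it renders the connection-weight product
an exact signed attribution; tested against the composed map to 1e-9 on
the probability scale).

Evaluation: accuracy on train and test, precision and recall with
**ruptured as the positive class** (the clinically prioritized error
direction), an overfitting flag when train − test accuracy exceeds 0.10,
and the ROC curve by threshold sweep with trapezoidal AUC (equal to the
Mann–Whitney concordance probability, ties counted ½ — tested against
brute-force pairwise concordance and against scikit-learn). Precision with
zero predicted positives is reported as 0 with a warning flag.

Importance: linear-SVM signed coefficients; permutation importance for
rbf-SVM and KNN (signed — a harmful permuted feature goes negative);
native split-gain importances for RF/XGB (unsigned by nature); MLP
connection-weight products (signed, exact under the identity activation).
All weights refer to standardized features. For cohort-level attribution
the dedicated `linear_svm_importance` helper fits a strongly regularized
linear SVM (C = 0.02): morphometric batteries contain near-collinear
clusters (IR is a deterministic transform of NA; NSI and SF are monotone
transforms of each other), and with weak regularization the margin problem
is ill-conditioned within a cluster — proxy pairs can take large
opposite-sign weights that carry no information about the label.
Ridge-like shrinkage shares weight inside a cluster and leaves the ranking
to genuine signal; on planted cohorts the attribution then recovers
{EI, SR, I} as the top three in 20/20 seeds, degrading as C grows exactly
as the conditioning argument predicts.

## Problem sizes and numerical defaults

The shipped tests use grids (32, 16)–(128, 64) for conformance, (192, 192)
for Monte-Carlo oracle fixtures, 100-element randomized suites for the
isoperimetric bounds, 10⁶ Monte-Carlo points, and cohorts of 150–709 rows
(the determinism check runs the full five-family protocol twice at n =
300). These sizes are chosen so the whole suite runs in a few minutes on
one core while every property is exercised at a scale where its failure
modes (discretization bias, sampling noise, degenerate ties) are visible.

## Known limitations

- The neck contour must project to a simple polygon on its best-fit plane;
  severely overhanging ostia violate this and are rejected rather than
  mis-measured.
- MDPN is resolved only to MPH/(n_slices − 1); the default 200 slices puts
  that well below mesh discretization error for realistic sacs.
- Angle metrics inherit the non-uniqueness of the diameter pair on
  symmetric sacs (see MD above).
- The irregularity proxy (UI > 0.05) is a crude stand-in for a clinical
  judgement; it exists so unannotated geometries remain measurable.
- The synthetic cohort supports protocol validation, not effect-size or
  performance claims about real aneurysm populations.
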