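# aneumorph

Morphometry of cerebral aneurysm sacs and rupture-status classification.

Cerebral aneurysms — balloon-like out-pouchings of arteries in the Circle of
Willis — are assessed for rupture risk largely through the shape of the sac.
`aneumorph` computes a battery of **35 morphological parameters** from a
triangulated 3D sac surface (plus a neck-contour annotation) and runs a
five-family machine-learning protocol that classifies aneurysms as ruptured
vs unruptured and attributes the decision to individual shape features.

The battery comprises 27 established descriptors — volumes, areas, heights,
angles and their ratios, including the convex-hull indices

```
EI  = 1 − (18π)^{1/3} · DV_CH^{2/3} / DA_CH      (ellipticity index)
NSI = 1 − (18π)^{1/3} · DV^{2/3} / DA            (nonsphericity index)
UI  = 1 − DV / DV_CH                             (undulation index)
```

— and 8 novel isoperimetric/outlet descriptors built on "ideal" reference
shapes:

```
IR  = √(NA/π)            IRR = 2π·IR / NC        (roundness: circle ⇒ 1)
IS  = (3·DV / 4π)^{1/3}  ISR = 4π·IS² / (DA+NA)  (sphericity: sphere ⇒ 1)
ON  = #outlets           COD = Σ outlet diameters    IOR = DPVI / COD
```

IRR ≤ 1 because the circle has the smallest perimeter among planar shapes of
equal area; ISR ≤ 1 because the sphere has the smallest surface among solids
of equal volume. Both bounds are exercised continuously by the test suite.

Because the open multi-centric morphology databases the method targets are
not bundled, the package ships a first-class synthetic module: parametric
sac families (hemisphere, spherical cap, half-ellipsoid, lobulated,
undulated) with closed-form ground truth, and labelled cohorts (default 253
ruptured / 456 unruptured) with a planted logistic signal for end-to-end
pipeline validation.

## Worked example

Measure a spherical-cap sac (sphere radius 2 mm cut 1 mm below its center,
so the sac bulges past its widest section):

```python
from aneumorph import SacSpec, make_sac, compute_all

geom, truth = make_sac(SacSpec(family="spherical_cap", radius=2.0,
                               cap_offset=1.0, resolution=(128, 64)))
rec = compute_all(geom)
print(rec.CPH, rec.MDPN, rec.ISR)
```

Selected fields of the record (mm, mm², mm³, degrees):

```
DV     28.2273     # sac volume  (closed form: 28.2743)
DA     37.6714     # dome area
NA      9.4096     # ostium (neck) area
MD      4.0000     # maximum diameter = sphere diameter
CPH     3.0000     # central height = R + offset
MDPN    0.9950     # widest parallel section sits ~1 mm above the neck
NSI     0.0554     # slightly non-hemispherical
UI      0.0000     # convex: no undulation
IRR     0.9996     # circular neck
ISR     0.9522     # close to, but below, the spherical bound
```

Run the full pipeline from the shell:

```sh
$ echo '{"kind": "cohort", "seed": 0}' > cohort.json
$ aneumorph simulate --config cohort.json --out run
wrote run/cohort.csv (709 rows)
$ aneumorph train-eval --table run/cohort.csv --out reports --seed 0
SVM: train_acc=0.889 test_acc=0.739 precision=0.694 recall=0.490 auc=0.777 [gap>10%]
KNN: train_acc=0.748 test_acc=0.620 precision=0.412 recall=0.137 auc=0.612 [gap>10%]
RF: train_acc=1.000 test_acc=0.725 precision=0.688 recall=0.431 auc=0.783 [gap>10%]
XGB: train_acc=0.996 test_acc=0.732 precision=0.627 recall=0.627 auc=0.789 [gap>10%]
MLP: train_acc=0.794 test_acc=0.754 precision=0.674 recall=0.608 auc=0.794
```

Each line reports train/test accuracy, precision and recall for the
ruptured class, and the ROC AUC; `[gap>10%]` flags a train-test accuracy
gap above 0.10 (the protocol's overfitting rule of thumb). `reports/`
contains the full JSON reports, per-model ROC curves as CSV, signed feature
importances and a cohort summary.

## Layout

- `aneumorph.geometry_io` — STL/OBJ/PLY meshes + JSON annotations, CSV
  feature tables
- `aneumorph.mesh_core` — capping, volume/area, convex hull, neck plane,
  heights, parallel sections
- `aneumorph.morphometry` — the 35-parameter record
- `aneumorph.synthetic` — sac families with ground truth, random fixture
  suites, labelled cohorts
- `aneumorph.classify` — standardization, five model families with grid
  search + five-fold CV, ROC/AUC, signed importance
- `aneumorph.cli` — `aneumorph measure | simulate | train-eval`

See `docs/methods.md` for the measurement conventions, generator design and
known limitations.
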