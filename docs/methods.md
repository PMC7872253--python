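# Methods

## Scope and model

The package computes the planning and assessment quantities of bipolar
coxofemoral osteochondral allograft transplantation: a biplanar (chevron)
femoral-head osteotomy planned from four physeal-scar landmarks,
donor–recipient size matching on acetabular diameter, CT-based interface-gap
volumetry, and post-operative femoral morphometry (version, inclination,
neck length) compared against the virtual surgical plan.

All geometry lives in a right-handed patient-based frame in millimetres;
angles are reported in degrees, with internal math in radians. Volumes are
converted from voxel indices to this physical frame at load time
(index → physical via spacing, origin, direction).

## Femoral frame and measurement conventions

Post-operative limb pose in the scanner is arbitrary, so the frontal and
transverse planes are defined from the bone itself, not from scanner axes:

* `axis_prox` — best-fit cylinder axis of the diaphysis, pointing
  proximally (sign fixed by a proximal hint, e.g. head-ward).
* `axis_ml` — transcondylar direction (medial − lateral condyle),
  orthogonalized against `axis_prox`; the two must subtend > 10°.
* `axis_cc = axis_prox × axis_ml` — the stored triad is always
  right-handed; the anatomic *cranial* direction is `axis_cc` for a right
  femur and `−axis_cc` for a left one, which keeps "cranial" consistent
  across sides.

The femoral head is an orthogonal-distance best-fit sphere over the labeled
head region (algebraic linear initialization, Levenberg-style refinement,
tolerance 1e-10, ≤ 100 iterations; both criteria are available,
orthogonal-distance is the default). The neck axis runs from the head-sphere
center through the centroid of the labeled neck region. Measurements:

* **Inclination** — unsigned frontal-plane angle between the neck direction
  (toward the head) and the *distal* diaphyseal direction; ≈ 135° for a
  normal canine femur. Range (0, 180).
* **Version** — signed transverse-plane angle between the neck direction
  and `axis_ml`; anteversion (cranially directed neck) is positive on both
  sides via the side-aware frame. These sign/reference conventions are fixed
  and documented here, not inferred from any external source.
* **Neck length** — distance from the head center to the closest-approach
  point of the neck axis to the diaphyseal axis (the exact intersection when
  the axes are coplanar; generically skew 3D lines never intersect exactly).

Head/neck/diaphysis/articular regions are **inputs** (named vertex-index
lists from the generator or annotation files); no automatic anatomical
parcellation is attempted.

## Osteotomy planning and execution

The chevron plan is definitional: plane A through (craniomedial,
caudomedial, craniolateral), plane B through (caudomedial, caudolateral,
craniolateral). Because the triples share two landmarks, both planes contain
the caudomedial and craniolateral points — the chevron ridge — and the
implementation asserts this rather than assuming it. Plane normals are
oriented positive toward a head-side reference point (e.g. the head-sphere
center); the dihedral angle is an emergent property of the landmarks, so no
default is imposed.

Virtual osteotomies slice the watertight bone mesh by each half-space and
close the cut cross-sections with deterministically ear-clipped caps
(convex cross-sections take a fan path), after welding the duplicate
vertices that plane slicing introduces. Graft plus remainder conserve the
input volume to well below 0.1 %.

Graft subchondral thickness is measured at every articular vertex by
casting a ray along the inward surface normal to the first surface hit.
Since the articular surface of these grafts is spherical by construction of
the procedure, the inward normal is taken as the radial direction toward
the best-fit articular sphere center; per-vertex averaged mesh normals are
deliberately not used because cap faces share the cut-rim vertices and bias
them. The flag `thickness_ok` enforces the < 8 mm bound (structural
integrity versus recipient immune load).

Donor-to-recipient superimposition is a Kabsch least-squares proper rigid
alignment of the four physeal landmarks. A reflection optimum almost always
means mirrored/mislabeled landmarks, so it raises an error instead of
silently flipping the bone. `interface_fit` previews apposition as
symmetric sampled point-to-surface distances, restricted to the apposing
cut faces when those are identified.

## Segmentation and gap volumetry

* Bone: HU ≥ `hu_min`, default 300 HU (typical bone-window practice; the
  acquisition protocol named only a scanner "bone algorithm"). Inclusive.
* Gap: HU ≤ `hu_max`, default 250 HU, read as inclusive.
* Surfaces: marching cubes at the 0.5 level of the zero-padded binary mask;
  `process=False` is used when building trimesh objects because vertex
  merging/degenerate-face removal can re-open a closed marching-cubes
  surface. The single-voxel degenerate case yields the expected
  marching-cubes octahedron (volume ≈ voxel/6).
* The gap ROI is the intersection of the two bones' dilations (ellipsoidal
  structuring element in physical mm, default radius 2 mm) minus the bones,
  and gap components must touch both the donor-side and recipient-side bone
  (26-connectivity) — a reproducible substitute for manual ROI cleanup.
* No subvoxel/partial-volume estimation: accuracy statements hold at stated
  voxel sizes. On the 1 mm hemispherical-shell phantom the volumetric error
  drops from ≈ 8.5 mm³ at 0.5 mm voxels to ≈ 0.7 mm³ at 0.25 mm.

## Matching and statistics

Pairing maximizes the number of donor–recipient pairs subject to the
1–4 mm donor-smaller window and, among maximal assignments, minimizes
Σ|size difference − 2.5 mm| (solved as a rectangular assignment problem
with prohibitive cost on infeasible pairs). The published pairing was done
by inspection; this objective is an explicit, reproducible stand-in.

Accuracy per hip is the absolute deviation of each measured parameter from
its plan; the contralateral target is the plan mirrored across the sagittal
plane (Householder reflection; side flag flips; version, inclination and
neck length are preserved because reflection is an isometry and the version
sign convention is side-aware).

Groups are compared with a one-tailed paired t-test,
t = mean(d)/(sd(d)/√n) with the n−1 sample standard deviation, direction
supplied by the caller per hypothesis (the study hypotheses are "guide more
accurate", i.e. guide < freehand); Shapiro–Wilk normality is computed on
the paired differences — the quantity that enters the statistic. α = 0.05,
no multiple-testing correction (none was applied in the source study;
recorded as-is). Zero-variance differences raise a degenerate-input error.

## Synthetic data: what it emulates and what it does not

`generate_femur` builds a stylized canine proximal femur: head sphere
(default r = 10 mm) on a cylindrical neck (r = 5 mm) whose direction
realizes the requested inclination/version relative to a cylindrical shaft
(r = 7 mm, length 80 mm) with condylar prominences. Defaults (inclination
135°, anteversion 20°, neck length 35 mm) approximate a 20–40 kg dog. With
no mesh-boolean engine required, the watertight union surface is extracted
by marching cubes over the exact signed-distance minimum of the primitives
(default pitch 0.4 mm); ground truth is analytic, so nothing downstream
depends on the meshing route. The four physeal landmarks sit on the
head–neck junction ring at the cranial/caudal × medial/lateral extremes
with axial offsets (craniomedial distal, craniolateral proximal, …) that
reproduce the undulating physeal scar and induce a genuine chevron; this
extremal-point placement replaces visual identification of the scar.
Optional Gaussian vertex noise (seeded) is applied after region labeling.
Generators are deterministic given a seed, and changing only the seed
changes only the noise realization.

`generate_graft_scene` models the donor–recipient interface as concentric
spherical caps: solid graft (r = 11 mm), recipient-bed shell at
r + gap width, a bone plug sealing the scene's open face (in vivo the
interface is enclosed by surrounding bone — without it the thresholded gap
would leak out of the rim), and a soft-tissue filler occupying the gap
shell. The closed-form gap volume (4/3)π(r_o³ − r_i³)·(1 − cos α)/2 is
recorded; for the 11→12 mm hemisphere it is 831.47 mm³, verified
independently by numeric integration in the tests.

The rasterizer assigns each voxel center the HU of the innermost
(smallest-volume) containing mesh — cortical/subchondral bone 1200 HU,
marrow 200 HU, soft tissue 40 HU, background −1000 HU; plausible constants,
not a scanner model. Marrow (200 HU) sits below the 300 HU bone threshold
and above the 250 HU gap threshold by construction, so both thresholds'
discriminative roles are exercised. Inside/outside is decided by counting
triangle crossings along z-columns (vectorized over triangle-column pairs,
with a fixed sub-nanometre jitter so edges through sample columns cannot
double-count); exact per-mesh voxel counts are recorded for bookkeeping
tests.

What passing tests therefore show: the *computational* pipeline is correct
on geometry whose truth is known. What they do not show: robustness to real
CT physics (noise, partial volume, beam hardening, metal artifact from
fixation wires), to pathological anatomy (osteophytes, remodeling obscuring
the physeal scar), or to manual landmarking variability. There is no
statistical shape model; the femur is a union of primitives.

## Numerical choices

* Collinearity for plane construction: rejected below 1e-8 × the squared
  pairwise scale; plane membership asserted at 1e-9 × scale.
* Axis fitting: PCA initialization, then least-squares refinement of two
  tilt angles plus a two-parameter axis offset, minimizing the spread of
  radial distances (the cylinder criterion with radius profiled out).
  Requires anisotropy ratio ≥ 2. Sign: proximal hint if supplied, else
  positive z (ties toward positive x).
* `projected_angle` returns (−180, 180], right-hand rule about the plane
  normal; projections shorter than 1e-9 raise a degenerate-input error.
* Cap triangulation order is deterministic (lexicographic loop starts,
  fixed ear order), so clipped outputs are bit-reproducible.
* STL/PLY store float32 coordinates: mesh round trips preserve geometry to
  ≈ 4e-6 mm per coordinate at bone scale (tested at 1e-4).
* Study reports embed the config hash and seed but no timestamps, so a
  rerun with the same config is byte-identical.
* Problem sizes used by the test and acceptance runs: 0.4 mm mesh pitch for
  the 6×3×3 recovery grid, 0.25 mm voxels for shell-gap volumetry, 0.5 mm
  pitch and 0.4 mm voxels inside the 5-pair synthetic study, 200 replicates
  for the power simulation.

## Known limitations

* Region labels must be supplied; there is no automatic head/neck/shaft
  parcellation, and acetabular cup orientation is not measured.
* The interface-gap accuracy claims assume an ROI that encloses the gap;
  with ROI dilation equal to the gap width a thin boundary layer can be
  missed (observed ≈ 5 % at a 2 mm gap with 2 mm dilation).
* The paired study in `run_pipeline` draws execution errors from fixed
  error models calibrated to the published group means; it is a structural
  echo of the cadaver comparison, not a re-analysis of it (the raw
  per-subject cadaver data are not available).
* Physical guide hardware (shelves, drill sleeves, the acetabular jig) and
  fixation-wire planning are out of scope; the package stops at the
  geometry the guides are meant to realize.
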