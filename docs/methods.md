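# Methods

This note documents the models, algorithms and numerical choices behind
`dentiform`, in the order data flows through the package.

## Geometric kernel

Curves are polynomial B-splines (`scipy.interpolate.BSpline` under the
hood). Open curves use clamped knot vectors (end-knot multiplicity
degree+1), so they interpolate their end control points; closed curves
wrap the first `degree` control points over a uniform knot vector and
evaluate periodically with C^(degree−1) seam continuity. Degree is
cubic by default, reduced to `n−1` when a curve has fewer than four
control points. All weights are 1: uniform-weight rational splines are
exactly polynomial B-splines, and nothing in the tooth construction
needs genuinely rational geometry (no exact conics are required —
"circular" sections are closed cubic B-splines normalised to the target
width, which is what matters for the measurement contract).

Surfaces come in three constructions:

* **Loft**: closed sections stacked along v. Between sections the
  surface interpolates with a shape-preserving piecewise-cubic
  (PCHIP) spline per ring point. PCHIP was chosen over a global cubic
  B-spline interpolant because it cannot overshoot: a loft through
  sections of widths 4.2 → 6.5 → 6.3 mm stays inside the data range,
  which the parameter-faithfulness contract depends on. Two sections
  degenerate to a ruled surface. Sections are auto-reoriented
  counter-clockwise about +z before skinning (robustness over
  strictness).
* **Coons patch**: the standard bilinearly blended patch from four
  boundary curves; restricted to any edge of the unit square it
  reproduces the boundary curve exactly, which is what makes
  multi-patch crowns watertight after vertex welding.
* **Revolution**: a half-plane profile (x = radius ≥ 0, z = axial)
  swept about an axis; u is the angle fraction.

Tessellation samples the surface on an `nu × nv` parameter grid
(defaults 64 × 48-class resolutions; chosen so the analytic
cylinder/sphere area tests pass within 2%). Closed-in-u surfaces are
seam-welded by index wrapping; end rings whose spatial extent is below
a tolerance collapse to a single apex vertex with a triangle fan (pole
welding). Face windings are made globally consistent by propagating
pairwise edge-direction parity over a spanning forest of the
face-adjacency graph, then oriented outward via the signed volume —
a vectorised equivalent of the usual per-face traversal repair.

## Tooth construction

Canonical frame: tooth axis = +z (occlusal up), mesial = +x,
buccal/labial = +y, origin at the CEJ-plane centre. The templates hold
only dimensionless ratios, so builds are exactly scale-equivariant.

**Incisor.** Root: loft through four closed sections — apex (scaled to
1% of RAD and pole-welded), mid-root with width exactly RAD at half
root length, a subcervical collar at 1.03·CEJ, and the cervical section
at CEJ. The collar creates a slight cervical constriction — the
anatomical neck — and is what makes the CEJ *identifiable from the
geometry alone* as a local width minimum; with a monotone root→equator
width profile the CEJ plane would be undetectable from a mesh with no
prior knowledge of crown height. Connection loft: CEJ ring → equator
ring (width EQU at 0.32·C_H above the CEJ). Crown: four Coons patches
bounded by the equator ring quadrants, four profile curves and a flat
incisal edge curve at exactly z = C_H. The incisal edge is
mesio-distally asymmetric (the distal corner more rounded) and the
sections labially biased; besides being anatomically motivated, these
asymmetries remove the 180° rotational ambiguity that would otherwise
make rigid registration of an incisor ill-posed.

**Molar.** Crown: loft through the CEJ ring, the equator ring and an
occlusal rim whose height varies around the ring (mesial side up to
MC_H − dome, distal to DC_H − dome), capped by two ruled patches
between the rim halves and a shape-preserving cusp-ridge curve that
attains exactly MC_H at the mesial cusp and DC_H at the distal cusp
with a central fossa dip. The occlusal relief is deliberately smooth —
two cusps and a fossa, no fissure detail — because the crown of such a
model is expected to be replaced by an optical scan in downstream use;
the contract is the measured heights and widths, not cusp morphology.
Trunk: loft from the CEJ ring (with the same 1.03 collar) down to the
furcation level, where the section is a smooth soft-max support-function
outline enclosing the root circles with a positive clearance. The
furcation itself is an explicit "pant-leg" junction: the trunk ring
splits at two saddle points into chains zipped to the outer halves of
the two root rings, the facing root-ring halves are zipped to each
other (the furcation floor/fornix), and two saddle triangles close the
junction — giving a watertight two-contour topology below the furcation
without any boolean operations. Each root is a surface of revolution
whose monotone (PCHIP) radius profile passes exactly through RAD/2 at
half root length and tapers to a welded apex pole. With `PRAD`/`PT_H`
given, a palatal root splits off first through a second, y-oriented
junction (maxillary configuration). The furcation sits `H_FURC` above
the shorter root apex when given (it is measured clinically and
geometrically necessary, even though the molar build could default it),
else at 0.72 of the shorter root length.

Derived feasibility (roots fitting inside the trunk with positive web
gap and inter-root clearance, half-root-length lying below the
furcation) is validated at build time with named parameter errors.

## Mesh metrology

Widths follow the panoramic projection convention: the width of a
horizontal slice is its mesio-distal (x) extent. The width profile is
computed on 200 uniformly spaced z-levels (face/plane crossings,
vectorised), with 3-point parabolic refinement of extrema. The equator
is the widest slice in the occlusal region (top 45% of the axial
extent); the CEJ plane is found by walking apically from the equator
while tracking the running width minimum and stopping once the width
has risen a cumulative 0.5% above it — i.e. the first local minimum,
which the builders guarantee to be the cervical constriction. This
replaces a simpler "narrowest slice in the middle third" rule, which is
ill-posed on teeth whose root keeps narrowing through the middle third.
Cross-section contours are counted via connected components of the
face-adjacency graph restricted to plane-crossing faces; the furcation
is the top of the z-band in which mesial and distal contours are
separate (refined by bisection), per-root apexes come from clustering
sub-furcation vertices around the contour centroids, and root widths
are slice extents of the matching contour at half root length
(CEJ-to-apex midpoint, the same convention the builders use).

Dahlberg's error is `S_D = sqrt(Σ d_i² / 2n)` over replicate pairs; it
estimates the standard deviation of a single reading's error and is
scale-equivariant. Scale calibration fits the multiplicative factor
minimising `Σ (ref_i − f·target_i)²` in closed form (`f = ⟨r,t⟩/⟨t,t⟩`);
it is direction-agnostic — the package's convention is that the factor
multiplies the *target* method's values onto the reference's scale.

The comparison protocol delegates Shapiro–Wilk, Wilcoxon signed-rank
and Kruskal–Wallis to `scipy.stats` — the contract here is the
protocol's structure (normality per method and per paired difference;
pairwise Wilcoxon overall, per arch and per tooth group from FDI
notation; omnibus Kruskal–Wallis across methods and across tooth
groups), not a re-derivation of test internals. All-zero paired
differences report p = 1 with a "degenerate" flag (the exact test is
undefined, but identical methods should read as "no difference");
groups with fewer than two pairs are flagged "insufficient data" rather
than crashing. Raw p-values are reported without multiple-testing
correction, mirroring the protocol structure being emulated; this is
documented, not endorsed.

## Segmentation and threshold calibration

Scalar volumes are axis-aligned grids with per-axis spacing and an
origin; a minimal NRRD reader/writer (ASCII header, raw little-endian
data) covers file exchange, since no NRRD library is part of the
package's dependency set. Iso-surfaces come from scikit-image's
marching cubes (Lewiner variant; its ambiguity resolution is adopted,
not re-derived), with spacing/origin applied to reach mm coordinates.

Binary occupancy volumes of a closed mesh are computed by per-slice
scanline parity (cross-section segments cast against +x rays from the
grid points) — equivalent to a winding-number test for closed meshes
but linear in grid size. Threshold calibration sweeps a user-supplied
tau grid (no derivative-based search: the objective is cheap and
possibly non-smooth), best-fit aligns each extracted surface to the
reference and records the mean absolute vertex-to-reference distance;
tau* is the arg-min. For a symmetric blur of a binary occupancy the
half-level surface is preserved, so tau* ≈ 0.5 up to curvature effects;
a uniformly inflated reference pushes tau* below 0.5 (lower thresholds
enlarge the segmented object). A single global threshold is used.

## Registration and deviation mapping

Best-fit alignment is point-to-surface ICP: moving vertices (subsampled
to 1200) are matched to exact nearest points on the fixed surface
(k-d-tree candidate culling over triangle centroids, then exact
point-triangle distances), and each update is the closed-form Kabsch
solution, which cannot increase the correspondence rms. Initialisation
is centroid + principal axes, trying the four proper sign combinations
and keeping the best; convergence at |Δrms| < 1e-6 mm or 200
iterations; an optional trim fraction drops the worst correspondences
for partial-overlap cases (default 0).

Signed deviation maps are one-sided (parametric → segmented), matching
the "excess/lacking" colour semantics: distance to the segmented
surface, signed by an inside/outside test. The sign comes from the
angle-weighted pseudonormal of the closest feature (face, edge or
vertex), which is exact for closed, consistently oriented meshes and
linear-time; the generalized winding number is kept as the slower
independent reference and the two are cross-checked in the test suite.
Deviation reports partition vertices into axial bands — apex (apical
15% of the extent), CEJ band (±1 mm around the CEJ plane), crown
(above), root body (the rest) — widths chosen as sensible defaults
since the regions are anatomical names without canonical widths.

## Synthetic study generator

The generator emulates, at measurement level, what a single-patient
imaging study provides. Defaults: landmark noise 0.15 mm per reading
(a digitisation floor comfortably below the 1 mm repeatability bound
the emulated protocol demands); PAN magnification ×1.15 on heights and
×1.05 on widths (vertical magnification dominates panoramic
distortion; the values sit inside the 17–27% worst-case range reported
for posterior regions, and are simulation settings, not claims about
any patient); CBCT unit 1/0.313854 mm so that scale calibration
recovers a factor of 0.313854; segmentation error as a smooth
displacement field of 0.3 mm RMS amplitude and ~6 mm wavelength (a sum
of 24 seeded harmonics rescaled to the exact RMS — smooth enough to
preserve topology and emulate global segmentation bias rather than
voxel noise). Replicate readings re-draw only the landmark noise. All
randomness flows from one seed through named `SeedSequence` substreams,
so every artifact is bit-reproducible and independently regenerable.

What the generator does *not* emulate: beam hardening, scatter and
metal artifacts; PAN image formation (only measurement-level
distortion); operator landmarking variability beyond i.i.d. Gaussian
noise; root dilaceration or other malformations (the parametric classes
cannot represent them either). Passing tests therefore demonstrate the
pipeline's correctness and its noise propagation under this error
model, not clinical accuracy on real radiographs.

## Problem sizes and tolerances

Default tessellation gives ~3.4k vertices (incisor) to ~6.8k (molar).
Round-trip parameter recovery is asserted at max(2%, 0.1 mm) over 50
random parameter sets per class; ICP transform recovery at 1e-3
rad/mm over 20 random motions below 30°/10 mm; threshold calibration
on a 0.5 mm-voxel occupancy grid with a 9-point tau grid; the
statistics error rates at 1000 protocol replicates of 50 paired
observations. These sizes keep the full validation suite at a few
minutes on one CPU while leaving each statistical check adequately
powered.

## Known limitations

* Two tooth classes only; premolars and canines are approximated by the
  single-rooted class in the synthetic arch roster.
* The CEJ is identifiable only because the builders guarantee a
  cervical constriction; meshes of real teeth with a perfectly monotone
  cervical width profile would need an operator-supplied CEJ height.
* The furcation junction floor is planar; real fornices are domed.
* One-sided deviation mapping understates discrepancies in regions
  where the segmented mesh bulges away from the parametric surface
  (a symmetric/Hausdorff variant would bound it from above).
* `estimate_scale` assumes a purely multiplicative relation; offset
  errors between methods alias into the factor.
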