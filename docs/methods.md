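# Methods

## Problem setting

A donor ("source") FE model carries cortical-bone thickness implicitly, as the
wall thickness of a one-element-thick layer of penta- and hexahedral solid
elements with distinct inner (endosteal) and outer (periosteal) skins. A target
model represents the same anatomy as a triangulated shell surface with
different size, shape and tessellation, and needs an explicit thickness value
per node. `cortimap` turns the implicit donor field into an explicit nodal
field on the target. All lengths are millimetres; no unit handling is
performed.

## Thickness extraction

Each outer-skin node is paired with the inner-skin node occupying the
topologically opposite corner of a shared solid element (hexahedron column
i ↔ i+4, wedge vertex i ↔ i+3). Pairing is required to agree across every
element sharing a node; a contradictory layer is rejected. A nearest-inner-node
fallback (`pairing_method="nearest"`) exists for layers whose element ordering
does not follow the keyword column convention, at the cost of determinism
guarantees near thin, highly curved regions.

The direction vector **d** (inner → outer) is oblique wherever the two skins
are laterally offset, so the thickness is the projection |**d** · **n̂**| on
the outward vertex normal — the absolute value guards against inconsistently
labelled skins producing negative thickness. Vertex normals are area-weighted
averages of incident face normals (angle-weighted optional); for a solid layer
each skin face is oriented against the direction from its owning element's
centroid to the face centroid, which always points out of the solid. For plain
surfaces a consistent winding is propagated across shared edges and the global
sign fixed by the signed volume (closed surfaces) or the mean outward
projection (open sheets, where the choice is immaterial for the symmetric
quantities computed here).

Degenerate geometry is reported, not rejected: nodes with thickness below a
floor (default 1e-6 mm) or with |α| = |**d** · **n̂**|/|**d**| < 0.2 (direction
vector nearly tangent to the surface) are listed in the QC report.

### Inner/outer labelling

When skin node sets are not supplied, they are derived from topology by
two-colouring the constraint graph in which nodes sharing a skin face take the
same label and through-thickness column mates take opposite labels; the colour
class lying farther from the layer centroid on average is the outer skin. The
structural validation additionally requires every element's two skin faces to
be boundary faces (owned by exactly one element), which rejects stacks more
than one element thick. This presumes the keyword node-ordering convention in
which the element's first and second node groups are the two skins; files with
other orderings must provide explicit node sets.

## Dual-Kriging morph

The morph is an exact scattered-data interpolator: per output coordinate, an
affine drift plus a radial fluctuation Σ bₛ K(‖x − xₛ‖) with the logarithmic
generalized covariance K(h) = h² log h, with K(0) = 0 as the continuity limit
(applied on the system diagonal). The coefficients solve the bordered
symmetric system

    [ K  P ] [b]   [y]
    [ Pᵀ 0 ] [a] = [0],   P = [1 | x | y | z],

whose last four rows impose the side conditions Σ bₛ = 0 and Σ bₛ xₛ = 0 that
make the problem well-posed; they also force any exactly affine correspondence
into the drift (fluctuation vanishes to solver precision). Coplanar or
duplicated control points make the system singular and are rejected with a
diagnostic. Distances are used in raw millimetres; `normalize=True` rescales to
a unit bounding-box diagonal purely for conditioning, with outputs mapped back
(results agree with the raw solve to well below 1e-6 on the scales used here).

Morph quality is scored as the distance q from each target node to the nearest
morphed source node (a nearest-neighbour correspondence via a k-d tree),
summarised as mean ± sd and max, plus the RMS distance over matched landmark
pairs. Because the fitted morph interpolates retained landmarks exactly, that
landmark RMSE is ~0 for any fresh fit; it is informative after control-point
optimization, when removed landmarks act as held-out probes.

### Control-point optimization

Backward elimination is greedy: every round refits the morph without each
remaining landmark in turn and scores the configuration by a cross-validation
RMSE over *all* original landmark pairs — retained points scored by
leave-one-out refits, removed points as probes of the current fit. The point
whose removal lowers this RMSE most is discarded; elimination stops when no
removal improves it by more than a numerical tolerance (1e-8 mm absolute),
with ties broken by the lowest landmark index for determinism. The
leave-one-out form is essential: a naive residual over retained points is
identically zero under exact interpolation and can never expose an
inconsistent landmark, whereas under CV a mis-picked point inflates both its
own held-out error and the distortion it induces at its neighbours, so it is
removed first and the objective strictly decreases.

## Projection and the β tradeoff

The projected thickness at target node i is the weighted mean of all morphed
source nodal thicknesses with weights q_ij^−β. Weights are computed in log
space and shifted by the per-node maximum before exponentiation, so β = 50 (or
500) cannot overflow; a target node coincident with a source node takes that
source value exactly (zero-distance limit, no epsilon inflation); β = 0
short-circuits to the plain source mean. All source nodes contribute (no
cutoff radius), matching the full sum; every projected value is therefore a
convex combination of source values and is bounded by the source field's
extremes. Projected values are invariant to source-node permutation and to
uniform coordinate scaling (weights are ratios of like powers).

Accuracy compares a projection to the β_max = 50 anchor, which is treated as
the faithful (nearest-neighbour-like) transfer:
A(β) = 1 − Σ(t(50) − t(β))² / Σ(t(50) − t(0))², so A(0) = 0 and A(50) = 1
identically. Smoothness starts from the per-node residual E_i of an ordinary
least-squares fit predicting the thicknesses of the nodes edge-connected to i
from their coordinates (first-order spatial model; the node's own value is not
included, and rank-deficient neighbourhoods use the minimum-norm solution so
the residual remains defined). A constant or exactly linear field gives
E_i = 0 everywhere. The reported smoothness is oriented so that
S(β) = 1 − Σ(E(50) − E(β))² / Σ(E(50) − E(0))², i.e. S(0) = 0 for the
perfectly smooth uniform projection and S(50) = 1 at the anchor: S measures
the fraction of the anchor's roughness a projection retains. The selected
exponent is where the rising accuracy curve crosses the falling smoothness
curve 1 − S, located by piecewise-linear interpolation on the β grid (default
0–4, 10, 25, 50); with several crossings the smallest is taken, and on the
degenerate two-point grid {0, 50} the two straight lines cross at β = 25 by
construction. A constant source field makes both metric denominators vanish;
both metrics are then defined as 1 with a warning, since every projection
equals the anchor.

## Synthetic fixtures

The generators emulate the donor/target situation with full ground truth:

- **Geometry.** Icosphere-tessellated spheres or ellipsoids (near-uniform
  valence ≈ 6, matching the regression's neighbourhood assumption). Defaults:
  semi-axes 50 × 40 × 60 mm (hip-bone scale), refinement level 2
  (162 nodes / 320 faces per skin).
- **Thickness.** Strictly positive analytic fields: constant t₀; latitudinal
  t₀ + t₁ cos θ (defaults 1.5 ± 0.5 mm, spanning the 1–2 mm range typical of
  pelvic cortical bone); Gaussian bumps. The inner skin is offset inward along
  the analytic normal by the local thickness, one wedge element per face; a
  thickness exceeding the minimum radius of curvature is rejected as
  self-intersecting.
- **Target.** A re-tessellation of the same surface (seeded random rotation of
  the icosphere and/or a different level) pushed through a known deformation:
  affine (seeded shear + 0.9 scale + translation), or a localized radial bulge
  (amplitude 0.2, angular width 0.8 rad, global scale 0.9 — a gentle,
  landmark-resolvable anthropometry change). The pre-deformation coordinates
  of every target node are retained, so the true transferred field at each
  target node is known exactly.
- **Landmarks.** Farthest-point-sampled surface nodes (default 24, seeded at
  the max-z node for determinism), matched through the true deformation, with
  optional Gaussian noise and a single injected outlier of specified offset.

What the fixtures do *not* emulate: real cortical geometry has open
boundaries, sharp ridges, locally varying element quality and hand-picked
landmarks with correlated (not i.i.d.) placement error. Passing tests
therefore demonstrate the correctness of the algorithms and their analytic
limits, not anatomical accuracy of any particular transfer.

## Numerical choices and problem sizes

- Exact-interpolation, side-condition and affine-reproduction tolerances are
  1e-8–1e-9 on millimetre-scale coordinates, comfortably above the ~1e-12
  solver roundoff of the (n+4)-sized bordered systems used here (n ≤ ~150).
- Mesh writers emit shortest-round-trip decimal floats, so write/read cycles
  are bit-exact (and trivially exceed 6 significant digits); CSV readers use
  pandas' round-trip float parser for the same reason.
- Test and acceptance runs use refinement levels 1–3 (up to 642 nodes per
  skin) and 24 landmarks, where every stage completes in seconds while the
  convergence trends (extraction error, end-to-end field recovery RMSE) are
  already monotone and well resolved.
- The β sweep's reported curves are deterministic given the inputs; the
  pipeline report is byte-identical across reruns on one machine.

## Known limitations

- The keyword reader covers the mesh-geometry cards only (`*NODE`,
  `*ELEMENT_SOLID`, `*ELEMENT_SHELL`, `*ELEMENT_SHELL_THICKNESS`), not
  materials, sets or contacts; wedge solids must use the degenerate-hexahedron
  node pattern.
- Topological inner/outer pairing assumes the column node-ordering convention;
  files violating it need explicit skin sets or the nearest-node fallback.
- The landmark RMSE reported for a fresh (unoptimized) morph is ~machine zero
  by exact interpolation and should not be read as a morph-quality measure;
  use the nearest-node q statistics, or the CV RMSE trace from optimization.
- Landmark-free (surface/ICP) registration, automatic landmark detection and
  mesh repair are out of scope; the package produces solver-ready input but
  does not run any FE solve.
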