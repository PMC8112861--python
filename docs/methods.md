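# Methods

## Mechanical model

A coronary segment is idealized as a long extruded cylinder of outer
diameter 4 mm whose cross-section carries the segmented plaque anatomy.
Evaluated away from the ends, a translationally invariant extrusion under
static luminal pressure is exactly the 2-D **plane-strain** problem, so
the cross-section is solved directly in 2-D: this replaces a 3-D
extrusion-plus-midplane-section workflow with a mechanically equivalent
and much cheaper model. Out-of-plane stress follows from
`σ_zz = ν (σ_xx + σ_yy)`.

Assumptions, in decreasing order of importance:

- **Linear elasticity, small strain.** Tissue is isotropic linear
  elastic; the pressure acts on the *undeformed* lumen boundary. The mean
  luminal displacement under 17 kPa is 10–20% of the lumen radius in the
  synthetic cohorts, at the boundary of where hyperelastic effects start
  to matter; stresses in the few most compliant lesions are likely
  underestimated.
- **Static load only.** 130 mmHg (17 kPa) luminal pressure; no flow shear
  stress, no pressure pulsation, no residual stress.
- **Fixed outer wall.** The outer 4 mm circle is fully constrained,
  modelling tethering to the surrounding tissue. This stiffens the
  response relative to a free or elastically supported adventitia.
- **Region-wise homogeneous materials** (defaults, overridable):

  | region | E | ν |
  |---|---|---|
  | fibrous cap | 244 kPa | 0.27 |
  | necrotic lipid core | 1 kPa | 0.48 |
  | calcification | 10 GPa | 0.30 |
  | vessel wall | 800 kPa | 0.27 |

  Named sensitivity variants: `wall_incompressible` (ν → 0.48 for wall
  and cap), `soft_calcification` (E → 10 MPa), `bone_calcification`
  (E → 20 GPa). These bracket the literature spread; the sensitivity
  stage quantifies their effect with paired t-tests.

## Discretization

The mesher builds a structured banded polar grid of 6-node quadratic
triangles around the lumen centroid. Radial *rings* follow the material
interfaces — lumen boundary, cap outer boundary, the inclusion outer
boundary inside each lipid/calcification sector (blended by a cosine ramp
to a default mid-wall radius outside it) — and angular *spokes* include
the inclusion sector edges exactly, with a cosine grading that clusters
spokes near those edges. Every element therefore lies wholly inside one
material region and region boundaries are element edges. Mid-edge nodes
sit at chord midpoints (straight-sided elements): the map is affine, so
element validity follows from ring monotonicity, and the boundary-chord
error is O(h²), the same order as the discretization.

Supported geometry class: cross-sections star-shaped about the lumen
centroid, with radially contiguous inclusions attached to the outer side
of the cap — the class the synthetic generator emits and a good
approximation of OCT segmentations of non-dissected plaques. Arbitrary
multiply-nested topologies are out of scope and rejected with an error.

Element type and sampling:

- Quadratic (6-node) triangles: better interface stress accuracy and
  resistance to volumetric locking at ν = 0.48 than linear elements.
- Stresses are recovered at **element centroids** (no nodal
  extrapolation), deliberately avoiding singular-corner amplification of
  the max-type endpoints; peak metrics are instead checked for mesh
  convergence (below).
- Load: consistent nodal forces from 3-point Gauss integration of the
  pressure traction over the curved quadratic lumen edges.
- Solver: direct sparse factorization of the reduced symmetric system in
  double precision. Iterative solvers are deliberately not used: the
  stiffness contrast spans seven orders of magnitude (1 kPa lipid to
  10 GPa calcification).
- Units: geometry in mm, moduli and pressure in Pa internally (a
  consistent pair for the per-unit-thickness 2-D problem); outputs in kPa.

Refinement ladder: `coarse` (2×), `fine` (1×, default: cap tangential
target 0.05 mm, wall 0.2 mm), `very_fine` (0.5×). The cap is resolved
radially 5× finer than its tangential target (minimum 3 layers): the peak
cap stress is read at centroids, so its mesh stability is governed by the
innermost-layer thickness.

**Verification.** On a homogeneous annulus (a = 1 mm, b = 2 mm,
E = 800 kPa, ν = 0.27, p = 17 kPa, fixed outer edge) the solver is
checked against the closed-form axisymmetric solution
`u(r) = A r + B/r` with `σ_rr(a) = −p`, `u(b) = 0`:
`A = −p / (2(λ+μ) + 2μ b²/a²)`, `B = −A b²`. The maximal relative von
Mises error is ≈0.9% at `coarse`, ≈0.2% at `fine` and <0.1% at
`very_fine`, decreasing monotonically.

**Peak-stress mesh stability.** Between `fine` and `very_fine`, PCS
changes by well under 2% when the peak lies in the cap interior. When the
peak sits at a lipid *shoulder* — the junction of cap, core and wall, an
inherent stress riser — the change is 2–4%. This is a property of
max-type metrics near material junctions, not of the solver; the
regression test asserts the measured bound (max < 4.5%, median < 2%).

## Stress endpoints and rupture proximity

PCS is the maximal centroid von Mises stress over cap elements, MPS over
all solid elements (a switch can exclude calcification interiors, whose
stiff cores can dominate the maximum). Argmax ties break to the lowest
element index, making outputs deterministic. The mean luminal
displacement fraction is the mean displacement magnitude of lumen
boundary nodes divided by the mean lumen radius — one defensible reading
of an "average displacement" linearity diagnostic whose exact
normalization is not standardized.

For ruptured lesions, the rupture-proximity statistic is the wrapped
angular distance (in [0°, 180°]) between the rupture angle and the
PCS/MPS angles, aggregated as mean ± sd and the fraction within 10°, plus
30°-bin polar histograms.

## Synthetic cohort

The generator emulates the two study populations from their published
summary statistics; it is the test substrate, not a patient model.

- Continuous morphology ~ truncated normal (FCT ≥ 20 µm, arc ∈ [30°,
  360°]); binary features ~ Bernoulli. Group defaults: minimal FCT
  97 ± 15 / 49 ± 10 µm, maximal lipid arc 110 ± 8 / 178 ± 39°,
  macrophages 40%/60%, spotty calcification 70%/80% (stable/vulnerable).
- Lipid *length* (a pullback-scale quantity with no printed summary) is
  set to 35 ± 10 / 55 ± 15 mm so that arc × length reproduces the
  published lipid-volume-index group means (≈3850 / ≈9800 °·mm).
- Geometry: lumen = smoothly perturbed circle (low-order Fourier
  waviness, radius 1.0 ± 0.12 mm); cap thickness profile cosine-tapered
  from a group-level maximum (140/105 µm, placing the realized mean FCT
  at the published 133/94 µm) down to the sampled minimum at the lipid
  mid-angle — C¹, avoiding artificial stress singularities in the cap.
  The lipid core is an annular sector attached to the cap's outer side,
  full depth (0.4 ± 0.1 mm) over its arc with a ~10° cosine end-rounding
  so the outline meets the cap tangentially. An optional calcification
  sector (30 ± 10°, 0.2 ± 0.05 mm deep) is placed angularly clear of the
  lipid sector.
- Ground-truth rupture angle = realized minimal-FCT angle + wrapped
  normal noise (sd 20°, the scale of the angular scatter observed between
  rupture sites and stress maxima in patients).
- Reproducibility: each lesion draws from its own substream spawned from
  the master seed; invalid geometries are rejected and resampled
  (bounded retries). Morphology annotations are *measured* on the
  realized polygons, never copied from the sampled targets.

What the generator does **not** model, hence what passing tests do not
show about real data: fibrocalcific stable plaques whose cap is backed by
stiff tissue (the published stable group's very low cap stress,
52 ± 42 kPa, likely reflects these; the synthetic stable group sits near
120 kPa, so group separation is somewhat weaker than in patients),
positive remodeling, thrombus and dissection geometry, multi-frame
longitudinal structure, and any image-level realism.

The simulated second observer (`perturb_contours`) displaces each traced
contour radially by an independent low-order Fourier field of prescribed
RMS (inclusion inner boundaries blend with the cap field so regions stay
attached). Because both the lumen and cap carry independent fields, FCT
noise is ≈√2× the contour noise; the interobserver stage defaults to
0.01 mm, the OCT axial-resolution scale. ICC of the stress endpoints
degrades steeply with contour noise — a faithful reflection of the
strongly nonlinear thickness–stress relation.

## Vulnerability scores

Lipid volume index = mean lipid arc × lipid length (°·mm); the macrophage
volume index is defined analogously (its source definition is not spelled
out anywhere authoritative — flagged assumption). In single-frame
analysis the mean lipid arc equals the frame's arc. The Burgmaier score
uses the published coefficients
(−2.401 + 1.568·[macrophages] + 2.639·(arc/90°) + 0.255·(length/mm)
− 0.738·(FCT/10 µm)); the CLIMA score awards one point per strict
criterion (MLA < 3.5 mm², FCT < 75 µm, arc > 180°, macrophages present).
Features undefined for a lesion are set to zero before scoring.

## Statistics

Conventions chosen to match common clinical-statistics software:

- Student pooled-variance t by default (Welch by flag); accepts
  (mean, sd, n) summaries so printed tables can be re-tested directly.
- Fisher exact two-sided by the minimum-likelihood-sum definition;
  Pearson χ² (no continuity correction) is provided alongside because
  published 2×2 p-values are often the uncorrected Pearson statistic
  even when a Fisher test is stated. Both are exposed; no attempt is
  made to guess any particular software path.
- ROC: thresholds at midpoints between consecutive unique scores
  (± sentinels beyond the extremes); AUC is the tie-corrected
  Mann–Whitney statistic; orientation auto-flips so reported AUC ≥ 0.5,
  with FCT-type features explicitly oriented low-positive. Youden cutoff
  maximizes sens + spec − 1, ties broken toward higher sensitivity (a
  fixed deterministic stand-in for "clinical judgment").
- DeLong's structural-component test for correlated AUCs; its type-I
  error at α = 0.05 is verified by simulation to lie in [0.03, 0.07].
- ICC(1,1) from the one-way random-effects ANOVA decomposition.
- Multivariable logistic combination by hand-written IRLS (convergence:
  max coefficient change < 1e−8 or 100 iterations), returning fitted
  probabilities for downstream ROC; perfect separation is flagged and
  the last stable iterate returned. statsmodels serves as an independent
  cross-check in the tests, never as the implementation.
- No multiple-testing correction anywhere (matching the source setting).

All statistical operations are pure functions: identical inputs give
bit-identical outputs.

## Pipeline and reproducibility

`run_experiment` chains cohort → solve → endpoints → features/scores →
group tests → ROC/Youden/DeLong → rupture proximity, writing CSV tables,
a JSON statistics report, a run manifest (config hash, seed, versions)
and optional per-lesion VTK fields; writes are atomic (temp file +
rename). A single master seed fans out to named substreams (cohort,
perturbation, selection), so re-runs are byte-identical and stages can be
reproduced in isolation. The interobserver stage re-segments 20% of the
plaques per group (rounded up, seeded selection). Default problem sizes —
10 lesions per group at the `fine` refinement (≈4–8·10³ elements,
≈0.3 s per solve) — keep a full experiment under half a minute and the
twenty-replicate acceptance computation around two minutes on one CPU.

## Known limitations

- Plane strain ignores longitudinal stenosis profile and end effects by
  construction; lesions whose mechanics are dominated by longitudinal
  geometry are outside the model.
- The mesher's supported geometry class (star-shaped, cap-adjacent
  contiguous inclusions) excludes dissections, intra-cap cores and
  deeply embedded calcifications.
- Max-type endpoints at material-junction shoulders retain a 2–4%
  mesh dependence between refinement levels (documented above).
- The synthetic stable population under-represents fibrocalcific
  plaques, compressing the group contrast relative to patient data.
- Linear elasticity underestimates stresses for the most compliant
  lesions (displacement fractions approaching 20%).
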