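# Methods

`pyeloreg` estimates the rigid 6-DOF pose of an endoscope inside a
preoperative surface model of a branched luminal organ (the motivating
anatomy is the renal collecting system seen in flexible ureteroscopy) by
aligning two sparse 2D point sets in every video frame:

* **generated contours** — projections of 3D *salient structural points*
  of the cavity mesh, selected per candidate pose;
* **actual contours** — barycenters of high-contrast superpixels extracted
  from the endoscopic image.

A mutual-information point-set similarity scores the alignment, and a
coarse-to-fine differential-evolution (DE) search over a bounded 6-DOF box
returns the pose that maximises it.

## Salient structural points

A surface point `p` with unit normal `g` is *salient* with respect to a
search volume `V_p` (an ellipsoid placed in the central chamber) when

1. **tangency is achievable**: the tangent plane at `p` intersects `V_p`
   (tested exactly in the ellipsoid metric), and
2. **it is visible**: strictly more than `N_s` seed points, laid out on a
   square grid of pitch `seed_spacing` on that tangent-plane region, can see
   `p` without the segment meeting any mesh triangle.

On kidney-like cavities the surviving vertices trace the creases where
calyces meet the pelvis — exactly the image structures an endoscopist
recognises. Extraction runs once per model over all mesh vertices.

At registration time a candidate pose keeps the subset of salient points
that (a) it views near-tangentially — the angle between the point normal
and the viewing ray, `theta = arccos |g·w|`, is at least `theta_T`; (b) are
unoccluded from the optical centre; (c) project inside the image; and, in
the fine stage, (d) lie within the headlight working distance
`max_view_distance`.

Parameter defaults, with rationale:

| parameter | default | why |
| --- | --- | --- |
| `theta_T` | 60° | at a sharp crease the *averaged* vertex normal sits roughly halfway between the two adjacent walls, so a grazing ray reads as 45–65°, not ~90°; thresholds close to 90° apply to smooth, finely tessellated surfaces |
| `N_s` | 5 (strict) | a handful of independent sightlines suppresses single-ray artefacts |
| `seed_spacing` | 1.5 mm | a few dozen seeds per tangent-plane region at the fixture scale |
| `max_view_distance` | 20 mm | with quadratic headlight attenuation and display gamma, structures beyond ~20 mm are too dark to yield image contours; applied in the fine stage only — the coarse stage localises globally and benefits from every visible structure |

## Actual contours

The image (0–255 scale) is oversegmented with SLIC (one superpixel per
~40 px²; compactness 5). A superpixel is selected when the largest absolute
mean-intensity difference to an 8-connected neighbour reaches `tau_gc`
(default 50), it holds at least `tau_n` pixels (default 3 at the reference
density, scaled with image area), and it is darker than its brightest
neighbour — structural contours are shadowed recesses. One barycenter per
selected superpixel forms the contour point set. Optionally (`snap_radius`,
default 5 px inside the registration pipeline, 0 in the plain extractor)
each barycenter is moved to the strongest-gradient pixel nearby, which
removes most of the inward bias of region barycenters relative to the true
intensity edge; the registration search depends on that bias being small.

Sobel gradient magnitude (normalised per image) and orientation (folded to
[0, π)) are sampled bilinearly at contour points for the gradient term.

## Similarity costs

With actual points `α = {p_i}` and generated points `G = {s_j}`, distances
`d_ij = |p_i − s_j| / length_scale` define a joint probability
`p_ij = exp(−d_ij) / Σ exp(−d_ij)` whose mutual information

`C_p = Σ_ij p_ij ln( p_ij / (Σ_k p_kj · Σ_l p_il) )`

is **maximised**: alignment concentrates mass on a near-permutation joint.
The implementation subtracts the minimum distance before exponentiation
(cancels in the normalisation, prevents underflow). `length_scale`
(default 2.5 px at 200×200) is deliberately close to the pixel scale: the
kernel then acts as a soft counter of matched pairs. Large scales make the
joint rows of densely spaced correct matches overlap, which *rewards*
sparse spread-out mismatches — a pathology we observed directly.

The gradient cost uses the same MI form on
`exp(−(m_ij + o_ij))` with `m_ij` the absolute magnitude difference (both
in [0, 1]) and `o_ij` the orientation difference folded to [0, π/2] and
normalised by π/2. The grouping `exp(−(m+o))` is used: a similarity must
decay in both mismatches.

A second (auxiliary) frame, related to the reference frame by a known
inter-frame camera transform `T_0n` (in practice from tracking hardware or
scene ground truth; here exact from the generator), contributes a second
position MI evaluated at pose `T_n = T_0n ∘ T_0`. The fine cost is
`w1·C_p + w2·C_grad + w3·C_p(aux)` with defaults (0.4, 0.2, 0.4) — the
auxiliary term carries substantial weight because it is the only term that
resolves the depth ambiguity of single-view contour alignment.

## Coarse-to-fine search

Poses are parameterised as intrinsic XYZ Euler angles (deg) plus
translation (mm). scipy's differential evolution (rand/1/bin, F = 0.7,
CR = 0.9, seeded, no polish) maximises:

1. **coarse** — position MI only, over the full user box (the protocol box
   is ±15° / ±10 mm around the initial estimate). Occlusion tests are served
   from a cache keyed on a 5° / 3 mm pose grid; tangency and projection are
   exact per candidate.
2. **fine cascade** — two levels, each shrinking the box around the running
   best pose (factors 2/3 then 1/3 of the original half-widths) and
   sharpening the MI kernel (scale factors 1.0 then 0.5). Each level seeds
   the DE population with the previous winner, so the cost can only
   improve. Exact occlusion tests; gradient attributes for generated
   points are sampled from one reduced-resolution (96 px wide) virtual
   render at the level's box centre — inside a shrunk box the local edge
   structure changes negligibly, and this removes the dominant
   per-candidate rendering cost (`rerender_per_candidate=True` restores
   exact behaviour).

The scale schedule exists because the sharp kernel's basin of attraction
is narrow (±1°/±1 mm); diving straight into it from a ±15° box fails, while
the smoothed kernel alone cannot reach millimetre accuracy.

## Virtual endoscopy

A software ray caster (uniform-grid DDA acceleration, numba-compiled)
renders Phong-shaded interior views with the point light co-located with
the camera (headlight), quadratic distance attenuation
(1, 0, 0.004 mm⁻²) and display gamma 2.2. Gamma matters beyond realism:
without it, smooth shading ramps alias into chains of contrast-selected
superpixels far from any structural edge. Radial lens distortion is not
modelled. Depth maps accompany every render; the depth-discontinuity mask
(8-neighbourhood range over a threshold) serves as the test oracle for
contour locations. The oracle threshold used in tests is 1 mm, which also
captures *fold* contours (near-tangential walls) — consistent with the
tangency-based definition of salient points; a pure-jump threshold of
2–3 mm would misclassify genuine fold contours as extraction errors.

## Synthetic phantoms

The generator builds a watertight genus-0 cavity as the marching-cubes
isosurface of a signed-distance union: an ellipsoidal chamber
(semi-axes 15 × 12 × 10.2 mm — a mid-size renal pelvis) plus capped
tubular calyces (radius 4–6 mm, length 12–18 mm). Two canned variants
mirror a complex/simple contrast: **K1-like** (3 primaries each splitting
into 2 children — 6 terminal calyces) and **K2-like** (3 single-level
calyces). The isosurface lattice is offset by 0.31 cells so the surface
never passes exactly through grid nodes (exact zeros produce degenerate
faces). Ten marker points for target-registration-error evaluation are
sampled area-uniformly on the surface and pushed 5 mm outward along the
face normal. `V_p` is the ellipsoid at 0.55 × the chamber semi-axes.

Ground-truth endoscope poses sample optical centres uniformly in `V_p`
(rejection-tested to lie inside the lumen by ray parity), aim at a random
calyx opening, and roll uniformly in [−180°, 180°). A sampled pose is
accepted as a test position only if its rendered view yields at least 8
actual-contour points — the synthetic analogue of choosing phantom test
positions that view structured regions; a coaxial down-the-tube view
carries no contour information and defeats any contour-based method.
Cameras are ideal pinholes, 90° field of view (typical for ureteroscopes),
200×200 px.

What the generator does **not** emulate: real tissue texture and specular
wetness, illumination inhomogeneity, lens distortion, fluid and debris,
breathing/deformation, segmentation error in the preoperative model, and
tracking noise in the inter-frame transform (taken exact here). Passing
tests therefore demonstrate the geometric and algorithmic core under
idealised imaging, not clinical performance.

## Evaluation

* **mTRE** — mean over markers of `|T_gt p − T_est p|` (mm).
* **OE** — geodesic angle of `R_gt R_estᵀ` (deg); **PE** — `|t_gt − t_est|`
  (mm). These act on the pose matrices; an alternative reading of PE as the
  optical-centre distance differs when rotation errors exist.
* **contour agreement** — mean distance-transform lookup of contour points
  into an oracle mask (px); a plain mean-boundary-distance surrogate for
  published contour-quality indices whose exact formulas live outside this
  package.

The randomised-trial protocol (`pyeloreg.metrics.trial_suite`) perturbs a
ground-truth pose uniformly inside the ±15°/±10 mm box (the chart of the
search space), registers from the perturbed start with the box centred on
it, and reports initial/coarse/final mTRE, OE, PE per trial. The auxiliary
frame is the stored view with the widest angular baseline to the
reference. The stress protocol widens the box to ±90°/±30 mm with a larger
DE budget.

## Study size and observed behaviour

Library defaults follow the printed protocol scale (population 40,
coarse/fine 60/40 generations). The test suite and the acceptance script
run a desk-scale configuration chosen once — population 36, 40 coarse and
25 fine generations, 200×200 views, 96-px in-loop renders, 0.9 mm mesh
resolution, 4–5 stored views and 10 trials per fixture — sized so a full fixture
suite completes in minutes on one core.

Under these conditions the simple fixture (K2-like) shows large error
reduction (median mTRE falls from ~10 mm to ~2 mm; the multi-view
configuration roughly halves the single-view final error, and the fine
cascade improves on the coarse stage). The complex fixture (K1-like)
improves but saturates near 5 mm median: its sibling branches produce
near-identical contour rings that the position-MI coarse stage confuses at
±15° start offsets, and no setting of kernel scale, mesh resolution, view
resolution or auxiliary-view choice that we evaluated removes the
resulting impostor maxima. This mirrors — in exaggerated form, because the
synthetic K1 is *more* self-similar than a patient kidney — the general
observation that structural repetition is the failure mode of
contour-based registration.

## Known limitations

* Salient candidates are mesh vertices; accuracy is floored by the mesh
  resolution and by the ±1 px quantisation of barycenter snapping
  (~1.5 mm mTRE at the fixture scale).
* The MI cost ignores unmatched points by construction; highly
  self-similar anatomy can produce impostor maxima (see above).
* The visibility cache during the coarse stage trades ~1 grid-cell of
  occlusion accuracy for an order-of-magnitude speedup.
* The frozen-render gradient approximation assumes small boxes in the fine
  stage; it is exact only at the box centre.
* Image-translation objectives are provided as loss functions for
  completeness of the cost family; no networks are trained here, and the
  pipeline operates on rendered or real images directly.
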