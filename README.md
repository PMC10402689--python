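# pyeloreg

Contour-based 2D/3D rigid registration for endoscopy of branched luminal
organs — estimating *where the endoscope is* inside a preoperative surface
model from what its camera sees.

During flexible ureteroscopy of the kidney the surgeon navigates a branched
cavity (renal pelvis + calyces) with a monocular scope. Given a triangle
mesh of the cavity (from CT), camera intrinsics, one or two video frames and
a rough initial pose, `pyeloreg` recovers the 6-DOF camera pose
`T ∈ SE(3)` (model → camera) by aligning:

* **generated contours** `G = {s_j}` — image projections of 3D *salient
  structural points* (calyx rims and pelvis–calyx junctions, found by
  tangent-plane and visibility tests against a search volume `V_p`), and
* **actual contours** `α = {p_i}` — barycenters of dark, high-contrast
  superpixels extracted from the frame,

under a joint-probability mutual-information similarity

```
p_ij = exp(−‖p_i − s_j‖/σ) / Σ_ij exp(−‖p_i − s_j‖/σ)
C_p  = Σ_ij p_ij ln( p_ij / (Σ_k p_kj · Σ_l p_il) )
```

maximised coarse-to-fine with differential evolution: a position-only
search over the full ±15° / ±10 mm box, then a shrinking-box cascade that
adds a gradient term and a second-view position term
(`C_fine = w1·C_p + w2·C_grad + w3·C_p(aux)`, with the auxiliary pose
`T_n = T_0n ∘ T_0` from a known inter-frame transform).

A synthetic phantom generator (kidney-like branched cavities, exterior
marker points, ground-truth poses, Phong-rendered interior views) makes the
entire pipeline runnable and testable with no external data. Accuracy is
reported as mean target registration error (mTRE) over the markers, plus
orientation and position error (OE/PE).

## Worked example

```python
import pyeloreg as pr
from pyeloreg.registration import DEConfig, pose_encode, register
from pyeloreg.scene import SearchRange, perturb_pose
from pyeloreg.geometry import compose, invert
from pyeloreg.metrics import mtre

# synthetic phantom: simple 3-calyx collecting system, 5 endoscope views
scene = pr.make_scene(pr.k2_like_spec(seed=0, mesh_resolution=0.9), n_poses=5)
feats = pr.extract_salient_points(scene.mesh, scene.pelvis_volume,
                                  grid=scene.grid)

t_gt = scene.gt_poses[0]
box = SearchRange.around(pose_encode(t_gt), rot_deg=15, trans_mm=10)
start, _ = perturb_pose(t_gt, box, seed=5)            # simulated rough init
search = SearchRange.around(pose_encode(start), 15, 10)
t0n = compose(scene.gt_poses[1], invert(t_gt))        # inter-frame transform

res = register(scene.mesh, feats,
               [scene.rendered_views[0], scene.rendered_views[1]],
               scene.intrinsics, search,
               cfg=DEConfig(population_size=36, max_iterations_coarse=40,
                            max_iterations_fine=25, rng_seed=0),
               t0n=t0n, grid=scene.grid)

print(f"salient points: {len(feats)}")
print(f"initial mTRE: {mtre(t_gt, start, scene.markers):.2f} mm")
print(f"coarse  mTRE: {mtre(t_gt, res.pose_coarse, scene.markers):.2f} mm")
print(f"final   mTRE: {mtre(t_gt, res.pose_fine, scene.markers):.2f} mm")
```

Output:

```
salient points: 114
initial mTRE: 11.08 mm
coarse  mTRE: 2.82 mm
final   mTRE: 1.27 mm
```

The initial error is the simulated hand-alignment offset; the coarse stage
localises to a few millimetres from the position term alone, and the fine
cascade (gradient + second view) brings the median down to ~2 mm on this
fixture — the second view is what resolves the depth-direction ambiguity a
single silhouette cannot.

The same pipeline is available from the shell:

```
pyeloreg simulate --spec k2 --out scene/ --seed 0
pyeloreg extract-features --scene scene/ --out features.csv
pyeloreg register --scene scene/ --view 0 --aux-view 1 \
    --features features.csv --out result.json --seed 0
pyeloreg evaluate --scene scene/ --result result.json --out report.csv
```

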