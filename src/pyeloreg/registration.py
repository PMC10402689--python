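"""Coarse-to-fine 6-DOF pose search by differential evolution.

Stage 1 (coarse) maximises the position-only contour MI over the full
search box; stage 2 is a fine cascade whose levels shrink the box around
the running best pose and sharpen the MI kernel while maximising the
weighted cost (position + gradient + auxiliary-view position). Poses are
chased in a 6-vector chart: intrinsic XYZ Euler angles in degrees plus
translation in mm.

Actual contours are pose-independent and computed once per view; generated
contours are recomputed per candidate. During the coarse stage the
expensive occlusion test is served from a cache keyed on a 5 deg / 3 mm
pose grid; the fine levels run exact tests and sample gradient attributes
for generated points from one reduced-resolution virtual render per level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.optimize import differential_evolution
from scipy.spatial.transform import Rotation

from .contours import Contour2D, ContourParams, attach_gradients, \
    extract_actual_contours
from .features import SalientParams, SalientPointSet, generate_contour, \
    select_for_pose
from .geometry import CameraIntrinsics, RigidPose, project_points
from .raycast import TriangleGrid
from .render import LightingParams, render_view
from .scene import SearchRange
from .similarity import CostWeights, EmptyContourError, auxiliary_view_pose, \
    fine_cost, position_cost


def pose_encode(pose: RigidPose) -> np.ndarray:
    """Pose -> (rx, ry, rz deg intrinsic XYZ, tx, ty, tz mm)."""
    ang = Rotation.from_matrix(pose.rotation).as_euler("XYZ", degrees=True)
    return np.concatenate([ang, pose.translation])


def pose_decode(v: np.ndarray) -> RigidPose:
    """6-vector -> pose; angles outside +/-180 are wrapped by construction."""
    v = np.asarray(v, float).reshape(6)
    return RigidPose.from_euler_deg(v[:3], v[3:])


@dataclass(frozen=True)
class DEConfig:
    population_size: int = 40
    max_iterations_coarse: int = 60
    max_iterations_fine: int = 40
    mutation: float = 0.7
    recombination: float = 0.9
    strategy: str = "rand1bin"
    rng_seed: int = 0
    tol: float = 1e-6
    fine_range_shrink: float = 2.0 / 3.0
    #: fine-stage cascade: (box shrink factor, kernel-scale factor) pairs.
    #: Each level re-centres a shrunk box on the running best pose and
    #: sharpens the position-MI kernel — a scale schedule that funnels the
    #: search into the narrow basin of the sharp objective.
    fine_levels: tuple = ((2.0 / 3.0, 1.0), (1.0 / 3.0, 0.5))
    cache_pitch_deg: float = 5.0
    cache_pitch_mm: float = 3.0
    render_size: int = 96
    rerender_per_candidate: bool = False
    #: include the auxiliary view's position MI in the coarse objective.
    #: Off by default (the plain location cost suffices at moderate search
    #: ranges and costs half as much); essential at expanded ranges, where
    #: single-view alignment admits wrong-branch hypotheses that only a
    #: second viewpoint can reject.
    multiview_coarse: bool = False

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0 < self.recombination <= 1:
            raise ValueError("recombination must be in (0, 1]")
        if not 0 < self.mutation < 2:
            raise ValueError("mutation must be in (0, 2)")
        if not 0 < self.fine_range_shrink <= 1:
            raise ValueError("fine_range_shrink must be in (0, 1]")


@dataclass
class RegistrationResult:
    pose_coarse: RigidPose
    pose_fine: RigidPose
    cost_trace: list                 # [(stage, generation, best_cost), ...]
    evaluations: int
    converged: bool
    config: dict = field(default_factory=dict)

    @property
    def pose(self) -> RigidPose:
        return self.pose_fine

    def to_json(self, path) -> None:
        payload = {
            "schema": "pyeloreg-result/1",
            "pose_coarse": self.pose_coarse.matrix.tolist(),
            "pose_fine": self.pose_fine.matrix.tolist(),
            "cost_trace": [[s, int(g), float(c)] for s, g, c in self.cost_trace],
            "evaluations": int(self.evaluations),
            "converged": bool(self.converged),
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class _DERun:
    """One seeded DE maximisation over a box, with best-so-far bookkeeping."""

    def __init__(self, func_max: Callable, search: SearchRange,
                 cfg: DEConfig, maxiter: int, seed: int,
                 x0: Optional[np.ndarray] = None):
        self.func = func_max
        self.search = search
        self.cfg = cfg
        self.maxiter = maxiter
        self.seed = seed
        self.x0 = x0
        self.nfev = 0
        self.best_x = search.center.copy()
        self.best_v = -np.inf
        self.trace = []

    def _neg(self, x):
        self.nfev += 1
        v = self.func(x)
        if v > self.best_v:
            self.best_v = v
            self.best_x = np.array(x, float)
        return -v

    def run(self):
        lo = self.search.lower.copy()
        hi = self.search.upper.copy()
        if np.all(hi - lo <= 0):
            v = self.func(self.search.center)
            self.nfev += 1
            self.best_v = v
            self.best_x = self.search.center.copy()
            self.trace.append((0, v))
            return True
        tiny = hi - lo <= 0
        hi[tiny] = lo[tiny] + 1e-9
        gen = {"i": 0}

        def cb(xk, convergence=0.0):
            self.trace.append((gen["i"], self.best_v))
            gen["i"] += 1

        popsize = max(4, int(np.ceil(self.cfg.population_size / 6)))
        npop = popsize * 6
        from scipy.stats import qmc
        sampler = qmc.LatinHypercube(d=6, seed=self.seed)
        init = qmc.scale(sampler.random(npop), lo, hi)
        if self.x0 is not None:
            init[0] = np.clip(np.asarray(self.x0, float), lo, hi)
        res = differential_evolution(
            self._neg, bounds=list(zip(lo, hi)), strategy=self.cfg.strategy,
            maxiter=self.maxiter, popsize=popsize, tol=self.cfg.tol,
            mutation=self.cfg.mutation, recombination=self.cfg.recombination,
            seed=self.seed, polish=False, init=init,
            updating="immediate", callback=cb)
        if -res.fun > self.best_v:
            self.best_v = -res.fun
            self.best_x = res.x
        self.trace.append((gen["i"], self.best_v))
        return bool(res.success)


def coarse_search(objective: Callable, search: SearchRange, cfg: DEConfig):
    """Maximise ``objective`` over the box; return (best pose vector,
    shrunk search range centred on it, trace, nfev, converged)."""
    run = _DERun(objective, search, cfg, cfg.max_iterations_coarse, cfg.rng_seed)
    converged = run.run()
    shrunk_half = search.half_widths * cfg.fine_range_shrink
    center = np.clip(run.best_x, search.lower, search.upper)
    lo = np.maximum(center - shrunk_half, search.lower)
    hi = np.minimum(center + shrunk_half, search.upper)
    shrunk = SearchRange((lo + hi) / 2, (hi - lo) / 2)
    return run.best_x, shrunk, run.trace, run.nfev, converged


def fine_search(objective: Callable, search: SearchRange, cfg: DEConfig,
                x0: Optional[np.ndarray] = None):
    """Maximise the full fine cost inside the shrunk box.

    The coarse winner ``x0`` is injected into the initial population so the
    fine stage can only improve on it in cost.
    """
    run = _DERun(objective, search, cfg, cfg.max_iterations_fine,
                 cfg.rng_seed + 1, x0=x0)
    converged = run.run()
    return run.best_x, run.trace, run.nfev, converged


def _scaled_intrinsics(intr: CameraIntrinsics, size: int) -> CameraIntrinsics:
    s = size / intr.width
    return CameraIntrinsics(fx=intr.fx * s, fy=intr.fy * s,
                            cx=intr.cx * s, cy=intr.cy * s,
                            width=size, height=max(1, int(round(intr.height * s))))


class ContourObjective:
    """Callable cost builder shared by the two search stages."""

    def __init__(self, mesh, grid: TriangleGrid, features: SalientPointSet,
                 intr: CameraIntrinsics, actual0: Contour2D,
                 weights: CostWeights, salient: SalientParams,
                 cfg: DEConfig, length_scale: float = 2.5,
                 actual_aux: Optional[Contour2D] = None,
                 t0n: Optional[RigidPose] = None,
                 light: Optional[LightingParams] = None):
        self.mesh = mesh
        self.grid = grid
        self.features = features
        self.intr = intr
        self.actual0 = actual0
        self.actual_aux = actual_aux
        self.t0n = t0n
        self.weights = weights
        self.salient = salient
        self.cfg = cfg
        self.length_scale = length_scale
        self.light = light or LightingParams()
        self._vis_cache = {}
        self._render_intr = _scaled_intrinsics(intr, cfg.render_size)

    # -- coarse stage -----------------------------------------------------
    def _cached_visibility(self, x: np.ndarray) -> np.ndarray:
        """Occlusion mask for all salient points at the snapped grid pose."""
        pitch = np.array([self.cfg.cache_pitch_deg] * 3
                         + [self.cfg.cache_pitch_mm] * 3)
        key = tuple(np.round(x / pitch).astype(int))
        mask = self._vis_cache.get(key)
        if mask is None:
            snapped = pose_decode(np.asarray(key) * pitch)
            oc = snapped.optical_center
            starts = np.broadcast_to(oc, self.features.points.shape)
            mask = ~self.grid.segments_blocked(starts, self.features.points)
            self._vis_cache[key] = mask
        return mask

    def _select_coarse(self, pose: RigidPose, x: np.ndarray) -> SalientPointSet:
        f = self.features
        oc = pose.optical_center
        w = f.points - oc
        dist = np.linalg.norm(w, axis=1)
        ok = dist > 1e-9
        w[ok] /= dist[ok, None]
        cosang = np.abs((f.normals * w).sum(axis=1))
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        # no working-distance cut here: the coarse stage localises globally
        # and benefits from every visible structure; the distance-limited
        # selection is a fine-stage precision measure
        keep = ok & (theta >= self.salient.theta_T)
        _, _, in_frame = project_points(f.points, pose, self.intr)
        keep &= in_frame & self._cached_visibility(x)
        return f.subset(keep)

    def coarse_value(self, x: np.ndarray) -> float:
        """Location-based coarse cost: position MI in the reference view,
        optionally averaged with the auxiliary view's position MI."""
        pose = pose_decode(x)
        sel = self._select_coarse(pose, np.asarray(x, float))
        gen = generate_contour(sel, pose, self.intr)
        c0 = 0.0
        if len(gen) and len(self.actual0):
            c0 = position_cost(self.actual0, gen, self.length_scale)
        if not self.cfg.multiview_coarse or self.t0n is None \
                or self.actual_aux is None:
            return c0
        pose_aux = auxiliary_view_pose(pose, self.t0n)
        x_aux = pose_encode(pose_aux)
        sel_aux = self._select_coarse(pose_aux, x_aux)
        gen_aux = generate_contour(sel_aux, pose_aux, self.intr)
        c_aux = 0.0
        if len(gen_aux) and len(self.actual_aux):
            c_aux = position_cost(self.actual_aux, gen_aux, self.length_scale)
        return 0.5 * (c0 + c_aux)

    # -- fine stage -------------------------------------------------------
    def prepare_fine(self, center_pose: RigidPose) -> None:
        """Render the virtual view once at the fine-stage box centre.

        Generated-contour gradient attributes are then sampled from this
        frozen render for every fine candidate; inside the shrunk box the
        local edge structure changes little, and this removes the dominant
        per-candidate rendering cost. Set ``rerender_per_candidate`` to
        re-render at every candidate instead.
        """
        if self.weights.w2 <= 0:
            return
        img, _ = render_view(self.mesh, center_pose, self._render_intr,
                             self.light, grid=self.grid)
        self._frozen_render = img

    def _generated_with_gradients(self, sel: SalientPointSet,
                                  pose: RigidPose) -> Contour2D:
        gen = generate_contour(sel, pose, self.intr)
        if len(gen) == 0 or self.weights.w2 <= 0:
            return gen
        if self.cfg.rerender_per_candidate or \
                getattr(self, "_frozen_render", None) is None:
            img, _ = render_view(self.mesh, pose, self._render_intr,
                                 self.light, grid=self.grid)
        else:
            img = self._frozen_render
        scale = self._render_intr.width / self.intr.width
        scaled = Contour2D(gen.points * scale, source="generated")
        scaled = attach_gradients(scaled, img)
        return Contour2D(gen.points, scaled.grad_mag, scaled.grad_ori,
                         source="generated")

    def fine_value(self, x: np.ndarray, breakdown: bool = False):
        pose = pose_decode(x)
        sel = select_for_pose(self.features, pose, self.intr, self.grid,
                              self.salient.theta_T,
                              self.salient.max_view_distance)
        gen0 = self._generated_with_gradients(sel, pose)
        gen_aux = None
        if self.weights.w3 > 0 and self.t0n is not None \
                and self.actual_aux is not None:
            pose_aux = auxiliary_view_pose(pose, self.t0n)
            sel_aux = select_for_pose(self.features, pose_aux, self.intr,
                                      self.grid, self.salient.theta_T,
                                      self.salient.max_view_distance)
            gen_aux = generate_contour(sel_aux, pose_aux, self.intr)
        bd = fine_cost(pose, self.actual0, gen0, self.weights,
                       self.length_scale, self.actual_aux, gen_aux)
        return bd if breakdown else bd.c_fine


def register(mesh, features: SalientPointSet, views: list,
             intr: CameraIntrinsics, search: SearchRange,
             cfg: DEConfig = None, weights: CostWeights = None,
             salient_params: SalientParams = None,
             contour_params: ContourParams = None,
             t0n: Optional[RigidPose] = None,
             length_scale: float = 2.5,
             grid: TriangleGrid = None,
             light: LightingParams = None) -> RegistrationResult:
    """Full pipeline: actual contours -> coarse DE -> fine DE -> T_opt.

    ``views`` is a list of grayscale images in [0, 1]; the first is the
    reference frame, an optional second is the auxiliary frame whose
    inter-frame camera transform ``t0n`` must then be supplied. ``search``
    is the 6-DOF box (centre = start pose chart vector).
    """
    cfg = cfg or DEConfig()
    weights = weights or CostWeights()
    salient_params = salient_params or SalientParams()
    if len(features) == 0:
        raise ValueError("empty salient point set: enlarge V_p or lower theta_T")
    if not views:
        raise ValueError("at least one view is required")
    if grid is None:
        grid = TriangleGrid(mesh.vertices, mesh.faces)

    cparams = (contour_params or ContourParams()).scaled_for_image(views[0].shape)
    actual0 = attach_gradients(extract_actual_contours(views[0], cparams),
                               views[0])
    if len(actual0) == 0:
        raise EmptyContourError("no actual contours found in the reference view")
    actual_aux = None
    if len(views) > 1 and weights.w3 > 0:
        if t0n is None:
            raise ValueError("auxiliary view given but no inter-frame transform")
        actual_aux = extract_actual_contours(views[1], cparams)
        if len(actual_aux) == 0:
            actual_aux = None

    obj = ContourObjective(mesh, grid, features, intr, actual0, weights,
                           salient_params, cfg, length_scale,
                           actual_aux=actual_aux, t0n=t0n, light=light)

    x_coarse, shrunk, trace_c, nfev_c, conv_c = coarse_search(
        obj.coarse_value, search, cfg)

    # fine cascade: shrink the box around the running best pose and sharpen
    # the position-MI kernel level by level
    x = x_coarse
    trace = [("coarse", g, c) for g, c in trace_c]
    nfev = nfev_c
    conv_f = True
    for li, (shrink, ls_factor) in enumerate(cfg.fine_levels):
        half = search.half_widths * shrink
        lo = np.maximum(x - half, search.lower)
        hi = np.minimum(x + half, search.upper)
        box = SearchRange((lo + hi) / 2, (hi - lo) / 2)
        obj.length_scale = length_scale * ls_factor
        obj.prepare_fine(pose_decode(box.center))
        x, trace_l, nfev_l, conv_l = fine_search(obj.fine_value, box, cfg, x0=x)
        trace += [(f"fine{li + 1}", g, c) for g, c in trace_l]
        nfev += nfev_l
        conv_f = conv_f and conv_l
    x_fine = x
    nfev_f = nfev - nfev_c
    return RegistrationResult(
        pose_coarse=pose_decode(x_coarse),
        pose_fine=pose_decode(x_fine),
        cost_trace=trace,
        evaluations=nfev_c + nfev_f,
        converged=conv_c and conv_f,
        config={"de": asdict(cfg),
                "weights": asdict(weights),
                "salient": asdict(salient_params),
                "length_scale": length_scale},
    )
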