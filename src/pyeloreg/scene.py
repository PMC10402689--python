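"""Synthetic branched-cavity scenes: kidney-like phantoms for end-to-end tests.

The generator emulates a renal collecting system: an ellipsoidal central
chamber (the renal pelvis) merged with several capped tubular calyces.
Geometry is defined as a signed-distance union and meshed with marching
cubes, which guarantees a watertight genus-0 surface without boolean mesh
operations. Ten exterior marker points, ground-truth endoscope poses inside
the lumen, Phong-rendered views and exact inter-frame transforms complete a
scene, so the whole registration pipeline can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml
from skimage import measure

from .geometry import CameraIntrinsics, RigidPose, compose, vertex_normals
from .raycast import TriangleGrid


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid ``(x-c)^T diag(1/a^2) (x-c) <= 1`` (mm)."""

    center: tuple = (0.0, 0.0, 0.0)
    radii: tuple = (8.0, 7.0, 6.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        u = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return (u ** 2).sum(axis=1) <= 1.0

    def sample_inside(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, 3))
        got = 0
        while got < n:
            u = rng.uniform(-1, 1, size=(2 * (n - got) + 8, 3))
            u = u[(u ** 2).sum(axis=1) <= 1.0]
            take = min(len(u), n - got)
            out[got:got + take] = u[:take]
            got += take
        return out * np.asarray(self.radii) + np.asarray(self.center)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic branched cavity.

    Defaults give a mid-size renal pelvis; the two canned variants
    (:func:`k1_like_spec`, :func:`k2_like_spec`) mirror a complex two-level
    tree versus a simple single-level one.
    """

    pelvis_radius: float = 15.0
    n_calyces: int = 3
    calyx_radius_range: tuple = (4.0, 6.0)
    calyx_length_range: tuple = (12.0, 18.0)
    branch_angles: object = "random"   # list of (azimuth, elevation) deg, or "random"
    two_level: bool = False
    mesh_resolution: float = 1.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_calyces < 0:
            raise ValueError("n_calyces must be >= 0")
        if self.calyx_radius_range[1] >= self.pelvis_radius:
            raise ValueError("calyx radius must be smaller than the pelvis radius")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")


def k1_like_spec(seed: int = 0, mesh_resolution: float = 1.2) -> SceneSpec:
    """Complex variant: 6 terminal calyces from a two-level branch tree."""
    return SceneSpec(n_calyces=3, two_level=True, rng_seed=seed,
                     mesh_resolution=mesh_resolution,
                     branch_angles=[(0.0, 15.0), (120.0, -10.0), (240.0, 20.0)])


def k2_like_spec(seed: int = 0, mesh_resolution: float = 1.2) -> SceneSpec:
    """Simple variant: 3 single-level calyces."""
    return SceneSpec(n_calyces=3, two_level=False, rng_seed=seed,
                     mesh_resolution=mesh_resolution,
                     branch_angles=[(0.0, 10.0), (130.0, -15.0), (235.0, 25.0)])


def _dir_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def _capsule_sdf(points, a, b, radius):
    ab = b - a
    ap = points - a
    t = np.clip(ap @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1) - radius


def _ellipsoid_sdf(points, center, radii):
    # scaled-Euclidean approximation; adequate for iso-surfacing a union
    u = (points - center) / radii
    k = np.linalg.norm(u, axis=1)
    return (k - 1.0) * radii.min()


@dataclass
class _Branch:
    start: np.ndarray     # on/inside the chamber
    end: np.ndarray
    radius: float


def _build_branches(spec: SceneSpec, rng: np.random.Generator):
    chamber_radii = np.array([spec.pelvis_radius,
                              0.8 * spec.pelvis_radius,
                              0.68 * spec.pelvis_radius])
    if spec.branch_angles == "random":
        az = rng.uniform(0, 360, spec.n_calyces)
        # keep azimuths apart to avoid handles between tubes
        az = np.sort(az)
        el = rng.uniform(-25, 25, spec.n_calyces)
        angles = list(zip(az, el))
    else:
        angles = list(spec.branch_angles)[: spec.n_calyces]
    branches = []
    for azd, eld in angles:
        d = _dir_from_angles(azd, eld)
        r = rng.uniform(*spec.calyx_radius_range)
        length = rng.uniform(*spec.calyx_length_range)
        # support radius of the chamber along d
        surf = 1.0 / np.linalg.norm(d / chamber_radii)
        start = 0.5 * surf * d
        end = surf * d + length * d
        branches.append(_Branch(start, end, r))
        if spec.two_level:
            axis = d
            ortho = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(ortho) < 1e-6:
                ortho = np.cross(axis, [0.0, 1.0, 0.0])
            ortho /= np.linalg.norm(ortho)
            for sign in (+1.0, -1.0):
                child_dir = axis * np.cos(np.radians(30)) \
                    + sign * ortho * np.sin(np.radians(30))
                child_len = 0.7 * length
                child_r = 0.7 * r
                branches.append(_Branch(end - 2.0 * child_r * axis,
                                        end + child_len * child_dir, child_r))
    return chamber_radii, branches


def make_branched_cavity(spec: SceneSpec) -> trimesh.Trimesh:
    """Mesh the cavity (SDF union + marching cubes), lumen-facing winding.

    The returned mesh is watertight; face winding is chosen so the surface
    normals point *into* the lumen, where the endoscope lives.
    """
    rng = np.random.default_rng(spec.rng_seed)
    chamber_radii, branches = _build_branches(spec, rng)

    pts_max = chamber_radii.max()
    for b in branches:
        pts_max = max(pts_max, np.abs(b.start).max() + b.radius,
                      np.abs(b.end).max() + b.radius)
    pad = 3.0 * spec.mesh_resolution
    h = spec.mesh_resolution
    # offset the lattice so the isosurface never passes exactly through
    # grid nodes (exact zeros make marching cubes emit degenerate faces)
    lo = -(pts_max + pad) + 0.31 * h
    hi = pts_max + pad
    n = int(np.ceil((hi - lo) / h)) + 1
    axis = lo + h * np.arange(n)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    sdf = _ellipsoid_sdf(pts, np.zeros(3), chamber_radii)
    for b in branches:
        sdf = np.minimum(sdf, _capsule_sdf(pts, b.start, b.end, b.radius))
    vol = sdf.reshape(n, n, n)

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    # trimesh fixes winding outward; flip so normals face the lumen
    mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError(f"cavity meshing failed to close for spec {spec}")
    return mesh


def lumen_vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Area-weighted per-vertex normals (lumen-facing for scene meshes)."""
    return vertex_normals(mesh.vertices, mesh.faces)


def place_markers(mesh: trimesh.Trimesh, n: int = 10, seed: int = 0,
                  offset: float = 5.0) -> np.ndarray:
    """Evaluation targets: points on a +offset-mm inflated copy of the surface."""
    rng = np.random.default_rng(seed)
    areas = mesh.area_faces
    fidx = rng.choice(len(areas), size=n, p=areas / areas.sum())
    r1, r2 = rng.uniform(size=(2, n))
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    tri = mesh.triangles[fidx]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) \
        + r2[:, None] * (tri[:, 2] - tri[:, 0])
    vn = lumen_vertex_normals(mesh)
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    # lumen-facing winding => face normal points inward; outward = -fn
    return pts - offset * fn


@dataclass(frozen=True)
class SearchRange:
    """A 6-DOF box: center (rx,ry,rz deg, tx,ty,tz mm) +/- half-widths."""

    center: np.ndarray
    half_widths: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, float).reshape(6)
        w = np.asarray(self.half_widths, float).reshape(6)
        if np.any(w < 0):
            raise ValueError("half-widths must be non-negative")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "half_widths", w)

    @classmethod
    def around(cls, center6, rot_deg: float = 15.0, trans_mm: float = 10.0):
        return cls(np.asarray(center6, float),
                   np.array([rot_deg] * 3 + [trans_mm] * 3))

    @property
    def lower(self):
        return self.center - self.half_widths

    @property
    def upper(self):
        return self.center + self.half_widths


def look_at_pose(center: np.ndarray, target: np.ndarray,
                 roll_deg: float = 0.0) -> RigidPose:
    """Model->camera pose with optical center ``center`` looking at ``target``."""
    d = np.asarray(target, float) - np.asarray(center, float)
    d = d / np.linalg.norm(d)
    up = np.array([0.0, 0.0, 1.0])
    if abs(d @ up) > 0.98:
        up = np.array([0.0, 1.0, 0.0])
    r1 = np.cross(up, d)
    r1 /= np.linalg.norm(r1)
    r2 = np.cross(d, r1)
    rot = np.vstack([r1, r2, d])      # rows: camera x, y, z axes in model space
    c = np.radians(roll_deg)
    roll = np.array([[np.cos(c), -np.sin(c), 0.0],
                     [np.sin(c), np.cos(c), 0.0],
                     [0.0, 0.0, 1.0]])
    rot = roll @ rot
    return RigidPose.from_rt(rot, -rot @ np.asarray(center, float))


@dataclass
class PhantomScene:
    """A complete synthetic phantom: geometry, targets, truth, views."""

    mesh: trimesh.Trimesh
    markers: np.ndarray
    pelvis_volume: Ellipsoid
    gt_poses: list
    intrinsics: CameraIntrinsics
    spec: SceneSpec
    calyx_openings: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    rendered_views: list = field(default_factory=list)
    depth_maps: list = field(default_factory=list)
    relative_transforms: list = field(default_factory=list)
    _grid: TriangleGrid = None

    @property
    def grid(self) -> TriangleGrid:
        if self._grid is None:
            self._grid = TriangleGrid(self.mesh.vertices, self.mesh.faces)
        return self._grid


def _calyx_openings(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Chamber-exit points of the primary branches (junction centers)."""
    chamber_radii, branches = _build_branches(spec, rng)
    n_primary = spec.n_calyces
    pts = []
    for b in branches[: n_primary * (3 if spec.two_level else 1)]:
        d = b.end - b.start
        d /= np.linalg.norm(d)
        surf = 1.0 / np.linalg.norm(d / chamber_radii)
        pts.append(surf * d)
    return np.asarray(pts[:n_primary]) if n_primary else np.zeros((0, 3))


def sample_gt_poses(scene: PhantomScene, n_poses: int, seed: int = 0,
                    max_draws: int = 10_000) -> list:
    """Endoscope truth poses: centers in V_p aimed at calyx openings.

    Roll is uniform in [-180, 180); depth (distance to the aimed opening)
    varies through the uniform position sampling. Every pose must pass an
    inside-lumen parity test.
    """
    rng = np.random.default_rng(seed)
    openings = scene.calyx_openings
    if len(openings) == 0:
        openings = np.array([[0.0, 0.0, 0.0]])
    poses = []
    draws = 0
    while len(poses) < n_poses:
        if draws >= max_draws:
            raise RuntimeError("could not place poses inside the lumen")
        c = scene.pelvis_volume.sample_inside(1, rng)[0]
        draws += 1
        if not scene.grid.point_inside(c[None])[0]:
            continue
        k = rng.integers(len(openings))
        roll = rng.uniform(-180.0, 180.0)
        target = openings[k]
        if np.linalg.norm(target - c) < 2.0:
            continue
        poses.append(look_at_pose(c, target, roll))
    return poses


def perturb_pose(gt: RigidPose, search: SearchRange, seed: int = 0):
    """Offset a pose uniformly within the box, in the 6-vector chart.

    Returns ``(start_pose, offset6)``; zero half-widths reproduce ``gt``.
    """
    from .registration import pose_decode, pose_encode
    rng = np.random.default_rng(seed)
    offset = rng.uniform(-search.half_widths, search.half_widths)
    v = pose_encode(gt) + offset
    return pose_decode(v), offset


def make_scene(spec: SceneSpec, intrinsics: CameraIntrinsics = None,
               n_markers: int = 10, n_poses: int = 4,
               render: bool = True, light=None,
               min_contour_points: int = 8) -> PhantomScene:
    """Build a full phantom scene deterministically from ``spec.rng_seed``.

    When views are rendered, each candidate ground-truth pose is accepted
    only if its view yields at least ``min_contour_points`` actual-contour
    points — the synthetic analogue of a phantom protocol in which test
    positions are chosen to view structured regions of the collecting
    system (a coaxial down-the-tube view carries no contour information
    and would be useless as a test position).
    """
    from .render import LightingParams, render_view

    if intrinsics is None:
        intrinsics = CameraIntrinsics.from_fov(90.0, 200, 200)
    mesh = make_branched_cavity(spec)
    chamber_radii, _ = _build_branches(spec, np.random.default_rng(spec.rng_seed))
    vp = Ellipsoid(center=(0.0, 0.0, 0.0), radii=tuple(0.55 * chamber_radii))
    scene = PhantomScene(
        mesh=mesh,
        markers=place_markers(mesh, n_markers, seed=spec.rng_seed + 1),
        pelvis_volume=vp,
        gt_poses=[],
        intrinsics=intrinsics,
        spec=spec,
        calyx_openings=_calyx_openings(spec, np.random.default_rng(spec.rng_seed)),
    )
    if not render:
        scene.gt_poses = sample_gt_poses(scene, n_poses, seed=spec.rng_seed + 2)
        return scene

    from .contours import ContourParams, extract_actual_contours

    light = light or LightingParams()
    cparams = ContourParams().scaled_for_image((intrinsics.height,
                                                intrinsics.width))
    attempt = 0
    while len(scene.gt_poses) < n_poses:
        if attempt > 20 * n_poses:
            raise RuntimeError("could not find enough structured viewpoints")
        pose = sample_gt_poses(scene, 1, seed=spec.rng_seed + 2 + 101 * attempt)[0]
        attempt += 1
        img, depth = render_view(mesh, pose, intrinsics, light, grid=scene.grid)
        if len(extract_actual_contours(img, cparams)) < min_contour_points:
            continue
        scene.gt_poses.append(pose)
        scene.rendered_views.append(img)
        scene.depth_maps.append(depth)
    t0 = scene.gt_poses[0]
    from .geometry import invert
    scene.relative_transforms = [compose(p, invert(t0)) for p in scene.gt_poses]
    return scene


def save_scene(scene: PhantomScene, out_dir) -> None:
    """Write mesh.ply, markers.csv, poses/, views/ and a YAML manifest."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    (out / "poses").mkdir(parents=True, exist_ok=True)
    (out / "views").mkdir(exist_ok=True)
    scene.mesh.export(out / "mesh.ply", encoding="ascii")
    pd.DataFrame(scene.markers, columns=["x", "y", "z"]).to_csv(
        out / "markers.csv", index=False)
    for i, pose in enumerate(scene.gt_poses):
        pose.to_json(out / "poses" / f"pose_{i:03d}.json")
    for i, img in enumerate(scene.rendered_views):
        iio.imwrite(out / "views" / f"view_{i:03d}.png",
                    (np.clip(img, 0, 1) * 255).astype(np.uint8))
    manifest = {
        "schema": "pyeloreg-scene/1",
        "spec": {
            "pelvis_radius": float(scene.spec.pelvis_radius),
            "n_calyces": int(scene.spec.n_calyces),
            "two_level": bool(scene.spec.two_level),
            "mesh_resolution": float(scene.spec.mesh_resolution),
            "rng_seed": int(scene.spec.rng_seed),
        },
        "pelvis_volume": {
            "center": [float(x) for x in scene.pelvis_volume.center],
            "radii": [float(x) for x in scene.pelvis_volume.radii]},
        "intrinsics": {"fx": float(scene.intrinsics.fx),
                       "fy": float(scene.intrinsics.fy),
                       "cx": float(scene.intrinsics.cx),
                       "cy": float(scene.intrinsics.cy),
                       "width": int(scene.intrinsics.width),
                       "height": int(scene.intrinsics.height)},
        "n_views": len(scene.rendered_views),
    }
    (out / "scene.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_scene(scene_dir) -> PhantomScene:
    import imageio.v3 as iio
    import pandas as pd

    d = Path(scene_dir)
    manifest = yaml.safe_load((d / "scene.yaml").read_text())
    spec = SceneSpec(
        pelvis_radius=manifest["spec"]["pelvis_radius"],
        n_calyces=manifest["spec"]["n_calyces"],
        two_level=manifest["spec"]["two_level"],
        mesh_resolution=manifest["spec"]["mesh_resolution"],
        rng_seed=manifest["spec"]["rng_seed"],
    )
    mesh = trimesh.load(d / "mesh.ply", process=True)
    intr = CameraIntrinsics(**manifest["intrinsics"])
    poses = [RigidPose.from_json(p) for p in sorted((d / "poses").glob("*.json"))]
    views = [np.asarray(iio.imread(p), float) / 255.0
             for p in sorted((d / "views").glob("*.png"))]
    scene = PhantomScene(
        mesh=mesh,
        markers=pd.read_csv(d / "markers.csv")[["x", "y", "z"]].to_numpy(),
        pelvis_volume=Ellipsoid(tuple(manifest["pelvis_volume"]["center"]),
                                tuple(manifest["pelvis_volume"]["radii"])),
        gt_poses=poses,
        intrinsics=intr,
        spec=spec,
        calyx_openings=_calyx_openings(spec, np.random.default_rng(spec.rng_seed)),
        rendered_views=views,
    )
    if poses:
        from .geometry import invert
        scene.relative_transforms = [compose(p, invert(poses[0])) for p in poses]
    return scene
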