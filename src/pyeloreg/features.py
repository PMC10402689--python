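"""Salient 3D structural features of a cavity mesh.

A surface point is *salient* when some endoscope position inside the search
volume V_p (an ellipsoid in the renal pelvis) can view it tangentially:
its tangent plane must intersect V_p (perpendicularity is achievable) and a
sufficient number of seed positions on that intersection must see the point
without occlusion. On kidney-like cavities the surviving points concentrate
on the rims where calyces meet the pelvis.

At registration time, :func:`select_for_pose` keeps the subset of the
precomputed salient set that a specific camera pose views near-tangentially
(angle between the point normal and the viewing ray >= theta_T), unoccluded
and in frame; :func:`generate_contour` projects it to the image plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contours import Contour2D
from .geometry import CameraIntrinsics, RigidPose, project_points
from .raycast import TriangleGrid
from .scene import Ellipsoid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SalientParams:
    """Salient-point extraction and per-pose selection parameters.

    theta_T is the tangency threshold in degrees. On smooth, finely meshed
    surfaces values close to 90 give thin contours; on crease-dominated
    meshes the averaged vertex normal at a crease already sits ~45 degrees
    off both adjacent walls, so a grazing ray reads as theta ~ 45-65 rather
    than ~90 and the default is set accordingly. N_s is the strict minimum
    count of visible tangent-plane seeds; seed_spacing their grid pitch in
    mm. max_view_distance (mm) bounds the headlight's working range:
    structures beyond it are too dark to produce image contours, so they
    are excluded from per-pose selection.
    """

    theta_T: float = 60.0
    N_s: int = 5
    seed_spacing: float = 1.5
    max_view_distance: float = 20.0

    def __post_init__(self):
        if not 0 < self.theta_T <= 90:
            raise ValueError("theta_T must be in (0, 90] degrees")
        if self.N_s < 1:
            raise ValueError("N_s must be >= 1")
        if self.seed_spacing <= 0:
            raise ValueError("seed_spacing must be positive")
        if self.max_view_distance <= 0:
            raise ValueError("max_view_distance must be positive")


@dataclass
class SalientPointSet:
    points: np.ndarray           # (K, 3) model space, mm
    normals: np.ndarray          # (K, 3) unit
    source_vertex_ids: np.ndarray  # (K,) int

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls) -> "SalientPointSet":
        return cls(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, int))

    def subset(self, mask: np.ndarray) -> "SalientPointSet":
        return SalientPointSet(self.points[mask], self.normals[mask],
                               self.source_vertex_ids[mask])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
            "nx": self.normals[:, 0], "ny": self.normals[:, 1],
            "nz": self.normals[:, 2], "vertex_id": self.source_vertex_ids,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SalientPointSet":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(),
                   df[["nx", "ny", "nz"]].to_numpy(),
                   df["vertex_id"].to_numpy(int))


def tangent_plane_region(p, normal, vp: Ellipsoid):
    """Intersection of the tangent plane at ``p`` with the ellipsoid V_p.

    Returns ``(center, e1, e2, extent)`` — a point on the plane nearest the
    V_p center, an orthonormal in-plane basis and a world-space radius bound
    of the intersection — or ``None`` when the plane misses V_p. The miss
    test is exact: the plane misses iff the V_p-metric distance from the
    V_p center to the plane exceeds 1.
    """
    p = np.asarray(p, float)
    n = np.asarray(normal, float)
    c = np.asarray(vp.center, float)
    radii = np.asarray(vp.radii, float)
    # map to the unit-ball space u = (x - c)/radii; plane n.x = n.p becomes
    # (n*radii).u = n.(p - c)
    a = n * radii
    na = np.linalg.norm(a)
    if na < 1e-15:
        return None
    dist = (n @ (p - c)) / na      # signed distance in the V_p metric
    if abs(dist) > 1.0:
        return None
    # in-plane basis (world space)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    # world-space point on the plane closest to the Vp center
    center = c + (n @ (p - c)) / (n @ n) * n
    extent = float(radii.max())
    return center, e1, e2, extent


def _region_seeds(region, vp: Ellipsoid, spacing: float) -> np.ndarray:
    """Square-grid seeds of pitch ``spacing`` on the plane, clipped to V_p."""
    center, e1, e2, extent = region
    k = int(np.floor(extent / spacing))
    offs = spacing * np.arange(-k, k + 1)
    aa, bb = np.meshgrid(offs, offs)
    pts = center + aa.ravel()[:, None] * e1 + bb.ravel()[:, None] * e2
    inside = vp.contains(pts)
    pts = pts[inside]
    if len(pts) == 0:
        # degenerate region: fall back to its center if that lies in V_p
        if vp.contains(center[None])[0]:
            pts = center[None]
    return pts


def collision_filter(p, region, vp: Ellipsoid, grid: TriangleGrid,
                     params: SalientParams):
    """Visibility vote over grid seeds on the tangent-plane region.

    A seed is valid when the open segment seed->p meets no mesh triangle;
    the point is salient iff the valid count strictly exceeds ``N_s``.
    Returns ``(is_salient, n_valid_seeds)``.
    """
    seeds = _region_seeds(region, vp, params.seed_spacing)
    if len(seeds) == 0:
        return False, 0
    ends = np.broadcast_to(np.asarray(p, float), seeds.shape)
    blocked = grid.segments_blocked(seeds, ends)
    n_valid = int((~blocked).sum())
    return n_valid > params.N_s, n_valid


def extract_salient_points(mesh, vp: Ellipsoid,
                           params: SalientParams = None,
                           normals: np.ndarray = None,
                           grid: TriangleGrid = None) -> SalientPointSet:
    """Preoperative salient-point extraction over all mesh vertices (F_Vp)."""
    from .scene import lumen_vertex_normals

    params = params or SalientParams()
    verts = np.asarray(mesh.vertices, float)
    if normals is None:
        normals = lumen_vertex_normals(mesh)
    if grid is None:
        grid = TriangleGrid(mesh.vertices, mesh.faces)

    keep = []
    for i in range(len(verts)):
        region = tangent_plane_region(verts[i], normals[i], vp)
        if region is None:
            continue
        ok, _ = collision_filter(verts[i], region, vp, grid, params)
        if ok:
            keep.append(i)
    if not keep:
        log.warning("no salient points found; V_p may be too small or "
                    "N_s too strict")
        return SalientPointSet.empty()
    idx = np.asarray(keep, int)
    return SalientPointSet(verts[idx], normals[idx], idx)


def select_for_pose(f: SalientPointSet, pose: RigidPose,
                    intr: CameraIntrinsics, grid: TriangleGrid,
                    theta_T: float = 60.0,
                    max_view_distance: float = 20.0) -> SalientPointSet:
    """Per-pose selection: tangency (>= theta_T), visibility, in-frame,
    within the headlight working distance.

    The tangency angle is ``arccos(|g.w|)`` in [0, 90] degrees, with w the
    unit viewing ray from the optical center to the point — the absolute
    value makes the test insensitive to the surface-orientation sign.
    """
    if len(f) == 0:
        return SalientPointSet.empty()
    oc = pose.optical_center
    w = f.points - oc
    dist = np.linalg.norm(w, axis=1)
    valid = (dist > 1e-9) & (dist <= max_view_distance)
    w[dist > 1e-9] /= dist[dist > 1e-9, None]
    cosang = np.abs((f.normals * w).sum(axis=1))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    keep = valid & (theta >= theta_T)

    uv, in_front, in_frame = project_points(f.points, pose, intr)
    keep &= in_frame

    if np.any(keep):
        idx = np.flatnonzero(keep)
        starts = np.broadcast_to(oc, (len(idx), 3))
        blocked = grid.segments_blocked(starts, f.points[idx])
        keep[idx[blocked]] = False
    return f.subset(keep)


def generate_contour(p: SalientPointSet, pose: RigidPose,
                     intr: CameraIntrinsics) -> Contour2D:
    """Project a pose-filtered salient set to a generated contour."""
    if len(p) == 0:
        return Contour2D(np.zeros((0, 2)), source="generated")
    uv, _, in_frame = project_points(p.points, pose, intr)
    return Contour2D(uv[in_frame], source="generated")
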