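"""Virtual endoscopy: software ray-cast rendering with Phong shading.

The light source is co-located with the camera (headlight), the standard
situation for a single-scope endoscope. Output is a grayscale image in
[0, 1] plus a depth map in mm (+inf where no surface is hit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraIntrinsics, RigidPose, vertex_normals
from .raycast import TriangleGrid


@dataclass(frozen=True)
class LightingParams:
    """Phong coefficients; attenuation is 1/(c0 + c1 d + c2 d^2) with d in mm.

    ``gamma`` models the camera's display-gamma encoding (output =
    linear^(1/gamma)); it compresses bright-side shading ramps while
    preserving the contrast of shadowed recesses, as endoscope cameras do.
    Set gamma=1 for a linear response.
    """

    ambient: float = 0.06
    diffuse: float = 0.9
    specular: float = 0.25
    shininess: float = 24.0
    attenuation: tuple = (1.0, 0.0, 0.004)
    gamma: float = 2.2

    def __post_init__(self):
        for name in ("ambient", "diffuse", "specular"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.shininess <= 0:
            raise ValueError("shininess must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def camera_rays(pose: RigidPose, intr: CameraIntrinsics):
    """Model-space origin and per-pixel unit directions (H*W, 3)."""
    u = np.arange(intr.width) + 0.5
    v = np.arange(intr.height) + 0.5
    uu, vv = np.meshgrid(u, v)
    x = (uu - intr.cx) / intr.fx
    y = (vv - intr.cy) / intr.fy
    dirs_cam = np.stack([x, y, np.ones_like(x)], axis=-1).reshape(-1, 3)
    dirs_cam /= np.linalg.norm(dirs_cam, axis=1, keepdims=True)
    dirs_model = dirs_cam @ pose.rotation  # R^T applied row-wise
    origin = pose.optical_center
    return origin, dirs_model


def render_view(mesh, pose: RigidPose, intr: CameraIntrinsics,
                light: LightingParams = None, grid: TriangleGrid = None):
    """Render one view; returns ``(image in [0,1], depth map in mm)``.

    Shading per hit: ``ambient + att*(diffuse*max(0, n.l) +
    specular*max(0, r.v)^shininess)`` with the point light at the camera.
    Normals are barycentric-interpolated vertex normals, flipped toward the
    camera so the winding convention cannot darken interior walls.
    """
    light = light or LightingParams()
    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces, int)
    if len(faces) == 0:
        h, w = intr.height, intr.width
        return np.zeros((h, w)), np.full((h, w), np.inf)
    if grid is None:
        grid = TriangleGrid(verts, faces)
    vn = vertex_normals(verts, faces)

    origin, dirs = camera_rays(pose, intr)
    t, tri_idx, bary = grid.cast(np.broadcast_to(origin, dirs.shape), dirs)
    hit = tri_idx >= 0

    img = np.zeros(len(dirs))
    depth = np.full(len(dirs), np.inf)
    if np.any(hit):
        th = t[hit]
        fh = faces[tri_idx[hit]]
        u_b = bary[hit, 0]
        v_b = bary[hit, 1]
        w_b = 1.0 - u_b - v_b
        n = (w_b[:, None] * vn[fh[:, 0]] + u_b[:, None] * vn[fh[:, 1]]
             + v_b[:, None] * vn[fh[:, 2]])
        n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)
        d = dirs[hit]
        # flip normals to face the camera
        facing = (n * d).sum(axis=1)
        n[facing > 0] *= -1.0
        # headlight: l = v = -d
        ndotl = np.maximum(0.0, -(n * d).sum(axis=1))
        # r = 2(n.l)n - l with l = -d
        r = 2.0 * ndotl[:, None] * n + d
        rdotv = np.maximum(0.0, -(r * d).sum(axis=1))
        c0, c1, c2 = light.attenuation
        att = 1.0 / np.maximum(c0 + c1 * th + c2 * th ** 2, 1e-9)
        shade = light.ambient + att * (
            light.diffuse * ndotl + light.specular * rdotv ** light.shininess)
        img[hit] = shade
        depth[hit] = th
    img = np.clip(img, 0.0, 1.0)
    if light.gamma != 1.0:
        img = img ** (1.0 / light.gamma)
    return img.reshape(intr.height, intr.width), depth.reshape(intr.height, intr.width)


def silhouette_depth_edges(depth: np.ndarray, jump_threshold: float) -> np.ndarray:
    """Depth-discontinuity mask: pixels whose 8-neighbourhood depth range
    exceeds ``jump_threshold`` mm. Serves as an oracle for contour locations."""
    d = np.asarray(depth, float)
    finite = np.isfinite(d)
    big = np.nanmax(np.where(finite, d, np.nan)) if finite.any() else 0.0
    dd = np.where(finite, d, big + 10 * max(jump_threshold, 1.0))
    lo = dd.copy()
    hi = dd.copy()
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            shifted = np.roll(np.roll(dd, dy, axis=0), dx, axis=1)
            # roll wraps; mask the wrapped border afterwards
            lo = np.minimum(lo, shifted)
            hi = np.maximum(hi, shifted)
    mask = (hi - lo) > jump_threshold
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    return mask
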