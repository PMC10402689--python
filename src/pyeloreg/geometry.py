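"""Rigid transforms, pinhole camera, and ray/triangle primitives.

Conventions used throughout the package:

* right-handed coordinates, camera looks down +z;
* image origin top-left, u to the right, v down;
* a :class:`RigidPose` maps model-space points to camera-space points
  (``X_cam = T @ X_model``);
* all 3D lengths are millimetres, image coordinates are pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

_EPS_ORTHO = 1e-9
#: self-intersection guard for ray tests (mm)
RAY_EPS = 1e-6


@dataclass(frozen=True)
class RigidPose:
    """A 4x4 homogeneous rigid transform (rotation in SO(3), translation mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"pose matrix must be 4x4, got {m.shape}")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-7):
            raise ValueError("rotation block is not orthogonal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has negative determinant")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=_EPS_ORTHO):
            raise ValueError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(4))

    @classmethod
    def from_rt(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidPose":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def from_translation(cls, t) -> "RigidPose":
        return cls.from_rt(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_euler_deg(cls, angles_deg, translation) -> "RigidPose":
        """Intrinsic XYZ Euler angles in degrees plus a translation (mm)."""
        r = Rotation.from_euler("XYZ", np.asarray(angles_deg, float), degrees=True)
        return cls.from_rt(r.as_matrix(), np.asarray(translation, float))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def optical_center(self) -> np.ndarray:
        """Camera origin expressed in model coordinates (-R^T t)."""
        return -self.rotation.T @ self.translation

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform N x 3 model-space points into camera space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.matrix.tolist(), "units": "mm"}, indent=2)
        )

    @classmethod
    def from_json(cls, path) -> "RigidPose":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["matrix"], dtype=float))


def compose(a: RigidPose, b: RigidPose) -> RigidPose:
    """Composition ``a`` after ``b``: result maps x -> a(b(x))."""
    return RigidPose(a.matrix @ b.matrix)


def invert(p: RigidPose) -> RigidPose:
    r = p.rotation.T
    return RigidPose.from_rt(r, -r @ p.translation)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Ideal pinhole intrinsics (no radial distortion)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @classmethod
    def from_fov(cls, fov_x_deg: float, width: int, height: int) -> "CameraIntrinsics":
        f = (width / 2.0) / np.tan(np.radians(fov_x_deg) / 2.0)
        return cls(fx=f, fy=f, cx=width / 2.0, cy=height / 2.0,
                   width=width, height=height)

    def fov_x_deg(self) -> float:
        return float(np.degrees(2.0 * np.arctan((self.width / 2.0) / self.fx)))


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


def project_points(points: np.ndarray, pose: RigidPose, intr: CameraIntrinsics):
    """Project model-space points through the pinhole camera.

    Returns ``(uv, in_front, in_frame)``: pixel coordinates (NaN where the
    point is behind the camera), a depth-positivity flag and an in-image flag.
    """
    cam = pose.apply(points)
    z = cam[:, 2]
    in_front = z > 0
    uv = np.full((len(cam), 2), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        uv[in_front, 0] = intr.fx * cam[in_front, 0] / z[in_front] + intr.cx
        uv[in_front, 1] = intr.fy * cam[in_front, 1] / z[in_front] + intr.cy
    in_frame = (
        in_front
        & (uv[:, 0] >= 0) & (uv[:, 0] <= intr.width - 1)
        & (uv[:, 1] >= 0) & (uv[:, 1] <= intr.height - 1)
    )
    return uv, in_front, in_frame


def ray_triangle_intersect(ray: Ray, v0, v1, v2, max_t: float = np.inf):
    """Moller-Trumbore intersection; returns the hit distance t or ``None``.

    Hits are accepted for t in (RAY_EPS, max_t]; degenerate triangles
    (area < 1e-12) are skipped.
    """
    v0 = np.asarray(v0, float)
    e1 = np.asarray(v1, float) - v0
    e2 = np.asarray(v2, float) - v0
    if np.linalg.norm(np.cross(e1, e2)) < 2e-12:  # area < 1e-12
        return None
    pvec = np.cross(ray.direction, e2)
    det = float(e1 @ pvec)
    if abs(det) < 1e-14:
        return None
    inv_det = 1.0 / det
    tvec = ray.origin - v0
    u = float(tvec @ pvec) * inv_det
    if u < -1e-12 or u > 1.0 + 1e-12:
        return None
    qvec = np.cross(tvec, e1)
    v = float(ray.direction @ qvec) * inv_det
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return None
    t = float(e2 @ qvec) * inv_det
    if RAY_EPS < t <= max_t:
        return t
    return None


def segment_occluded(p, q, triangles: np.ndarray) -> bool:
    """True iff any triangle blocks the open segment from p to q.

    ``triangles`` is an (M, 3, 3) array. Intersections within RAY_EPS of
    either endpoint are ignored (q typically lies on the surface itself).
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    length = np.linalg.norm(d)
    if length == 0:
        raise ValueError("segment endpoints coincide")
    ray = Ray(p, d / length)
    for tri in np.asarray(triangles, float).reshape(-1, 3, 3):
        t = ray_triangle_intersect(ray, tri[0], tri[1], tri[2],
                                   max_t=length - 1e-9 * max(length, 1.0))
        if t is not None and t < length * (1.0 - 1e-9) - RAY_EPS:
            return True
    return False


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals consistent with the face winding.

    Isolated vertices get a zero normal.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )  # magnitude = 2 * area, so summing these is area weighting
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    nonzero = norms > 0
    vn[nonzero] /= norms[nonzero, None]
    return vn
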