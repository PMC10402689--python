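"""Shared fixtures: small synthetic scenes and meshes, built once per session."""

import numpy as np
import pytest
import trimesh

import pyeloreg as pr


@pytest.fixture(scope="session")
def k2_scene():
    """Simple 3-calyx fixture scene with rendered views."""
    return pr.make_scene(pr.k2_like_spec(seed=0, mesh_resolution=0.9), n_poses=4)


@pytest.fixture(scope="session")
def k1_scene():
    """Complex two-level fixture scene with rendered views."""
    return pr.make_scene(pr.k1_like_spec(seed=0, mesh_resolution=0.9), n_poses=4)


@pytest.fixture(scope="session")
def k2_features(k2_scene):
    return pr.extract_salient_points(k2_scene.mesh, k2_scene.pelvis_volume,
                                     grid=k2_scene.grid)


@pytest.fixture(scope="session")
def sphere_cavity():
    """Closed icosphere cavity (radius 10 mm), lumen-facing winding."""
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    mesh.invert()   # normals point inward, toward the lumen
    return mesh


@pytest.fixture(scope="session")
def sphere_grid(sphere_cavity):
    return pr.TriangleGrid(sphere_cavity.vertices, sphere_cavity.faces)


def random_pose(rng):
    from scipy.spatial.transform import Rotation
    r = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return pr.RigidPose.from_rt(r.as_matrix(), rng.uniform(-50, 50, 3))
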