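"""MI point-set cost tests against independent double-loop references."""

import math

import numpy as np
import pytest

from pyeloreg import (Contour2D, CostWeights, RigidPose, auxiliary_view_pose,
                      compose, fine_cost, gradient_cost, invert, position_cost)
from pyeloreg.similarity import EmptyContourError
from conftest import random_pose


def reference_position_cost(a_pts, g_pts, scale):
    """Naive double-loop implementation of the joint-probability MI."""
    n, m = len(a_pts), len(g_pts)
    d = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            d[i, j] = math.dist(a_pts[i], g_pts[j]) / scale
    w = np.exp(-(d - d.min()))
    p = w / w.sum()
    total = 0.0
    for i in range(n):
        for j in range(m):
            col = sum(p[k, j] for k in range(n))
            row = sum(p[i, l] for l in range(m))
            total += p[i, j] * math.log(p[i, j] / (col * row))
    return total


def reference_gradient_cost(a, g):
    n, m = len(a), len(g)
    w = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            mm = abs(a.grad_mag[i] - g.grad_mag[j])
            do = abs(a.grad_ori[i] - g.grad_ori[j])
            do = min(do, math.pi - do)
            w[i, j] = math.exp(-(mm + do / (math.pi / 2)))
    p = w / w.sum()
    total = 0.0
    for i in range(n):
        for j in range(m):
            total += p[i, j] * math.log(p[i, j] /
                                        (p[:, j].sum() * p[i, :].sum()))
    return total


class TestPositionCost:
    def test_single_pair_coincident(self):
        c = Contour2D([[5.0, 5.0]])
        assert position_cost(c, Contour2D([[5.0, 5.0]]), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_row_factorises(self):
        a = Contour2D([[0.0, 0.0]])
        g = Contour2D([[3.0, 4.0], [10.0, 2.0]])
        assert position_cost(a, g, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matched_far_pairs_reach_ln2(self):
        s = 1.0
        a = Contour2D([[0.0, 0.0], [10.0 * s, 0.0]])
        g = Contour2D([[0.0, 0.0], [10.0 * s, 0.0]])
        assert position_cost(a, g, s) == pytest.approx(math.log(2), abs=1e-3)

    def test_empty_raises(self):
        with pytest.raises(EmptyContourError):
            position_cost(Contour2D(np.zeros((0, 2))), Contour2D([[0, 0]]))

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n, m = rng.integers(1, 51, 2)
            a = rng.uniform(0, 160, (n, 2))
            g = rng.uniform(0, 160, (m, 2))
            scale = rng.uniform(1, 30)
            mine = position_cost(Contour2D(a), Contour2D(g), scale)
            ref = reference_position_cost(a, g, scale)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(19)
        a = Contour2D(rng.uniform(0, 100, (13, 2)))
        g = Contour2D(rng.uniform(0, 100, (7, 2)))
        assert position_cost(a, g, 5.0) == pytest.approx(
            position_cost(g, a, 5.0), abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(23)
        a = rng.uniform(0, 100, (9, 2))
        g = rng.uniform(0, 100, (11, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([13.0, -4.0])
        v0 = position_cost(Contour2D(a), Contour2D(g), 8.0)
        v1 = position_cost(Contour2D(a @ rot.T + shift),
                           Contour2D(g @ rot.T + shift), 8.0)
        assert v0 == pytest.approx(v1, abs=1e-9)

    def test_mi_upper_bound(self):
        rng = np.random.default_rng(29)
        for _ in range(500):
            n, m = rng.integers(1, 20, 2)
            a = Contour2D(rng.uniform(0, 50, (n, 2)))
            g = Contour2D(rng.uniform(0, 50, (m, 2)))
            v = position_cost(a, g, rng.uniform(0.5, 10))
            assert -1e-9 <= v <= math.log(min(n, m)) + 1e-9


try:
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(float, st.tuples(st.integers(1, 12), st.just(2)),
                 elements=st.floats(0, 100)),
        g=arrays(float, st.tuples(st.integers(1, 12), st.just(2)),
                 elements=st.floats(0, 100)),
        scale=st.floats(0.5, 20),
    )
    def test_position_cost_properties(a, g, scale):
        """MI is non-negative, bounded by ln(min(n, m)), and symmetric."""
        va = position_cost(Contour2D(a), Contour2D(g), scale)
        vb = position_cost(Contour2D(g), Contour2D(a), scale)
        assert -1e-9 <= va <= math.log(min(len(a), len(g))) + 1e-9
        assert va == pytest.approx(vb, abs=1e-12)
except ImportError:       # pragma: no cover - hypothesis is optional
    pass


class TestGradientCost:
    def _with_grads(self, pts, mags, oris):
        return Contour2D(pts, np.asarray(mags, float), np.asarray(oris, float))

    def test_uniform_attributes_factorise(self):
        a = self._with_grads([[0, 0], [1, 1], [2, 2]], [0.5] * 3, [0.3] * 3)
        g = self._with_grads([[5, 5], [6, 6]], [0.5] * 2, [0.3] * 2)
        assert gradient_cost(a, g) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_zero(self):
        a = self._with_grads([[0, 0]], [0.9], [1.0])
        g = self._with_grads([[3, 3]], [0.1], [0.2])
        assert gradient_cost(a, g) == pytest.approx(0.0, abs=1e-12)

    def test_missing_gradients_error(self):
        with pytest.raises(ValueError):
            gradient_cost(Contour2D([[0, 0]]), Contour2D([[1, 1]]))

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(31)
        for _ in range(500):
            n, m = rng.integers(1, 51, 2)
            a = self._with_grads(rng.uniform(0, 100, (n, 2)),
                                 rng.uniform(0, 1, n),
                                 rng.uniform(0, np.pi, n))
            g = self._with_grads(rng.uniform(0, 100, (m, 2)),
                                 rng.uniform(0, 1, m),
                                 rng.uniform(0, np.pi, m))
            assert gradient_cost(a, g) == pytest.approx(
                reference_gradient_cost(a, g), abs=1e-12)


class TestAuxViewPose:
    def test_identity_start_gives_t0n(self):
        rng = np.random.default_rng(37)
        t0n = random_pose(rng)
        tn = auxiliary_view_pose(RigidPose.identity(), t0n)
        assert np.allclose(tn.matrix, t0n.matrix)

    def test_roundtrip_reproduces_frame(self):
        """T0n built from two gt frames must map the candidate=truth case
        back onto frame n's exact pose."""
        rng = np.random.default_rng(41)
        t_gt0, t_gtn = random_pose(rng), random_pose(rng)
        t0n = compose(t_gtn, invert(t_gt0))
        tn = auxiliary_view_pose(t_gt0, t0n)
        assert np.allclose(tn.matrix, t_gtn.matrix, atol=1e-9)


class TestFineCost:
    def test_weight_degeneracy(self):
        rng = np.random.default_rng(43)
        a = Contour2D(rng.uniform(0, 100, (8, 2)))
        g = Contour2D(rng.uniform(0, 100, (6, 2)))
        bd = fine_cost(RigidPose.identity(), a, g, CostWeights(1, 0, 0), 5.0)
        assert bd.c_fine == pytest.approx(bd.c_pos)
        assert bd.c_fine == pytest.approx(position_cost(a, g, 5.0))

    def test_aux_only_equals_aux_position_cost(self):
        rng = np.random.default_rng(47)
        a = Contour2D(rng.uniform(0, 100, (8, 2)))
        g = Contour2D(rng.uniform(0, 100, (6, 2)))
        bd = fine_cost(RigidPose.identity(), a, g,
                       CostWeights(0, 0, 1), 5.0, actual_aux=a, generated_aux=g)
        assert bd.c_fine == pytest.approx(position_cost(a, g, 5.0))

    def test_breakdown_linearity(self):
        rng = np.random.default_rng(53)
        a = Contour2D(rng.uniform(0, 100, (8, 2)), rng.uniform(0, 1, 8),
                      rng.uniform(0, np.pi, 8))
        g = Contour2D(rng.uniform(0, 100, (6, 2)), rng.uniform(0, 1, 6),
                      rng.uniform(0, np.pi, 6))
        w = CostWeights(0.4, 0.2, 0.4)
        bd = fine_cost(RigidPose.identity(), a, g, w, 5.0,
                       actual_aux=a, generated_aux=g)
        assert bd.c_fine == pytest.approx(
            w.w1 * bd.c_pos + w.w2 * bd.c_grad + w.w3 * bd.c_pos_aux)

    def test_empty_generated_flagged_not_raised(self):
        a = Contour2D([[0.0, 0.0]])
        bd = fine_cost(RigidPose.identity(), a, Contour2D(np.zeros((0, 2))),
                       CostWeights(), 5.0)
        assert bd.degenerate and bd.c_fine == 0.0
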