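"""Scalar oracles and analytic properties of the composite objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmfnet.losses import (LossWeights, complementarity_loss, consistency_loss,
                           cross_entropy_loss, focal_loss, total_loss)

W = LossWeights()  # published defaults: lambda1=0.25, lambda2=0.5, alpha=0.25,
                   # gamma=2.0, tau=1.0


def val(t):
    return float(t.data)


class TestFocal:
    def test_reference_point(self):
        # -0.25 * (1-0.5)^2 * ln 0.5 = 0.25 * 0.25 * ln 2
        expected = 0.25 * 0.25 * math.log(2)
        assert val(focal_loss(np.array([0.5]), np.array([1.0]), W)) == \
            pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.043321, abs=1e-6)

    def test_confident_correct_prediction_vanishes(self):
        loss = val(focal_loss(np.array([1.0 - 1e-9]), np.array([1.0]), W))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_gamma_zero_reduces_to_weighted_cross_entropy(self):
        w = LossWeights(gamma=0.0, alpha=0.5)
        loss = val(focal_loss(np.array([0.5]), np.array([0.0]), w))
        assert loss == pytest.approx(0.5 * math.log(2), abs=1e-9)

    def test_strictly_decreasing_in_p_for_positive_label(self):
        ps = np.linspace(0.01, 0.99, 50)
        losses = [val(focal_loss(np.array([p]), np.array([1.0]), W)) for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([1.2]), np.array([1.0]), W)

    def test_batch_mean_reduction(self):
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 1.0])
        single = val(focal_loss(p[:1], y[:1], W))
        assert val(focal_loss(p, y, W)) == pytest.approx(single, abs=1e-12)


class TestComplementarity:
    def test_coincident_embeddings_pay_full_margin(self):
        z = np.random.default_rng(0).normal(size=(4, 8))
        assert val(complementarity_loss(z, z, W)) == pytest.approx(1.0, abs=1e-9)

    def test_beyond_margin_is_free(self):
        z1 = np.zeros((1, 4))
        z2 = np.array([[2.0, 0, 0, 0]])  # squared distance 4 >= tau
        assert val(complementarity_loss(z1, z2, W)) == 0.0

    def test_inside_margin_scalar_value(self):
        z1 = np.zeros((1, 5))
        z2 = np.zeros((1, 5))
        z2[0, 0] = 0.6  # squared distance 0.36 -> hinge 0.64
        assert val(complementarity_loss(z1, z2, W)) == pytest.approx(0.64, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            complementarity_loss(np.zeros((2, 3)), np.zeros((2, 4)), W)


class TestConsistency:
    def test_identical_embeddings_cost_nothing(self):
        z = np.random.default_rng(1).normal(size=(3, 6))
        assert val(consistency_loss(z, z, W)) == 0.0

    def test_scalar_squared_distance(self):
        z1 = np.zeros((1, 2))
        z2 = np.array([[0.6, 0.8]])
        assert val(consistency_loss(z1, z2, W)) == pytest.approx(1.0, abs=1e-9)

    def test_batch_mean(self):
        z1 = np.zeros((2, 1))
        z2 = np.array([[1.0], [math.sqrt(3.0)]])  # squared distances 1 and 3
        assert val(consistency_loss(z1, z2, W)) == pytest.approx(2.0, abs=1e-9)


class TestTotal:
    def test_weighted_sum_of_components(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, size=6)
        y = (rng.random(6) < 0.5).astype(float)
        zc = (rng.normal(size=(6, 4)), rng.normal(size=(6, 4)))
        zs = (rng.normal(size=(6, 4)), rng.normal(size=(6, 4)))
        loss, parts = total_loss(p, y, zc, zs, W)
        expected = (parts["classification"] + 0.25 * parts["complementarity"]
                    + 0.5 * parts["consistency"])
        assert float(loss.data) == pytest.approx(expected, rel=1e-12)

    def test_zero_lambdas_leave_focal_only(self):
        w = LossWeights(lambda1=0.0, lambda2=0.0)
        p = np.array([0.3, 0.8])
        y = np.array([0.0, 1.0])
        z = (np.ones((2, 3)), np.zeros((2, 3)))
        loss, _ = total_loss(p, y, z, z, w)
        assert float(loss.data) == pytest.approx(val(focal_loss(p, y, w)), rel=1e-12)

    def test_everything_at_its_minimum_gives_zero(self):
        p = np.array([1.0 - 1e-9, 1e-9])
        y = np.array([1.0, 0.0])
        far = (np.zeros((2, 2)), np.full((2, 2), 5.0))   # cpp beyond margin
        same = (np.ones((2, 2)), np.ones((2, 2)))        # csp coincident
        loss, _ = total_loss(p, y, far, same, W)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)


class TestMonotonicityAndGradients:
    def test_hinge_vs_proximity_monotonicity_on_distance_grid(self):
        dists = np.linspace(0.0, 3.0, 31)
        comp, cons = [], []
        for d in dists:
            z1 = np.zeros((1, 1))
            z2 = np.array([[math.sqrt(d)]])
            comp.append(val(complementarity_loss(z1, z2, W)))
            cons.append(val(consistency_loss(z1, z2, W)))
        assert all(a >= b - 1e-12 for a, b in zip(comp, comp[1:]))   # non-increasing
        assert all(a <= b + 1e-12 for a, b in zip(cons, cons[1:]))   # non-decreasing

    def test_gradients_push_apart_and_pull_together(self):
        from dmfnet.nn.autograd import Tensor
        z1 = Tensor(np.array([[0.3, 0.0]]), requires_grad=True)
        z2 = np.array([[0.0, 0.0]])
        complementarity_loss(z1, z2, W).backward()
        # moving z1 along -grad must increase the distance (below margin)
        step = z1.data - 0.01 * z1.grad
        assert np.linalg.norm(step - z2) > np.linalg.norm(z1.data - z2)
        z1 = Tensor(np.array([[0.3, 0.0]]), requires_grad=True)
        consistency_loss(z1, z2, W).backward()
        step = z1.data - 0.01 * z1.grad
        assert np.linalg.norm(step - z2) < np.linalg.norm(z1.data - z2)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_all_terms_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        p = rng.uniform(0, 1, size=n)
        y = (rng.random(n) < 0.5).astype(float)
        zc = (rng.normal(size=(n, 3)), rng.normal(size=(n, 3)))
        zs = (rng.normal(size=(n, 3)), rng.normal(size=(n, 3)))
        loss, parts = total_loss(p, y, zc, zs, W)
        assert float(loss.data) >= 0
        assert all(v >= 0 for v in parts.values())


def test_plain_distance_variant():
    w = LossWeights(distance="plain")
    z1 = np.zeros((1, 1))
    z2 = np.array([[0.36]])   # plain distance 0.36, squared would be 0.1296
    assert val(complementarity_loss(z1, z2, w)) == pytest.approx(0.64, abs=1e-6)


def test_cross_entropy_baseline():
    assert val(cross_entropy_loss(np.array([0.5]), np.array([0.0]))) == \
        pytest.approx(math.log(2), abs=1e-9)
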