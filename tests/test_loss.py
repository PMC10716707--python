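"""Asymmetric focal loss: closed-form values, cross-entropy reduction,
margin behavior, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxrfuse.loss import LossParams, asl_focal_loss, asl_focal_loss_grad

BCE_PARAMS = LossParams(gamma_pos=0, gamma_neg=0, margin=0.0)


def bce(p, y, eps=1e-7):
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1 - y) * np.log(1 - p))


class TestPointValues:
    def test_perfect_positive_vanishes(self):
        assert asl_focal_loss(np.array([1.0 - 1e-7]), np.array([1])) \
            == pytest.approx(0.0, abs=1e-6)

    def test_margin_absorbs_easy_negative(self):
        # p <= m shifts to p_m = 0: an easy negative contributes nothing.
        loss = asl_focal_loss(np.array([0.0005]), np.array([0]),
                              LossParams(margin=0.001))
        assert loss == 0.0

    def test_bce_spot_value(self):
        # y=1, p=0.5 under pure cross-entropy: -ln(1/2).
        assert asl_focal_loss(np.array([0.5]), np.array([1]), BCE_PARAMS) \
            == pytest.approx(0.693147, abs=1e-6)

    def test_asymmetric_spot_value(self):
        # y=1, p=0.5, gamma+=1: (1-p)^1 * (-ln p) = 0.5 * ln 2.
        loss = asl_focal_loss(np.array([0.5]), np.array([1]),
                              LossParams(gamma_pos=1, gamma_neg=5))
        assert loss == pytest.approx(0.346574, abs=1e-6)


class TestBceEquivalence:
    def test_grid_equivalence(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=100)
        y = rng.integers(0, 2, size=100)
        ours = asl_focal_loss(p, y, LossParams(gamma_pos=0, gamma_neg=0,
                                               margin=0.0, reduction="none"))
        np.testing.assert_allclose(ours, bce(p, y), atol=1e-10)

    def test_balancing_factor(self):
        p = np.array([0.3, 0.7])
        y = np.array([1, 0])
        prm = LossParams(gamma_pos=0, gamma_neg=0, margin=0.0, alpha=0.25,
                         reduction="none")
        expected = np.array([0.25 * -np.log(0.3), 0.75 * -np.log(0.3)])
        np.testing.assert_allclose(asl_focal_loss(p, y, prm), expected,
                                   atol=1e-10)


class TestShapeAndValidation:
    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            asl_focal_loss(np.zeros(3), np.zeros(4))

    def test_non_binary_targets_raise(self):
        with pytest.raises(ValueError, match="binary"):
            asl_focal_loss(np.full(3, 0.5), np.array([0, 1, 2]))

    def test_reduction_mean_over_batch_sum_over_labels(self):
        p = np.full((2, 14), 0.5)
        y = np.zeros((2, 14), dtype=int)
        per_elem = asl_focal_loss(p, y, LossParams(reduction="none"))
        mean = asl_focal_loss(p, y, LossParams(reduction="mean"))
        assert mean == pytest.approx(per_elem.sum(axis=1).mean())


class TestProperties:
    def test_nonnegative_and_monotone(self):
        prm = LossParams()
        grid = np.linspace(0.01, 0.99, 60)
        pos = [asl_focal_loss(np.array([p]), np.array([1]), prm) for p in grid]
        neg = [asl_focal_loss(np.array([p]), np.array([0]), prm) for p in grid]
        assert min(pos + neg) >= 0.0
        assert all(a >= b - 1e-12 for a, b in zip(pos, pos[1:]))  # decreasing
        above = grid > prm.margin + 0.02
        neg_above = np.array(neg)[above]
        assert all(a <= b + 1e-12 for a, b in zip(neg_above, neg_above[1:]))

    def test_asymmetry_downweights_easy_negatives(self):
        # With gamma- > gamma+, an easy negative costs less than under a
        # symmetric focal loss at the same probability.
        p, y = np.array([0.1]), np.array([0])
        asym = asl_focal_loss(p, y, LossParams(gamma_pos=1, gamma_neg=5, margin=0))
        sym = asl_focal_loss(p, y, LossParams(gamma_pos=1, gamma_neg=1, margin=0))
        assert asym < sym

    @pytest.mark.parametrize("p0", [1e-7, 0.001, 0.5, 1 - 1e-7])
    def test_gradient_finite_everywhere(self, p0):
        g = asl_focal_loss_grad(np.array([p0, p0]), np.array([1, 0]))
        assert np.isfinite(g).all()

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(4, 5))
        y = rng.integers(0, 2, size=(4, 5))
        prm = LossParams()
        g = asl_focal_loss_grad(p, y, prm)
        eps = 1e-7
        for idx in [(0, 0), (1, 3), (3, 4)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            fd = (asl_focal_loss(pp, y, prm) - asl_focal_loss(pm, y, prm)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(p=st.floats(1e-3, 1 - 1e-3), y=st.integers(0, 1),
       gp=st.floats(0, 6), gn=st.floats(0, 6), m=st.floats(0, 0.5))
def test_loss_nonnegative_and_continuous_everywhere(p, y, gp, gn, m):
    prm = LossParams(gamma_pos=gp, gamma_neg=gn, margin=m)
    val = asl_focal_loss(np.array([p]), np.array([y]), prm)
    assert np.isfinite(val) and val >= 0.0
    # continuity probe: a tiny probability shift moves the loss by no
    # more than the local slope allows (|dL/dp| <= ~1/min(p, 1-p) here)
    eps = 1e-9
    nearby = asl_focal_loss(np.array([p + eps]), np.array([y]), prm)
    assert abs(nearby - val) <= 100 * eps / min(p, 1 - p)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(tp=st.integers(0, 50), tn=st.integers(0, 50),
       fp=st.integers(0, 50), fn=st.integers(0, 50),
       k=st.integers(2, 9))
def test_metric_scale_invariance_property(tp, tn, fp, fn, k):
    from cxrfuse.metrics import ConfusionCounts, metrics_from_counts

    if tp + tn + fp + fn == 0:
        return
    a = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    b = metrics_from_counts(ConfusionCounts(k * tp, k * tn, k * fp, k * fn))
    for name in ("accuracy", "precision", "recall", "specificity", "f1",
                 "balanced_accuracy"):
        va, vb = getattr(a, name), getattr(b, name)
        assert (np.isnan(va) and np.isnan(vb)) or va == pytest.approx(vb)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        LossParams(gamma_neg=-1)
    with pytest.raises(ValueError):
        LossParams(margin=1.0)
    with pytest.raises(ValueError):
        LossParams(alpha=1.5)
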