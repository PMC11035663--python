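"""Loss terms against explicit term-by-term oracles and gradient checks."""

import numpy as np
import pytest

from vesseltopo import losses, topo
from vesseltopo.autodiff import Tensor


def fd_gradient(f, x0, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x0.copy(), x0.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestSmoothL1:
    @pytest.mark.parametrize(
        "z,beta,expected",
        [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5), (2.0, 1.0, 1.5), (-2.0, 1.0, 1.5), (0.5, 2.0, 0.0625)],
    )
    def test_values(self, z, beta, expected):
        assert losses.smooth_l1(z, beta) == pytest.approx(expected)

    def test_continuity_at_beta(self):
        beta = 0.7
        below = losses.smooth_l1(beta - 1e-9, beta)
        above = losses.smooth_l1(beta + 1e-9, beta)
        assert below == pytest.approx(above, abs=1e-6)
        assert below == pytest.approx(0.5 * beta, abs=1e-6)

    def test_large_negative_residual_is_linear(self):
        # |z| handling: a huge negative residual must cost, not reward
        assert losses.smooth_l1(-100.0, 1.0) == pytest.approx(99.5)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            losses.smooth_l1(1.0, 0.0)


class TestTheta1:
    def setup_method(self):
        self.L = np.zeros((4, 6, 6))
        self.L[1:3, 1:5, 1:5] = 1
        self.D = topo.distance_transform(self.L.astype(np.uint8)).data

    def test_perfect_prediction_zero(self):
        assert losses.theta1(self.D, self.D, self.L) == pytest.approx(0.0)

    def test_constant_beta_error(self):
        cfg = losses.LossConfig(beta=1.0, reduction="sum")
        pred = self.D + 1.0  # error exactly beta on every vessel voxel
        k = int(self.L.sum())
        # background prediction errors must not contribute
        pred_bg = pred.copy()
        pred_bg[self.L == 0] = 99.0
        assert losses.theta1(self.D, pred_bg, self.L, cfg) == pytest.approx(0.5 * k)

    def test_matches_loop_oracle(self, rng):
        cfg = losses.LossConfig(beta=0.8, reduction="sum")
        pred = self.D + rng.normal(0, 2.0, size=self.D.shape)
        expected = 0.0
        for v in np.argwhere(self.L > 0):
            z = self.D[tuple(v)] - pred[tuple(v)]
            expected += 0.5 * z**2 / 0.8 if abs(z) < 0.8 else abs(z) - 0.4
        assert losses.theta1(self.D, pred, self.L, cfg) == pytest.approx(expected)

    def test_mean_reduction(self, rng):
        pred = self.D + 1.0
        cfg_sum = losses.LossConfig(reduction="sum")
        cfg_mean = losses.LossConfig(reduction="mean")
        k = int(self.L.sum())
        assert losses.theta1(self.D, pred, self.L, cfg_mean) == pytest.approx(
            losses.theta1(self.D, pred, self.L, cfg_sum) / k
        )

    def test_empty_vessel_set_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            out = losses.theta1(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
        assert out == 0.0


class TestTheta2:
    def test_perfect_skeleton_and_mask_zero(self):
        L = np.zeros((5, 7, 7))
        L[2, 2:5, 1:6] = 1
        phi = topo.skeletonize(L.astype(np.uint8)).data.astype(float)
        assert losses.theta2(L, L, phi) == pytest.approx(0.0, abs=1e-6)

    def test_empty_predictions_near_one(self):
        L = np.zeros((5, 7, 7))
        L[2, 2:5, 1:6] = 1
        z = np.zeros_like(L)
        assert losses.theta2(L, z, z) == pytest.approx(1.0, abs=1e-4)

    def test_matches_term_by_term_oracle(self, rng):
        L = (rng.random((5, 8, 8)) < 0.3).astype(np.uint8)
        lp = rng.random((5, 8, 8))
        j2 = rng.random((5, 8, 8))
        cfg = losses.LossConfig()
        phi = topo.skeletonize(L).data.astype(float)
        delta = topo.dilate(L, 1).data.astype(float)
        # soft dilation oracle: 3x3x3 running maximum of the probability map
        from scipy import ndimage

        soft = ndimage.maximum_filter(lp, size=3, mode="constant", cval=0.0)
        eps = cfg.epsilon
        expected = 1 - ((j2 * delta).sum() + (soft * phi).sum() + eps) / (
            j2.sum() + phi.sum() + eps
        )
        assert losses.theta2(L, lp, j2, cfg) == pytest.approx(expected, rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        L = (rng.random((3, 5, 5)) < 0.4).astype(np.uint8)
        lp0 = rng.random((3, 5, 5))
        j20 = rng.random((3, 5, 5))
        cfg = losses.LossConfig()

        lp = Tensor(lp0.copy(), requires_grad=True)
        out = losses.theta2(L, lp, j20, cfg)
        out.backward()
        num = fd_gradient(lambda a: losses.theta2(L, a, j20, cfg), lp0)
        np.testing.assert_allclose(lp.grad, num, atol=1e-3)


class TestTheta3:
    def test_perfect_binary_prediction(self):
        L = np.zeros((4, 4, 4))
        L[1:3, 1:3, 1:3] = 1
        assert losses.theta3(L, L) == pytest.approx(0.0, abs=1e-6)

    def test_all_background_prediction(self):
        L = np.zeros((4, 4, 4))
        L[0, 0, 0] = 1
        assert losses.theta3(L, np.zeros_like(L)) == pytest.approx(1.0, abs=1e-4)

    def test_half_confidence_value(self):
        L = np.zeros((4, 4, 4))
        L[0, 0, :4] = 1  # 4 voxels
        pred = L * 0.5
        # 1 - (2*2 + eps) / (4 + 2 + eps)
        assert losses.theta3(L, pred) == pytest.approx(1 / 3, abs=1e-6)

    def test_monotone_along_interpolation(self, rng):
        L = (rng.random((4, 6, 6)) < 0.3).astype(float)
        wrong = 1.0 - L
        values = [
            losses.theta3(L, (1 - t) * wrong + t * L) for t in np.linspace(0, 1, 11)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        L = (rng.random((3, 4, 4)) < 0.4).astype(float)
        x0 = rng.random((3, 4, 4))
        x = Tensor(x0.copy(), requires_grad=True)
        losses.theta3(L, x).backward()
        num = fd_gradient(lambda a: losses.theta3(L, a), x0)
        np.testing.assert_allclose(x.grad, num, atol=1e-3)


class TestDecorrelation:
    def test_identical_one_hot_full_correlation(self):
        p = np.array([1.0, 0.0, 0.0])
        d = np.array([1.0, 0.0, 0.0])
        assert losses.decorrelation_loss(prediction=p, true_label=d) == pytest.approx(1.0)

    def test_uniform_prediction_guarded_zero(self):
        p = np.full(4, 0.25)
        d = np.array([0.0, 1.0, 0.0, 0.0])
        assert losses.decorrelation_loss(prediction=p, true_label=d) == 0.0

    def test_hand_computed_pearson_value(self):
        p = np.array([0.7, 0.2, 0.1])
        d = np.array([1.0, 0.0, 0.0])
        assert losses.decorrelation_loss(prediction=p, true_label=d) == pytest.approx(
            0.988, abs=5e-4
        )

    def test_printed_denominator_variant_differs(self):
        p = np.array([0.7, 0.2, 0.1])
        d = np.array([1.0, 0.0, 0.0])
        cfg = losses.LossConfig(dcl_form="printed")
        pm = p - p.mean()
        dm = d - d.mean()
        expected = (pm * dm).sum() / np.sqrt((pm**2 * dm**2).sum())
        got = losses.decorrelation_loss(prediction=p, true_label=d, cfg=cfg)
        assert got == pytest.approx(expected)
        assert got != pytest.approx(0.988, abs=5e-4)

    def test_needs_two_domains(self):
        with pytest.raises(ValueError):
            losses.decorrelation_loss(prediction=np.array([1.0]), true_label=np.array([1.0]))

    def test_anticorrelated_prediction_negative(self):
        p = np.array([0.0, 0.5, 0.5])
        d = np.array([1.0, 0.0, 0.0])
        assert losses.decorrelation_loss(prediction=p, true_label=d) < -0.9

    def test_gradient_matches_finite_differences(self, rng):
        d = np.array([0.0, 1.0, 0.0])
        p0 = np.array([0.3, 0.5, 0.2])
        p = Tensor(p0.copy(), requires_grad=True)
        losses.decorrelation_loss(prediction=p, true_label=d).backward()
        num = fd_gradient(
            lambda a: losses.decorrelation_loss(prediction=a, true_label=d), p0
        )
        np.testing.assert_allclose(p.grad, num, atol=1e-4)


class TestTotalLoss:
    def _toy(self, rng):
        L = (rng.random((4, 6, 6)) < 0.3).astype(float)
        D = topo.distance_transform(L.astype(np.uint8)).data
        lp = rng.random((4, 6, 6))
        j1 = rng.random((4, 6, 6))
        j2 = rng.random((4, 6, 6))
        dp = np.array([0.5, 0.3, 0.2])
        onehot = np.array([1.0, 0.0, 0.0])
        return L, D, lp, j1, j2, dp, onehot

    def test_only_theta3_when_other_weights_zero(self, rng):
        L, D, lp, j1, j2, dp, onehot = self._toy(rng)
        cfg = losses.LossConfig(weight_theta1=0, weight_theta2=0, weight_dcl=0)
        total, terms = losses.total_loss(
            L, lp, J1_pred=j1, J2_pred=j2, D_true=D, domain_pred=dp,
            domain_onehot=onehot, cfg=cfg,
        )
        assert total == pytest.approx(losses.theta3(L, lp, cfg))
        assert terms["theta1"] == terms["theta2"] == terms["dcl"] == 0.0

    def test_equals_weighted_sum_of_terms(self, rng):
        L, D, lp, j1, j2, dp, onehot = self._toy(rng)
        cfg = losses.LossConfig(reduction="mean")
        total, terms = losses.total_loss(
            L, lp, J1_pred=j1, J2_pred=j2, D_true=D, domain_pred=dp,
            domain_onehot=onehot, cfg=cfg,
        )
        dcl = losses.decorrelation_loss(prediction=dp, true_label=onehot, cfg=cfg)
        expected = (
            losses.theta3(L, lp, cfg)
            + cfg.weight_theta1 * losses.theta1(D, j1, L, cfg)
            + cfg.weight_theta2 * losses.theta2(L, lp, j2, cfg)
            + cfg.weight_dcl * dcl**2  # the decorrelation penalty enters squared
        )
        assert total == pytest.approx(expected, rel=1e-6)

    def test_perfect_predictions_near_zero(self):
        L = np.zeros((4, 6, 6))
        L[1:3, 1:5, 1:5] = 1
        D = topo.distance_transform(L.astype(np.uint8)).data
        phi = topo.skeletonize(L.astype(np.uint8)).data.astype(float)
        uniform = np.full(3, 1 / 3)
        total, terms = losses.total_loss(
            L, L, J1_pred=D, J2_pred=phi, D_true=D,
            domain_pred=uniform, domain_onehot=np.array([1.0, 0.0, 0.0]),
            cfg=losses.LossConfig(reduction="mean"),
        )
        assert total == pytest.approx(0.0, abs=1e-4)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            losses.LossConfig(weight_theta1=-1.0)
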