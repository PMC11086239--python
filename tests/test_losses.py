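"""Cycle / adversarial / identity losses: fixed points and hand oracles."""

import numpy as np
import pytest
from scipy.signal import welch as scipy_welch
from scipy.stats import pearsonr

from fecgx.autodiff import tensor
from fecgx.losses import (LossReport, LossWeights, adversarial_loss, cycle_loss,
                          identity_loss, pearson, total_loss, welch_psd)

identity_fn = lambda x: x if hasattr(x, "data") else tensor(x)


class ConstantD:
    """Discriminator stub returning a fixed probability on 16 patches."""

    def __init__(self, p):
        self.p = p

    def __call__(self, x):
        b = x.shape[0] if hasattr(x, "shape") else len(x)
        return tensor(np.full((b, 16), self.p))


class TableD:
    """Stub returning one preset probability per sample."""

    def __init__(self, values):
        self.values = list(values)

    def __call__(self, x):
        b = x.shape[0]
        vals = [self.values.pop(0) for _ in range(b)]
        return tensor(np.array(vals)[:, None] * np.ones((1, 16)))


class TestCycleLoss:
    def test_identity_generators_give_zero(self, rng):
        x = rng.normal(size=(4, 64))
        y = rng.normal(size=(4, 64))
        assert cycle_loss(identity_fn, identity_fn, x, y).item() == 0.0

    def test_hand_computed_value(self):
        # forward: G2(G1(x)) = [1,1] vs x=[1,2] -> mean |diff| = 0.5
        # backward: exact reconstruction -> 0; total 0.5
        G1 = lambda t: t
        G2 = lambda t: tensor(np.array([[1.0, 1.0]])) if t.shape[1] == 2 else t
        x = np.array([[1.0, 2.0]])
        y = np.array([[0.0]])
        # y passes through G2 (shape 1) then G1 unchanged
        assert cycle_loss(G1, G2, x, y).item() == pytest.approx(0.5)

    def test_scaling_doubles_loss_on_zero_centered_data(self, rng):
        x = rng.normal(size=(8, 32))
        y = rng.normal(size=(8, 32))
        l1 = cycle_loss(lambda t: t * 2.0, identity_fn, x, np.zeros_like(y)).item()
        l2 = cycle_loss(lambda t: t * 3.0, identity_fn, x, np.zeros_like(y)).item()
        # |G2(G1(x)) - x| = |k*x - x| scales linearly in (k-1)
        assert l2 == pytest.approx(2.0 * l1, rel=1e-12)


class TestAdversarialLoss:
    def test_indifferent_discriminator_analytic_constant(self, rng):
        d_loss, g_loss = adversarial_loss(ConstantD(0.5), rng.normal(size=(3, 8)),
                                          rng.normal(size=(3, 8)))
        assert d_loss.item() == pytest.approx(-2.0 * np.log(0.5), abs=1e-12)
        assert g_loss.item() == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_perfect_discriminator_approaches_zero(self, rng):
        class PerfectD:
            def __init__(self):
                self.calls = 0

            def __call__(self, x):
                self.calls += 1
                p = 1.0 if self.calls == 1 else 0.0  # real first, fake second
                b = x.shape[0]
                return tensor(np.full((b, 16), p))

        d_loss, _ = adversarial_loss(PerfectD(), rng.normal(size=(2, 8)),
                                     rng.normal(size=(2, 8)))
        assert 0.0 <= d_loss.item() < 1e-5

    def test_hand_built_batch_log_sum_oracle(self):
        d = TableD([0.9, 0.8, 0.3, 0.1])
        d_loss, g_loss = adversarial_loss(d, np.zeros((2, 4)), np.zeros((2, 4)))
        expected_d = -(np.mean([np.log(0.9), np.log(0.8)])
                       + np.mean([np.log(0.7), np.log(0.9)]))
        assert d_loss.item() == pytest.approx(expected_d, abs=1e-12)
        assert g_loss.item() == pytest.approx(-np.mean([np.log(0.3), np.log(0.1)]))

    def test_batch_order_invariance(self, rng):
        real = rng.normal(size=(4, 16))
        fake = rng.normal(size=(4, 16))

        class NormD:
            def __call__(self, x):
                p = 1.0 / (1.0 + np.exp(-np.asarray(x.data).mean(axis=1)))
                return tensor(p[:, None] * np.ones((1, 16)))

        d1, _ = adversarial_loss(NormD(), real, fake)
        d2, _ = adversarial_loss(NormD(), real[::-1], fake[::-1])
        assert d1.item() == pytest.approx(d2.item(), rel=1e-12)


class TestIdentityLoss:
    def test_fixed_point_is_zero(self, rng):
        x = rng.normal(size=(3, 512))
        total, parts = identity_loss(identity_fn, x, x.copy())
        assert total.item() == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) < 1e-9 for v in parts.values())

    def test_sign_flip_makes_correlation_term_eight(self, rng):
        x = rng.normal(size=(5, 512))
        total, parts = identity_loss(lambda t: t * -1.0, x, x.copy())
        # rho(x, -x) = -1 -> (4/N) * N * (1 - (-1)) = 8; PSD and power unchanged
        assert parts["correlation"] == pytest.approx(8.0, abs=1e-9)
        assert parts["spectral"] == pytest.approx(0.0, abs=1e-9)
        assert parts["power"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_stepwise_scipy_evaluation(self, rng):
        x = rng.normal(size=(2, 1024))
        y = rng.normal(size=(2, 1024))
        gain = 1.3
        total, parts = identity_loss(lambda t: t * gain, x, y)
        # independent evaluation with scipy building blocks
        _, px = scipy_welch(x, fs=1.0, nperseg=256, detrend="constant")
        _, py = scipy_welch(y, fs=1.0, nperseg=256, detrend="constant")
        pg = px * gain ** 2
        t1 = np.mean([(1 - pearsonr(py[i], pg[i]).statistic)
                      * pearsonr(py[i], px[i]).statistic for i in range(2)]) * 2
        t2 = np.mean([1 - pearsonr(y[i], gain * x[i]).statistic for i in range(2)]) * 4
        p_in = (x ** 2).mean(axis=1)
        t3 = np.mean(np.abs(p_in - p_in * gain ** 2) / p_in)
        assert parts["spectral"] == pytest.approx(t1, abs=1e-6)
        assert parts["correlation"] == pytest.approx(t2, abs=1e-9)
        assert parts["power"] == pytest.approx(t3, abs=1e-9)
        assert total.item() == pytest.approx(t1 + t2 + t3, abs=1e-6)

    def test_zero_power_segment_rejected(self, rng):
        x = np.vstack([np.zeros(256), rng.normal(size=256)])
        with pytest.raises(ValueError, match="segment 0"):
            identity_loss(lambda t: t + 1.0, x, rng.normal(size=(2, 256)))

    def test_terms_nonnegative_on_random_batches(self, rng):
        for _ in range(5):
            x = rng.normal(size=(3, 512))
            y = rng.normal(size=(3, 512))
            _, parts = identity_loss(lambda t: t * 0.5 + 0.1, x, y)
            assert parts["correlation"] >= 0.0
            assert parts["power"] >= 0.0


class TestTotalLoss:
    def test_zero_weights_leave_adversarial_only(self):
        rep = LossReport(l_cycle=0.5, l_gan_fwd=1.0, l_gan_bwd=2.0,
                         l_identity_g1=3.0, l_identity_g2=4.0)
        assert total_loss(rep, LossWeights(0.0, 0.0)) == 3.0

    def test_lambda_scales_cycle(self):
        rep = LossReport(l_cycle=0.5, l_gan_fwd=0.0, l_gan_bwd=0.0,
                         l_identity_g1=0.0, l_identity_g2=0.0)
        assert total_loss(rep, LossWeights(10.0, 0.0)) == 5.0

    def test_matches_hand_weighted_sum(self, rng):
        vals = rng.uniform(0.1, 2.0, size=5)
        rep = LossReport(*vals)
        w = LossWeights(3.0, 7.0)
        expected = vals[1] + vals[2] + 3.0 * vals[0] + 7.0 * (vals[3] + vals[4])
        assert total_loss(rep, w) == pytest.approx(expected, rel=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0)


class TestHelpers:
    def test_pearson_matches_scipy(self, rng):
        x = rng.normal(size=300)
        y = x * 0.5 + rng.normal(size=300)
        assert pearson(x, y) == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson(np.ones(10), np.arange(10.0))

    def test_welch_proportional_to_scipy(self, rng):
        x = rng.normal(size=(1, 1024))
        _, ps = scipy_welch(x[0], fs=1.0, nperseg=256, detrend="constant")
        ours = welch_psd(x).data[0]
        ratio = ours / ps
        assert ratio.std() / ratio.mean() < 1e-9
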