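"""Loss components against hand evaluations and scalar oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tripletlstm as tl
from tripletlstm.losses import LOG_EPS, ClassWeights


def _weights_from_freq(freq):
    freq = np.asarray(freq, dtype=float)
    med = float(np.median(freq))
    return ClassWeights(weights=med / freq, frequencies=freq, median_frequency=med)


class TestClassWeights:
    def test_hand_evaluation(self):
        # frequencies (0.5, 0.3, 0.2) -> weights (0.6, 1.0, 1.5)
        labels = [0] * 50 + [1] * 30 + [2] * 20
        cw = tl.class_weights(labels, 3)
        np.testing.assert_allclose(cw.weights, [0.6, 1.0, 1.5], rtol=1e-12)

    def test_balanced_classes_give_unit_weights(self):
        labels = np.repeat(np.arange(5), 8)
        cw = tl.class_weights(labels, 5)
        np.testing.assert_array_equal(cw.weights, np.ones(5))

    def test_rarest_class_gets_largest_weight(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 100, size=7)
            labels = np.repeat(np.arange(7), counts)
            cw = tl.class_weights(labels, 7)
            assert np.argmax(cw.weights) == np.argmin(counts)
            # sorting oracle: weight order is reversed frequency order
            assert list(np.argsort(cw.weights)) == list(np.argsort(-counts, kind="stable"))

    def test_weight_frequency_product_is_median(self, rng):
        for _ in range(25):
            counts = rng.integers(1, 200, size=int(rng.integers(2, 12)))
            n = len(counts)
            labels = np.repeat(np.arange(n), counts)
            cw = tl.class_weights(labels, n)
            np.testing.assert_allclose(
                cw.weights * cw.frequencies, cw.median_frequency, rtol=1e-12
            )

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            tl.class_weights([0, 0, 1], 3)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        w = _weights_from_freq([0.5, 0.5])
        assert tl.weighted_cross_entropy([1.0, 0.0], [1, 0], w) == 0.0

    def test_hand_evaluation_ln2(self):
        w = _weights_from_freq([0.5, 0.5])
        loss = tl.weighted_cross_entropy([0.5, 0.5], [0, 1], w)
        assert loss == pytest.approx(math.log(2.0), abs=1e-12)

    def test_linear_in_weight(self):
        w1 = ClassWeights(weights=[1.0, 2.0], frequencies=[0.5, 0.5],
                          median_frequency=0.5)
        w2 = ClassWeights(weights=[2.0, 4.0], frequencies=[0.5, 0.5],
                          median_frequency=0.5)
        p = [0.3, 0.7]
        assert tl.weighted_cross_entropy(p, [0, 1], w2) == pytest.approx(
            2 * tl.weighted_cross_entropy(p, [0, 1], w1)
        )

    def test_log_clamped_at_epsilon(self):
        w = _weights_from_freq([0.5, 0.5])
        loss = tl.weighted_cross_entropy([1.0, 0.0], [0, 1], w)
        assert loss == pytest.approx(-math.log(LOG_EPS))

    def test_not_one_hot_rejected(self):
        w = _weights_from_freq([0.5, 0.5])
        with pytest.raises(ValueError, match="one-hot"):
            tl.weighted_cross_entropy([0.5, 0.5], [1, 1], w)


class TestTripletLoss:
    def test_inactive_hinge(self):
        e = np.array([0.0, 0.0])
        far = np.array([5.0, 0.0])
        assert tl.triplet_loss(e, e, far, m=1.0) == 0.0

    def test_hand_evaluation(self):
        # D(a,p)=1, D(a,n)=0.5, m=1 -> 1.5
        a = np.array([0.0, 0.0])
        p = np.array([1.0, 0.0])
        n = np.array([0.5, 0.0])
        assert tl.triplet_loss(a, p, n, m=1.0) == pytest.approx(1.5)

    def test_zero_margin_identical_pn(self, rng):
        a = rng.normal(size=4)
        pn = rng.normal(size=4)
        assert tl.triplet_loss(a, pn, pn, m=0.0) == 0.0

    def test_batch_mean(self, rng):
        a, p, n = (rng.normal(size=(10, 6)) for _ in range(3))
        per = [tl.triplet_loss(a[i], p[i], n[i], m=1.0) for i in range(10)]
        assert tl.triplet_loss(a, p, n, m=1.0) == pytest.approx(np.mean(per))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 5.0))
    def test_translation_invariance_and_nonnegativity(self, seed, m):
        r = np.random.default_rng(seed)
        a, p, n = (r.normal(size=5) for _ in range(3))
        shift = r.normal(size=5)
        base = tl.triplet_loss(a, p, n, m=m)
        assert base >= 0.0
        assert tl.triplet_loss(a + shift, p + shift, n + shift, m=m) == pytest.approx(
            base, abs=1e-9
        )


class TestTotalLoss:
    def _random_inputs(self, rng, n=4):
        def probs():
            v = rng.random(n) + 1e-3
            return v / v.sum()

        def onehot():
            y = np.zeros(n)
            y[rng.integers(0, n)] = 1
            return y

        freq = rng.random(n) + 0.1
        w = _weights_from_freq(freq / freq.sum())
        e = [rng.normal(size=6) for _ in range(3)]
        return (probs(), probs(), probs()), (onehot(), onehot(), onehot()), e, w

    def test_lambda_zero_reduces_to_cross_entropies(self, rng):
        (pp, pa, pn), ys, (ep, ea, en), w = self._random_inputs(rng)
        cfg = tl.LossConfig(margin=1.0, lam=0.0)
        expected = sum(
            tl.weighted_cross_entropy(p, y, w) for p, y in zip((pp, pa, pn), ys)
        )
        got = tl.total_loss(pp, pa, pn, ys, ep, ea, en, w, cfg)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_perfect_inputs_zero_total(self):
        w = _weights_from_freq([0.5, 0.5])
        onehots = (np.array([1.0, 0.0]),) * 3
        e_same = np.zeros(3)
        e_far = np.array([10.0, 0.0, 0.0])
        got = tl.total_loss(
            onehots[0], onehots[1], onehots[2],
            onehots, e_same, e_same, e_far, w, tl.LossConfig()
        )
        assert got == 0.0

    def test_monotone_in_lambda(self, rng):
        (pp, pa, pn), ys, (ep, ea, en), w = self._random_inputs(rng)
        en = ea + 1e-3 * rng.normal(size=6)  # hinge active
        vals = [
            tl.total_loss(pp, pa, pn, ys, ep, ea, en, w, tl.LossConfig(lam=lam))
            for lam in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_scalar_oracle_on_random_inputs(self, rng):
        """Independent pure-python re-evaluation of the combined objective."""
        for _ in range(50):
            (pp, pa, pn), ys, (ep, ea, en), w = self._random_inputs(rng)
            cfg = tl.LossConfig(margin=float(rng.random() * 2), lam=float(rng.random() * 2))
            got = tl.total_loss(pp, pa, pn, ys, ep, ea, en, w, cfg)

            def ce(p, y):
                c = int(np.argmax(y))
                return -w.weights[c] * math.log(max(p[c], 1e-12))

            d_ap = math.sqrt(sum((x - z) ** 2 for x, z in zip(ea, ep)))
            d_an = math.sqrt(sum((x - z) ** 2 for x, z in zip(ea, en)))
            oracle = (
                ce(pp, ys[0]) + ce(pa, ys[1]) + ce(pn, ys[2])
                + cfg.lam * max(0.0, d_ap - d_an + cfg.margin)
            )
            assert got == pytest.approx(oracle, abs=1e-9)
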