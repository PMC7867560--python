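"""Network architectures, training dynamics, and calcification scoring."""

import numpy as np
import pytest

from calcnet import (CalcMask, CalcnetError, CTStack, build_network,
                     score_calcification, train)
from calcnet.cnn import TrainConfig, network_spec
from calcnet.cnn.layers import softmax_cross_entropy
from calcnet.cnn.scoring import label_from_score
from calcnet.patches import TrainingSet


def _toy_training_set(n_per_class=40, p=13, seed=0, separable=True,
                      n_calcs=8):
    """Two constant-intensity classes (0.25 vs 0.75) with mild noise;
    trivially separable by any conv/fc stack."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = np.empty((n, 3, p, p), dtype=np.float32)
    y = np.empty(n, dtype=np.int8)
    ids = np.empty(n, dtype=object)
    for i in range(n):
        cls = i % 2
        level = 0.75 if (cls == 1 and separable) else 0.25
        if not separable:
            level = 0.5
        X[i] = level + rng.normal(0, 0.02, size=(3, p, p))
        y[i] = cls
        ids[i] = f"calc{(i // 2) % n_calcs}_{cls}"
    centers = np.zeros((n, 3), dtype=int)
    counts = {}
    for s in ids:
        counts[s] = counts.get(s, 0) + 1
    return TrainingSet(X.clip(0, 1), y, ids, centers, counts, False, p,
                       (-100.0, 1500.0))


class TestBuildNetwork:
    def test_candidate_c_has_two_conv_layers(self):
        spec = network_spec("C")
        assert spec.n_conv_layers == 2
        assert network_spec("A").n_conv_layers == 1
        assert network_spec("B").n_conv_layers == 1

    def test_seeded_init_is_reproducible(self):
        a = build_network("C", 31, seed=5)
        b = build_network("C", 31, seed=5)
        assert a.checksum() == b.checksum()
        c = build_network("C", 31, seed=6)
        assert a.checksum() != c.checksum()

    def test_softmax_outputs_sum_to_one(self):
        net = build_network("B", 21, seed=0)
        X = np.random.default_rng(0).normal(size=(5, 3, 21, 21))
        probs = net.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_unknown_candidate_rejected(self):
        with pytest.raises(CalcnetError):
            build_network("D", 31, seed=0)

    def test_undersized_patch_rejected(self):
        with pytest.raises(CalcnetError):
            build_network("C", 9, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        net = build_network("A", 15, seed=3)
        X = np.random.default_rng(1).normal(size=(4, 3, 15, 15))
        before = net.predict_proba(X)
        net.save(tmp_path / "model")
        from calcnet.cnn import Network
        loaded, meta = Network.load(tmp_path / "model")
        assert meta["candidate"] == "A"
        assert np.allclose(loaded.predict_proba(X), before)


class TestLayerNumerics:
    def test_conv_matches_scipy_correlate(self):
        """The im2col convolution must agree with an independent direct
        correlation for every output channel."""
        from scipy.signal import correlate
        rng = np.random.default_rng(7)
        net = build_network("A", 15, seed=2)
        conv = net.layers[0]
        x = rng.normal(size=(2, 3, 15, 15)).astype(np.float32)
        out = conv.forward(x)
        W = conv.W.reshape(3, 3, 3, 16)  # (cin, kh, kw, cout)
        for n in (0, 1):
            for f in (0, 7, 15):
                ref = sum(correlate(x[n, c], W[c, :, :, f], mode="valid")
                          for c in range(3)) + conv.b[f]
                assert np.allclose(out[n, f], ref, atol=1e-4)

    def test_backward_matches_directional_derivative(self):
        """Analytic gradient vs finite differences along a random direction."""
        rng = np.random.default_rng(3)
        net = build_network("C", 13, seed=1)
        X = rng.normal(size=(8, 3, 13, 13)).astype(np.float32)
        y = rng.integers(0, 2, 8)
        logits = net.forward(X)
        _, d = softmax_cross_entropy(logits, y)
        net.backward(d)
        grads = [g.copy() for g in net.grads]
        eps = 1e-3
        for p, g in zip(net.params, grads):
            v = rng.normal(size=g.shape).astype(np.float32)
            v /= np.linalg.norm(v)
            analytic = float((g * v).sum())
            p += eps * v
            l1, _ = softmax_cross_entropy(net.forward(X), y)
            p -= 2 * eps * v
            l2, _ = softmax_cross_entropy(net.forward(X), y)
            p += eps * v  # restore
            numeric = (l1 - l2) / (2 * eps)
            assert abs(numeric - analytic) <= 0.05 * abs(numeric) + 2e-4


class TestTrain:
    def test_separable_toy_reaches_perfect_accuracy(self):
        ts = _toy_training_set()
        net = build_network("C", 13, seed=0)
        log = train(net, ts, TrainConfig(epochs=20, batch_size=16, seed=0,
                                         val_fraction=0.0))
        # inference-mode accuracy on the training set (the in-epoch figure
        # is computed with dropout active and sits a little lower)
        probs = net.predict_proba(ts.X)
        assert float((probs.argmax(axis=1) == ts.y).mean()) == 1.0
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_single_class_rejected(self):
        ts = _toy_training_set(n_per_class=10)
        ts.y[:] = 1
        net = build_network("C", 13, seed=0)
        with pytest.raises(CalcnetError):
            train(net, ts, TrainConfig(epochs=1))

    def test_training_is_reproducible(self):
        ts = _toy_training_set(n_per_class=12)
        a = build_network("A", 13, seed=4)
        b = build_network("A", 13, seed=4)
        cfg = TrainConfig(epochs=3, batch_size=16, seed=9)
        log_a = train(a, ts, cfg)
        log_b = train(b, ts, cfg)
        assert a.checksum() == b.checksum()
        assert log_a.equals(log_b)

    def test_invalid_config_rejected(self):
        with pytest.raises(CalcnetError):
            TrainConfig(val_fraction=0.8)
        with pytest.raises(CalcnetError):
            TrainConfig(optimizer="sgd")


class _ConstantModel:
    """Stub classifier emitting a fixed stone probability for every voxel."""

    def __init__(self, p_stone, patch_size=9):
        self.p = np.atleast_1d(np.asarray(p_stone, dtype=float))
        self.spec = type("S", (), {"patch_size": patch_size})()

    def predict_proba(self, X, batch_size=1024):
        p = np.resize(self.p, len(X))
        return np.stack([1 - p, p], axis=1)


def _stack_and_mask(n_voxels, value=400.0):
    shape = (20, 20, 20)
    stack = CTStack(np.full(shape, value, dtype=np.float32), id="s")
    m = np.zeros(shape, dtype=bool)
    m.reshape(-1)[4000:4000 + n_voxels] = True
    return stack, CalcMask(m, "s")


class TestScoring:
    def test_constant_probability_model(self):
        stack, mask = _stack_and_mask(12)
        cs = score_calcification(_ConstantModel(0.8), stack, mask)
        assert np.isclose(cs.score, 0.8)
        assert cs.predicted_label == "stone"
        assert cs.n_voxels == 12

    def test_mean_of_two_voxels(self):
        stack, mask = _stack_and_mask(2)
        cs = score_calcification(_ConstantModel([0.2, 0.4]), stack, mask)
        assert np.isclose(cs.score, 0.3)
        assert cs.predicted_label == "phlebolith"

    def test_tie_at_cutoff_is_called_stone(self):
        assert label_from_score(0.5, cutoff=0.5) == "stone"
        assert label_from_score(0.4999999, cutoff=0.5) == "phlebolith"

    def test_score_is_mean_of_per_voxel_probs(self):
        stack, mask = _stack_and_mask(20)
        cs = score_calcification(_ConstantModel(np.linspace(0, 1, 20)),
                                 stack, mask)
        assert abs(cs.score - float(cs.per_voxel_probs.mean())) < 1e-9

    def test_matches_brute_force_voxel_loop(self, stone_stack, stone_mask):
        """Aggregated score equals the mean of independent single-voxel
        forward passes (brute-force oracle)."""
        from calcnet.cnn import STONE_INDEX
        from calcnet.patches import extract_triplet
        net = build_network("C", 15, seed=0)
        cs = score_calcification(net, stone_stack, stone_mask, patch_size=15)
        probs = []
        for c in stone_mask.voxel_indices():
            x = extract_triplet(stone_stack, tuple(c), 15).stacked()[None]
            probs.append(float(net.predict_proba(x)[0, STONE_INDEX]))
        assert np.isclose(cs.score, np.mean(probs), atol=1e-6)

    def test_cutoff_monotonicity(self):
        stack, mask = _stack_and_mask(5)
        labels = []
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            cs = score_calcification(_ConstantModel(0.55), stack, mask,
                                     cutoff=cutoff)
            labels.append(cs.predicted_label)
        # once the rising cutoff passes the score, stone flips to phlebolith
        # and never back
        flips = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert labels[0] == "stone" and labels[-1] == "phlebolith"
        assert len(flips) == 1
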