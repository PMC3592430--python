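"""Tests for z-normalization, the logistic function and the GLM filter."""

import numpy as np
import pytest
from scipy.special import logit

from ssrscan import GlmFilter, Interval, LabeledDetection, apply_filter, logistic, train_glm


def _paper_norm_filter(threshold=0.5):
    """Filter carrying published human-trained normalization constants."""
    return GlmFilter(
        mu=(25.537, 5.7773),
        sigma=(35.802, 0.23168),
        weights=(1.0, 1.0),
        bias=0.0,
        threshold=threshold,
    )


class TestZScore:
    def test_mean_maps_to_zero(self):
        filt = _paper_norm_filter()
        z1, z2 = filt.zscore(25.537, 5.7773)
        assert z1 == pytest.approx(0.0)
        assert z2 == pytest.approx(0.0)

    def test_one_sd_above_mean_maps_to_one(self):
        filt = _paper_norm_filter()
        z1, z2 = filt.zscore(25.537 + 35.802, 5.7773 + 0.23168)
        assert (z1, z2) == pytest.approx((1.0, 1.0))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            GlmFilter(mu=(0, 0), sigma=(0.0, 1.0), weights=(1, 1), bias=0.0)


class TestLogistic:
    def test_symmetry_point_and_limits(self):
        assert logistic(0.0) == 0.5
        assert logistic(1000.0) == pytest.approx(1.0)
        assert logistic(-1000.0) == pytest.approx(0.0)

    def test_complement_identity(self, rng):
        v = rng.normal(scale=5, size=100)
        assert np.allclose(logistic(v) + logistic(-v), 1.0)

    def test_monotone(self, rng):
        v = np.sort(rng.normal(size=50))
        assert np.all(np.diff(logistic(v)) >= 0)


class TestTrainGlm:
    def test_separable_clusters_reach_full_training_accuracy(self, rng):
        pos = [LabeledDetection(float(l), float(s), 1)
               for l, s in zip(rng.normal(80, 10, 200), rng.normal(5.8, 0.1, 200))]
        neg = [LabeledDetection(float(l), float(s), -1)
               for l, s in zip(rng.normal(10, 2, 200), rng.normal(4.0, 0.2, 200))]
        filt = train_glm(pos + neg)
        correct = sum(
            (filt.probability(d.length, d.average_score) >= 0.5) == (d.label == 1)
            for d in pos + neg
        )
        assert correct == 400

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        lengths = rng.normal(40, 20, 1000).clip(1)
        scores = rng.normal(5, 0.5, 1000)
        labels = rng.choice([1, -1], size=1000)
        data = [LabeledDetection(float(l), float(s), int(y))
                for l, s, y in zip(lengths, scores, labels)]
        filt = train_glm(data)
        correct = np.mean([
            (filt.probability(d.length, d.average_score) >= 0.5) == (d.label == 1)
            for d in data
        ])
        assert 0.4 < correct < 0.62

    def test_recovers_generating_weights(self, rng):
        n = 100_000
        true_w, true_b = (2.0, -1.2), 0.4
        z = rng.normal(size=(n, 2))
        x = np.column_stack([40 + 25 * z[:, 0], 5.5 + 0.3 * z[:, 1]])
        p = 1 / (1 + np.exp(-(true_w[0] * z[:, 0] + true_w[1] * z[:, 1] + true_b)))
        y = np.where(rng.random(n) < p, 1, -1)
        data = [LabeledDetection(float(a.clip(1)), float(b), int(c))
                for (a, b), c in zip(x, y)]
        filt = train_glm(data)
        assert filt.weights[0] == pytest.approx(true_w[0], rel=0.05)
        assert filt.weights[1] == pytest.approx(true_w[1], rel=0.05)
        assert filt.bias == pytest.approx(true_b, abs=0.05)

    def test_matches_independent_logistic_fit(self, rng):
        from sklearn.linear_model import LogisticRegression

        lengths = rng.gamma(4, 10, 500).clip(1)
        scores = rng.normal(5.2, 0.4, 500)
        labels = np.where(lengths + 20 * (scores - 5.2) + rng.normal(0, 15, 500) > 40, 1, -1)
        if labels.min() == labels.max():  # pragma: no cover - guard, not expected
            pytest.skip("degenerate draw")
        data = [LabeledDetection(float(l), float(s), int(y))
                for l, s, y in zip(lengths, scores, labels)]
        filt = train_glm(data)
        z = np.column_stack([
            (lengths - filt.mu[0]) / filt.sigma[0],
            (scores - filt.mu[1]) / filt.sigma[1],
        ])
        ref = LogisticRegression(C=1e6, tol=1e-10, max_iter=10_000).fit(z, labels == 1)
        assert filt.weights == pytest.approx(tuple(ref.coef_[0]), rel=1e-3, abs=1e-3)
        assert filt.bias == pytest.approx(float(ref.intercept_[0]), rel=1e-3, abs=1e-3)

    def test_single_class_rejected(self):
        data = [LabeledDetection(10 + i, 5.0, 1) for i in range(20)]
        with pytest.raises(ValueError, match="both classes"):
            train_glm(data)

    def test_small_classes_warn(self, rng):
        data = [LabeledDetection(80 + i, 5.8, 1) for i in range(12)]
        data += [LabeledDetection(5 + i, 4.0, -1) for i in range(5)]
        with pytest.warns(UserWarning, match="few GLM training examples"):
            train_glm(data)


class TestApplyFilter:
    def _detections(self, rng, n=50):
        out = []
        for k in range(n):
            length = float(rng.integers(2, 120))
            avg = float(rng.uniform(3.0, 6.0))
            out.append((Interval("chr", k * 200, k * 200 + int(length)), length, avg))
        return out

    def test_boundary_case_is_kept(self):
        filt = GlmFilter(mu=(10, 5), sigma=(1, 1), weights=(1.0, 0.0), bias=0.0)
        kept = apply_filter([(Interval("c", 0, 10), 10.0, 5.0)], filt)  # v = 0 -> p = 0.5
        assert len(kept) == 1
        assert kept[0].score == pytest.approx(0.5)

    def test_raising_threshold_shrinks_kept_set(self, rng):
        filt = GlmFilter(mu=(30, 5), sigma=(20, 0.5), weights=(2.0, 1.0), bias=-0.5)
        dets = self._detections(rng)
        kept_05 = {(iv.start, iv.end) for iv in apply_filter(dets, filt, threshold=0.5)}
        kept_99 = {(iv.start, iv.end) for iv in apply_filter(dets, filt, threshold=0.99)}
        assert kept_99 <= kept_05

    def test_decision_is_half_plane(self, rng):
        # Keeping a detection depends only on the sign of the linear score
        # shifted by logit(theta): the boundary is a line in feature space.
        filt = GlmFilter(mu=(30, 5), sigma=(20, 0.5), weights=(2.0, 1.0), bias=-0.5,
                         threshold=0.8)
        dets = self._detections(rng)
        kept = {(iv.start, iv.end) for iv in apply_filter(dets, filt)}
        for iv, length, avg in dets:
            in_half_plane = filt.decision_value(length, avg) - logit(0.8) >= 0
            assert ((iv.start, iv.end) in kept) == bool(in_half_plane)

    def test_empty_input(self):
        filt = GlmFilter(mu=(10, 5), sigma=(1, 1), weights=(1, 1), bias=0.0)
        assert apply_filter([], filt) == []
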