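"""Logistic (GLM) filter over HMM detections.

An HMM detection is summarized by two features: its length in bp and its
average score.  Long, high-scoring detections are real microsatellites;
short, low-scoring ones resemble what the HMM finds in shuffled sequence.
The filter z-scores both features with means and standard deviations taken
from the training pool, applies a fitted linear combination, and keeps a
detection when the logistic value reaches the decision threshold
(default 0.5; 0.99 is the strict preset for AT-rich genomes where shuffled
sequence is itself repetitive).

Fitting is plain maximum-likelihood logistic regression by iteratively
reweighted least squares with a mild L2 ridge (1e-6) so the Newton steps
stay defined even on linearly separable data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .core import Interval


def logistic(v: float | np.ndarray) -> float | np.ndarray:
    """Numerically safe logistic function 1 / (1 + exp(-v))."""
    out = expit(v)
    return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out


@dataclass(frozen=True)
class LabeledDetection:
    """A (length, average score) pair labeled +1 (true MS) or -1 (spurious)."""

    length: float
    average_score: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValueError("label must be +1 or -1")
        if self.length < 1:
            raise ValueError("detection length must be >= 1 bp")


@dataclass
class GlmFilter:
    """Trained logistic filter: z-normalization constants, weights and threshold."""

    mu: tuple[float, float]  # (length mean, average-score mean)
    sigma: tuple[float, float]
    weights: tuple[float, float]  # (w_length, w_average_score) on z-scores
    bias: float
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise ValueError("feature standard deviations must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def zscore(self, length: float, average_score: float) -> tuple[float, float]:
        return (
            (length - self.mu[0]) / self.sigma[0],
            (average_score - self.mu[1]) / self.sigma[1],
        )

    def decision_value(self, length, average_score):
        z1 = (np.asarray(length, dtype=float) - self.mu[0]) / self.sigma[0]
        z2 = (np.asarray(average_score, dtype=float) - self.mu[1]) / self.sigma[1]
        return self.weights[0] * z1 + self.weights[1] * z2 + self.bias

    def probability(self, length, average_score):
        """Logistic value of a detection with the given features."""
        return logistic(self.decision_value(length, average_score))


def train_glm(
    data: Iterable[LabeledDetection],
    threshold: float = 0.5,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFilter:
    """Fit the logistic filter on labeled detections.

    Means and SDs are computed from the whole (positive + negative)
    training pool.  Convergence: max absolute parameter change < ``tol``
    or ``max_iter`` Newton iterations.
    """
    rows = list(data)
    x = np.array([[d.length, d.average_score] for d in rows], dtype=float)
    y = np.array([1.0 if d.label == 1 else 0.0 for d in rows])
    if len(rows) == 0 or y.min() == y.max():
        raise ValueError("GLM training needs examples from both classes")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 10:
        warnings.warn(
            f"few GLM training examples (positives={n_pos}, negatives={n_neg}); "
            "the fitted filter may be unstable",
            stacklevel=2,
        )
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    if sigma.min() <= 0:
        raise ValueError("a feature is constant across the training pool")
    z = (x - mu) / sigma
    design = np.column_stack([np.ones(len(z)), z])
    beta = np.zeros(3)
    for _ in range(max_iter):
        p = expit(design @ beta)
        w = p * (1.0 - p)
        grad = design.T @ (y - p) - ridge * beta
        hess = (design * w[:, None]).T @ design + ridge * np.eye(3)
        step = np.linalg.solve(hess, grad)
        if not np.all(np.isfinite(step)):
            break
        beta += step
        if np.abs(step).max() < tol:
            break
    return GlmFilter(
        mu=(float(mu[0]), float(mu[1])),
        sigma=(float(sigma[0]), float(sigma[1])),
        weights=(float(beta[1]), float(beta[2])),
        bias=float(beta[0]),
        threshold=threshold,
    )


def apply_filter(
    detections: Sequence[tuple[Interval, float, float]],
    filt: GlmFilter,
    threshold: float | None = None,
) -> list[Interval]:
    """Keep detections whose logistic value reaches the threshold.

    ``detections`` pairs each interval with its (length, average score)
    features.  Kept intervals carry their logistic value as ``score``.
    A boundary case exactly at the threshold is kept (>=).
    """
    theta = filt.threshold if threshold is None else threshold
    kept: list[Interval] = []
    for interval, length, average_score in detections:
        p = float(filt.probability(length, average_score))
        if p >= theta:
            kept.append(replace(interval, score=p))
    return kept
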