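"""Fuzzy distance-based fusion of base-classifier probabilities.

The fusion layer maps the vector of M base-classifier confidences for a
sample into a multi-metric distance geometry against two ideal reference
vectors — the all-ones "prototypical positive" (diabetic) and the all-zeros
"prototypical negative" (non-diabetic) profile. Four distances (Euclidean,
Manhattan, cosine, Chebyshev) are combined by a convex weight vector into a
hybrid distance per class, converted to a fuzzy membership by exponential
decay ``mu = exp(-beta * Lambda)``, and normalised into a single score

    score = exp(mu_pos) / (exp(mu_pos) + exp(mu_neg))

thresholded at 0.5 for the final label. Confidence bands on the larger
membership stratify predictions for clinical triage.

By default the Euclidean and Manhattan distances are rescaled by ``sqrt(M)``
and ``M`` respectively so that all four metrics — and hence the hybrid
distance — lie in [0, 1] and are commensurate under weighted averaging; the
unscaled form is available via ``normalize=False``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ConfidenceMatrix",
    "DistanceWeights",
    "MetricBundle",
    "FusionResult",
    "FuzzyDistanceFusion",
    "CONFIDENCE_LEVELS",
    "deviation_vector",
    "multi_metric_distances",
    "hybrid_distance",
    "membership",
    "fuzzy_score",
    "decide",
    "confidence_level",
    "fuse",
]

#: Triage bands on the maximum fuzzy membership.
CONFIDENCE_LEVELS = ("VeryHigh", "High", "Moderate")

#: Tuned four-metric weights (Euclidean, Manhattan, cosine, Chebyshev).
DEFAULT_WEIGHTS = (0.30, 0.30, 0.20, 0.20)

#: Default decay sensitivity when untuned.
DEFAULT_BETA = 2.0

_ATOL = 1e-9


@dataclass(frozen=True)
class DistanceWeights:
    """Convex weights over the four distance metrics.

    Attributes
    ----------
    euclidean, manhattan, cosine, chebyshev : float
        Non-negative fractions summing to 1.
    """

    euclidean: float
    manhattan: float
    cosine: float
    chebyshev: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError(f"distance weights must be non-negative, got {tuple(vals)}")
        if abs(vals.sum() - 1.0) > _ATOL:
            raise ValueError(f"distance weights must sum to 1, got sum={vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.euclidean, self.manhattan, self.cosine, self.chebyshev], dtype=float
        )

    @classmethod
    def from_iterable(cls, w: Sequence[float]) -> "DistanceWeights":
        w = tuple(float(x) for x in w)
        if len(w) != 4:
            raise ValueError(f"expected 4 weights, got {len(w)}")
        return cls(*w)

    def drop(self, metric: str) -> "DistanceWeights":
        """Remove one metric, redistributing its weight proportionally."""
        names = ("euclidean", "manhattan", "cosine", "chebyshev")
        if metric not in names:
            raise ValueError(f"unknown metric {metric!r}; expected one of {names}")
        vals = dict(zip(names, self.as_array()))
        dropped = vals.pop(metric)
        remaining = sum(vals.values())
        if remaining <= _ATOL:
            raise ValueError(
                f"cannot drop {metric!r}: it carries all the weight ({dropped})"
            )
        scale = 1.0 / remaining
        vals = {k: v * scale for k, v in vals.items()}
        vals[metric] = 0.0
        return DistanceWeights(**{k: vals[k] for k in names})


@dataclass(frozen=True)
class MetricBundle:
    """The four per-class distances for one sample (normalised form in [0,1])."""

    euclidean: float
    manhattan: float
    cosine: float
    chebyshev: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.euclidean, self.manhattan, self.cosine, self.chebyshev], dtype=float
        )


@dataclass(frozen=True)
class FusionResult:
    """Per-sample fusion outputs, mutually consistent by construction."""

    lambda_pos: float
    lambda_neg: float
    mu_pos: float
    mu_neg: float
    fuzzy_score: float
    label: int
    confidence_level: str

    @property
    def mu_max(self) -> float:
        return max(self.mu_pos, self.mu_neg)


class ConfidenceMatrix:
    """Per-sample, per-model, per-class confidence scores.

    Parameters
    ----------
    positive : array-like of shape (n_samples, n_models)
        Positive-class (diabetic) probabilities from each base model.
    model_ids : sequence of str, optional
        Ordered base-model labels.

    The binary complement populates the negative class, so
    ``scores[i, z, 0] + scores[i, z, 1] == 1`` exactly.
    """

    class_ids = (0, 1)

    def __init__(self, positive, model_ids: Sequence[str] | None = None):
        P = np.asarray(positive, dtype=float)
        if P.ndim != 2:
            raise ValueError(f"expected a 2-D (samples x models) array, got ndim={P.ndim}")
        if P.shape[1] == 0:
            raise ValueError("empty ensemble: confidence matrix has no models")
        if np.any(~np.isfinite(P)) or np.any(P < 0) or np.any(P > 1):
            bad = np.argwhere(~((P >= 0) & (P <= 1)))
            i, z = bad[0]
            raise ValueError(
                f"confidence outside [0,1] at sample {i}, model index {z}: {P[i, z]!r}"
            )
        self.positive = P
        if model_ids is None:
            model_ids = tuple(f"model_{z}" for z in range(P.shape[1]))
        if len(model_ids) != P.shape[1]:
            raise ValueError("model_ids length does not match the number of models")
        self.model_ids = tuple(model_ids)

    @property
    def n_samples(self) -> int:
        return self.positive.shape[0]

    @property
    def n_models(self) -> int:
        return self.positive.shape[1]

    @property
    def scores(self) -> np.ndarray:
        """Full (samples x models x classes) score tensor."""
        return np.stack([1.0 - self.positive, self.positive], axis=2)

    def to_frame(self):
        import pandas as pd

        cols = {}
        for z, m in enumerate(self.model_ids):
            cols[f"{m}_neg"] = 1.0 - self.positive[:, z]
            cols[f"{m}_pos"] = self.positive[:, z]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame) -> "ConfidenceMatrix":
        pos_cols = [c for c in frame.columns if c.endswith("_pos")]
        if not pos_cols:
            raise ValueError("no '<model>_pos' columns found in confidence CSV")
        models = [c[: -len("_pos")] for c in pos_cols]
        return cls(frame[pos_cols].to_numpy(), model_ids=models)


def deviation_vector(confidences) -> np.ndarray:
    """Elementwise complement ``1 - S`` of a confidence vector."""
    S = np.asarray(confidences, dtype=float)
    bad = np.argwhere(~((S >= 0) & (S <= 1)))
    if bad.size:
        z = int(bad.ravel()[0])
        raise ValueError(f"confidence for model index {z} outside [0,1]: {S.flat[z]!r}")
    return 1.0 - S


def _cosine_distance(S: np.ndarray, positive_ideal: bool) -> np.ndarray:
    """Cosine distance against the relevant ideal direction.

    The all-zeros ideal has no direction, so for the negative class the
    deviation vector ``1 - S`` is compared with the ones vector instead.
    A zero-magnitude vector falls back to maximal misalignment (1).
    """
    V = S if positive_ideal else 1.0 - S
    M = V.shape[-1]
    norm = np.linalg.norm(V, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_sim = V.sum(axis=-1) / (norm * math.sqrt(M))
    d = 1.0 - cos_sim
    return np.where(norm > 0, d, 1.0)


def _distance_components(P: np.ndarray, positive_ideal: bool, normalize: bool) -> np.ndarray:
    """Stack of (d_E, d_M, d_C, d_Ch) for each row of ``P`` (n x M)."""
    dev = (1.0 - P) if positive_ideal else P
    M = P.shape[-1]
    d_e = np.linalg.norm(dev, axis=-1)
    d_m = np.abs(dev).sum(axis=-1)
    if normalize:
        d_e = d_e / math.sqrt(M)
        d_m = d_m / M
    d_ch = np.abs(dev).max(axis=-1)
    d_c = _cosine_distance(P, positive_ideal)
    return np.stack([d_e, d_m, d_c, d_ch], axis=-1)


def multi_metric_distances(
    confidences, positive_ideal: bool = True, normalize: bool = True
) -> MetricBundle:
    """Four distances from a length-M confidence vector to an ideal vector.

    Parameters
    ----------
    confidences : array-like of shape (n_models,)
        Per-model confidences in [0, 1].
    positive_ideal : bool
        True for the all-ones (positive-class) reference, False for the
        all-zeros one.
    normalize : bool
        Rescale Euclidean by sqrt(M) and Manhattan by M so every metric
        lies in [0, 1].
    """
    S = np.asarray(confidences, dtype=float)
    if S.ndim != 1 or S.size < 1:
        raise ValueError("confidences must be a non-empty 1-D vector")
    deviation_vector(S)  # bounds check with model index in the message
    d = _distance_components(S[None, :], positive_ideal, normalize)[0]
    return MetricBundle(*d)


def hybrid_distance(bundle: MetricBundle, weights: DistanceWeights) -> float:
    """Convex combination of the four distances (Eq. Lambda = sum w_k d_k)."""
    if not isinstance(weights, DistanceWeights):
        weights = DistanceWeights.from_iterable(weights)
    return float(weights.as_array() @ bundle.as_array())


def membership(lam, beta: float):
    """Exponential-decay membership ``mu = exp(-beta * Lambda)``."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("hybrid distance must be non-negative")
    out = np.exp(-beta * lam)
    return float(out) if out.ndim == 0 else out


def fuzzy_score(mu_pos, mu_neg):
    """Softmax-style normalisation ``e^mu_pos / (e^mu_pos + e^mu_neg)``."""
    mu_pos = np.asarray(mu_pos, dtype=float)
    mu_neg = np.asarray(mu_neg, dtype=float)
    if np.any(~np.isfinite(mu_pos)) or np.any(~np.isfinite(mu_neg)):
        bad = np.argwhere(~(np.isfinite(mu_pos) & np.isfinite(mu_neg))).ravel()
        raise FloatingPointError(f"non-finite membership at sample(s) {bad.tolist()}")
    out = 1.0 / (1.0 + np.exp(mu_neg - mu_pos))
    return float(out) if out.ndim == 0 else out


def decide(score):
    """Threshold the fuzzy score at 0.5; the tie goes to the positive class.

    In a screening setting a borderline case is routed to the
    higher-recall (diabetic) side.
    """
    score = np.asarray(score, dtype=float)
    out = (score >= 0.5).astype(int)
    return int(out) if out.ndim == 0 else out


def confidence_level(mu_max: float) -> str:
    """Triage band from the maximum membership (VeryHigh / High / Moderate)."""
    if mu_max > 0.9:
        return "VeryHigh"
    if mu_max > 0.7:
        return "High"
    return "Moderate"


def fuse(
    matrix: ConfidenceMatrix,
    weights: DistanceWeights | Sequence[float] = DEFAULT_WEIGHTS,
    beta: float = DEFAULT_BETA,
    normalize: bool = True,
) -> list[FusionResult]:
    """Run the full fusion pipeline over a confidence matrix.

    Per sample: deviation vectors, four distances against both ideals,
    hybrid distances, exponential memberships, normalised fuzzy score,
    thresholded label and confidence band.
    """
    if not isinstance(matrix, ConfidenceMatrix):
        matrix = ConfidenceMatrix(matrix)
    if not isinstance(weights, DistanceWeights):
        weights = DistanceWeights.from_iterable(weights)
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    w = weights.as_array()
    P = matrix.positive
    lam_pos = _distance_components(P, True, normalize) @ w
    lam_neg = _distance_components(P, False, normalize) @ w
    mu_pos = np.exp(-beta * lam_pos)
    mu_neg = np.exp(-beta * lam_neg)
    scores = fuzzy_score(mu_pos, mu_neg)
    labels = decide(np.atleast_1d(scores))
    results = []
    for i in range(matrix.n_samples):
        mu_max = max(mu_pos[i], mu_neg[i])
        results.append(
            FusionResult(
                lambda_pos=float(lam_pos[i]),
                lambda_neg=float(lam_neg[i]),
                mu_pos=float(mu_pos[i]),
                mu_neg=float(mu_neg[i]),
                fuzzy_score=float(np.atleast_1d(scores)[i]),
                label=int(labels[i]),
                confidence_level=confidence_level(mu_max),
            )
        )
    return results


def results_to_frame(results: Sequence[FusionResult]):
    """FusionResults as a DataFrame (the CSV export schema)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": np.arange(len(results)),
            "lambda_pos": [r.lambda_pos for r in results],
            "lambda_neg": [r.lambda_neg for r in results],
            "mu_pos": [r.mu_pos for r in results],
            "mu_neg": [r.mu_neg for r in results],
            "fuzzy_score": [r.fuzzy_score for r in results],
            "label": [r.label for r in results],
            "confidence_level": [r.confidence_level for r in results],
        }
    )


class FuzzyDistanceFusion(BaseEstimator):
    """Sklearn-style wrapper around the fusion layer.

    Operates on confidence matrices (samples x models of positive-class
    probabilities) rather than raw features; compose with a fitted base
    ensemble for an end-to-end classifier.

    Parameters
    ----------
    weights : tuple of 4 floats, default (0.30, 0.30, 0.20, 0.20)
        Convex weights for (Euclidean, Manhattan, cosine, Chebyshev).
    beta : float, default 2.0
        Exponential-decay sensitivity.
    normalize : bool, default True
        Use metrics rescaled to [0, 1].
    """

    def __init__(self, weights=DEFAULT_WEIGHTS, beta=DEFAULT_BETA, normalize=True):
        self.weights = weights
        self.beta = beta
        self.normalize = normalize

    def fit(self, C, y=None):
        matrix = C if isinstance(C, ConfidenceMatrix) else ConfidenceMatrix(C)
        DistanceWeights.from_iterable(self.weights)
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta!r}")
        self.n_models_ = matrix.n_models
        return self

    def transform(self, C) -> list[FusionResult]:
        return fuse(C, weights=DistanceWeights.from_iterable(self.weights),
                    beta=self.beta, normalize=self.normalize)

    def predict(self, C) -> np.ndarray:
        return np.array([r.label for r in self.transform(C)])

    def predict_score(self, C) -> np.ndarray:
        return np.array([r.fuzzy_score for r in self.transform(C)])
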