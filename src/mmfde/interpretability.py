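"""Feature attributions, rank stability and geometric-attribution concordance.

Attributions are exact interventional Shapley values: with m clinical
features the 2^m feature coalitions are enumerated and the value of a
coalition is the mean model output with the complementary features
replaced by background-sample values. Additivity (base value plus the sum
of attributions equals the explained output) then holds to machine
precision. Two explanation modes are provided: ``per_model_mean``
attributes the equally-weighted mean positive-class probability of the
four base models, and ``fused_model_agnostic`` attributes the end-to-end
fuzzy score of the fusion layer.

The module also computes cross-fold rank stability of feature importance
(mean Kendall tau over fold pairs on the top-k union) and the concordance
analysis between the sign of the dominant attribution and the
distance-based decision.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .fusion import DistanceWeights, FusionResult, fuse

__all__ = [
    "AttributionTable",
    "ConcordanceReport",
    "exact_shapley",
    "explain",
    "global_importance",
    "rank_stability",
    "concordance_analysis",
]

EXPLANATION_MODES = ("per_model_mean", "fused_model_agnostic")


@dataclass
class AttributionTable:
    """Per-sample, per-feature additive attributions.

    ``base_value + values.sum(axis=1)`` equals the explained model output
    for every sample (additivity).
    """

    values: pd.DataFrame
    base_value: float
    explained_output: np.ndarray
    mode: str

    @property
    def feature_names(self) -> tuple:
        return tuple(self.values.columns)

    def additivity_residual(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1).to_numpy() - self.explained_output


def exact_shapley(predict_fn, X: pd.DataFrame, background: pd.DataFrame) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact interventional Shapley values by coalition enumeration.

    Parameters
    ----------
    predict_fn : callable
        Maps a feature DataFrame to a 1-D output vector.
    X : DataFrame of shape (n, m)
        Samples to explain; m must be modest (2^m coalitions).
    background : DataFrame of shape (k, m)
        Reference sample defining the off-coalition feature distribution.

    Returns ``(phi, base_value, outputs)`` with ``phi`` of shape (n, m),
    ``base_value`` the mean background prediction, and ``outputs`` the
    explained predictions, satisfying ``base + phi.sum(1) == outputs``.
    """
    m = X.shape[1]
    if m > 16:
        raise ValueError(f"exact Shapley enumeration is limited to 16 features, got {m}")
    if list(background.columns) != list(X.columns):
        raise ValueError("background columns must match the explained samples")
    n, k = len(X), len(background)
    Xv = X.to_numpy(dtype=float)
    Bv = background.to_numpy(dtype=float)

    # v[T] for each coalition T: mean prediction over background rows with
    # features in T set to the explained sample's values.
    v = {}
    tiled_bg = np.tile(Bv, (n, 1))  # (n*k, m) blocks of the background
    for mask in range(1 << m):
        cols = [j for j in range(m) if mask >> j & 1]
        arr = tiled_bg.copy()
        if cols:
            arr[:, cols] = np.repeat(Xv[:, cols], k, axis=0)
        preds = np.asarray(predict_fn(pd.DataFrame(arr, columns=X.columns)), dtype=float)
        v[mask] = preds.reshape(n, k).mean(axis=1)

    fact = [math.factorial(i) for i in range(m + 1)]
    phi = np.zeros((n, m))
    for mask in range(1 << m):
        t = bin(mask).count("1")
        for j in range(m):
            if mask >> j & 1:
                continue
            w = fact[t] * fact[m - t - 1] / fact[m]
            phi[:, j] += w * (v[mask | (1 << j)] - v[mask])

    base = float(v[0].mean())
    # per-sample v(empty) is constant (pure background), so base is scalar
    outputs = v[(1 << m) - 1]
    return phi, base, outputs


def _background_sample(X: pd.DataFrame, background, seed: int) -> pd.DataFrame:
    if background is not None:
        return background
    k = min(32, len(X))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=k, replace=False)
    return X.iloc[idx].reset_index(drop=True)


def explain(
    handle,
    X: pd.DataFrame,
    mode: str = "per_model_mean",
    background: pd.DataFrame | None = None,
    weights=None,
    beta: float = 2.0,
    normalize: bool = True,
    seed: int = 0,
) -> AttributionTable:
    """Shapley attributions for the ensemble's predictions on ``X``.

    ``per_model_mean`` explains the equally-weighted mean positive-class
    probability of the four base models (by linearity this equals the
    average of per-model attributions). ``fused_model_agnostic`` explains
    the end-to-end fuzzy score, including the distance fusion with the
    given ``weights`` and ``beta``.
    """
    if mode not in EXPLANATION_MODES:
        raise ValueError(f"unknown explanation mode {mode!r}; expected {EXPLANATION_MODES}")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(handle.feature_names))
    bg = _background_sample(X, background, seed)

    if mode == "per_model_mean":
        def predict_fn(df):
            return handle.predict_confidences(df).positive.mean(axis=1)
    else:
        if weights is None:
            from .fusion import DEFAULT_WEIGHTS

            weights = DEFAULT_WEIGHTS
        w = DistanceWeights.from_iterable(weights) if not isinstance(weights, DistanceWeights) else weights

        def predict_fn(df):
            results = fuse(handle.predict_confidences(df), weights=w, beta=beta,
                           normalize=normalize)
            return np.array([r.fuzzy_score for r in results])

    phi, base, outputs = exact_shapley(predict_fn, X, bg)
    return AttributionTable(
        values=pd.DataFrame(phi, columns=list(X.columns)),
        base_value=base,
        explained_output=outputs,
        mode=mode,
    )


def global_importance(table: AttributionTable) -> list[tuple[str, float]]:
    """Features ranked by mean absolute attribution (ties alphabetical)."""
    if len(table.values) == 0:
        raise ValueError("empty attribution table")
    means = table.values.abs().mean(axis=0)
    return sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))


def rank_stability(per_fold_rankings: list[list[str]], k: int = 5) -> float:
    """Mean Kendall tau over fold pairs on the top-k union.

    For each pair of fold rankings, the union of both top-k sets is
    compared; a feature outside one ranking's top-k is placed by its
    position in that fold's full ranking.
    """
    if len(per_fold_rankings) < 2:
        raise ValueError("rank stability needs at least two fold rankings")
    universe = set(per_fold_rankings[0])
    for r in per_fold_rankings[1:]:
        if set(r) != universe:
            raise ValueError("all fold rankings must cover the same feature set")
    if k > len(universe):
        warnings.warn(f"k={k} exceeds the {len(universe)}-feature universe; clamping")
        k = len(universe)

    taus = []
    for ra, rb in itertools.combinations(per_fold_rankings, 2):
        top = sorted(set(ra[:k]) | set(rb[:k]))
        pos_a = [ra.index(f) for f in top]
        pos_b = [rb.index(f) for f in top]
        tau, _ = kendalltau(pos_a, pos_b)
        taus.append(tau)
    return float(np.mean(taus))


@dataclass
class ConcordanceReport:
    """Agreement between dominant-attribution direction and the
    distance-based decision, with confidence and error stratification."""

    concordance_pct: float
    discordance_pct: float
    pct_discordant_with_moderate_confidence: float
    misclassification_rate_concordant: float
    misclassification_rate_discordant: float
    n_evaluated: int
    n_excluded: int


def concordance_analysis(
    table: AttributionTable, results: list[FusionResult], labels
) -> ConcordanceReport:
    """Concordance between attributions and geometric decisions.

    Per sample the dominant feature is the one with the largest absolute
    attribution; its sign implies a class (positive attribution pushes
    toward diabetic). A sample is concordant when that implied class
    matches the distance-based label (arg-min hybrid distance). Samples
    whose attributions are identically zero are excluded and counted.
    """
    labels = np.asarray(labels).astype(int)
    if not (len(table.values) == len(results) == len(labels)):
        raise ValueError("attributions, fusion results and labels must align")
    vals = table.values.to_numpy()
    excluded = np.all(vals == 0, axis=1)

    abs_vals = np.abs(vals)
    dominant = abs_vals.argmax(axis=1)
    # break exact |value| ties alphabetically
    for i in np.where((abs_vals == abs_vals.max(axis=1, keepdims=True)).sum(axis=1) > 1)[0]:
        tied = np.where(abs_vals[i] == abs_vals[i].max())[0]
        dominant[i] = min(tied, key=lambda j: table.values.columns[j])

    implied = (vals[np.arange(len(vals)), dominant] > 0).astype(int)
    geometric = np.array([int(r.lambda_pos < r.lambda_neg) for r in results])
    mu_max = np.array([r.mu_max for r in results])
    predicted = np.array([r.label for r in results])

    keep = ~excluded
    concordant = implied[keep] == geometric[keep]
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no samples with non-zero attributions to evaluate")
    conc_pct = 100.0 * concordant.mean()

    disc_mask = ~concordant
    moderate = mu_max[keep] <= 0.7
    pct_disc_moderate = (
        100.0 * (disc_mask & moderate).sum() / disc_mask.sum() if disc_mask.any() else 0.0
    )
    wrong = predicted[keep] != labels[keep]
    mis_conc = 100.0 * wrong[concordant].mean() if concordant.any() else 0.0
    mis_disc = 100.0 * wrong[disc_mask].mean() if disc_mask.any() else 0.0

    return ConcordanceReport(
        concordance_pct=float(conc_pct),
        discordance_pct=float(100.0 - conc_pct),
        pct_discordant_with_moderate_confidence=float(pct_disc_moderate),
        misclassification_rate_concordant=float(mis_conc),
        misclassification_rate_discordant=float(mis_disc),
        n_evaluated=n,
        n_excluded=int(excluded.sum()),
    )
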