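"""Base gradient-boosting ensemble and leakage-safe preprocessing.

Four boosted-tree classifiers (LightGBM, XGBoost, scikit-learn gradient
boosting, AdaBoost) are trained on min-max-scaled clinical features and
their positive-class probabilities populate a :class:`ConfidenceMatrix`
for the fusion layer. The bespoke surface here is the fold discipline
(scaling and imputation parameters are fitted on training rows only), the
zero-as-missing imputation rule for PIDD-style columns, and the
confidence-matrix contract — the boosters themselves come from their
libraries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .fusion import (
    DEFAULT_BETA,
    DEFAULT_WEIGHTS,
    ConfidenceMatrix,
    DistanceWeights,
    FusionResult,
    fuse,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE3_SCHEMA",
    "ZERO_MISSING_COLUMNS",
    "BaseModelSpec",
    "SplitPlan",
    "CohortTable",
    "ClinicalPreprocessor",
    "EnsembleHandle",
    "MMFDEClassifier",
    "default_model_specs",
    "fit_ensemble",
    "train_base_models",
]

#: Clinical attribute schema: name -> (min, max) declared range.
TABLE3_SCHEMA = {
    "Pregnancies": (0.0, 17.0),
    "Glucose": (0.0, 199.0),
    "BloodPressure": (0.0, 122.0),
    "SkinThickness": (0.0, 99.0),
    "Insulin": (0.0, 846.0),
    "BMI": (0.0, 80.6),
    "DPF": (0.078, 2.42),
    "Age": (1.0, 120.0),
}

FEATURE_COLUMNS = tuple(TABLE3_SCHEMA)
OUTCOME_COLUMN = "Outcome"

#: Columns where a recorded zero is physiologically impossible and
#: therefore coded missingness (PIDD convention).
ZERO_MISSING_COLUMNS = ("Glucose", "BloodPressure", "SkinThickness", "Insulin", "BMI")

MODEL_ORDER = ("lightgbm", "xgboost", "gbm", "adaboost")


@dataclass
class CohortTable:
    """Feature matrix plus binary outcome with schema metadata."""

    features: pd.DataFrame
    outcome: np.ndarray
    attribute_ranges: dict = field(default_factory=lambda: dict(TABLE3_SCHEMA))

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome).astype(int)
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if len(self.features) != len(self.outcome):
            raise ValueError("features and outcome lengths differ")

    @property
    def n(self) -> int:
        return len(self.outcome)

    def validate_ranges(self) -> list[str]:
        """Warn (never fail) about values outside the declared ranges."""
        msgs = []
        for col, (lo, hi) in self.attribute_ranges.items():
            if col not in self.features:
                continue
            v = self.features[col]
            if (v < lo).any() or (v > hi).any():
                msg = f"column {col} has values outside the declared range [{lo}, {hi}]"
                warnings.warn(msg)
                msgs.append(msg)
        return msgs

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_COLUMNS + (OUTCOME_COLUMN,) if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        return cls(df[list(FEATURE_COLUMNS)].copy(), df[OUTCOME_COLUMN].to_numpy())

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out[OUTCOME_COLUMN] = self.outcome
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class BaseModelSpec:
    """Hyperparameters of one base booster.

    Defaults follow the reference configuration: 200 estimators at
    learning rate 0.05; tree depth 6 for LightGBM/XGBoost and 5 for GBM
    (AdaBoost keeps the library's stump base learner); L1 = L2 = 0.1 for
    the two histogram boosters and subsample 0.8 for GBM; seed 42.
    """

    model_kind: str
    n_estimators: int = 200
    learning_rate: float = 0.05
    max_depth: int | None = None
    regularization: tuple = ()
    seed: int = 42

    def build(self):
        reg = dict(self.regularization)
        if self.model_kind == "lightgbm":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                reg_alpha=reg.get("l1", 0.0),
                reg_lambda=reg.get("l2", 0.0),
                random_state=self.seed,
                verbose=-1,
            )
        if self.model_kind == "xgboost":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                reg_alpha=reg.get("l1", 0.0),
                reg_lambda=reg.get("l2", 0.0),
                random_state=self.seed,
                eval_metric="logloss",
                verbosity=0,
            )
        if self.model_kind == "gbm":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth if self.max_depth is not None else 3,
                subsample=reg.get("subsample", 1.0),
                random_state=self.seed,
            )
        if self.model_kind == "adaboost":
            # No depth/regularization row for AdaBoost: library stump default.
            logger.info("AdaBoost base learner: library default (depth-1 stump)")
            return AdaBoostClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                random_state=self.seed,
            )
        raise ValueError(f"unknown model_kind {self.model_kind!r}")


def default_model_specs(seed: int = 42) -> dict[str, BaseModelSpec]:
    """The four reference base-model specifications."""
    return {
        "lightgbm": BaseModelSpec("lightgbm", max_depth=6,
                                  regularization=(("l1", 0.1), ("l2", 0.1)), seed=seed),
        "xgboost": BaseModelSpec("xgboost", max_depth=6,
                                 regularization=(("l1", 0.1), ("l2", 0.1)), seed=seed),
        "gbm": BaseModelSpec("gbm", max_depth=5,
                             regularization=(("subsample", 0.8),), seed=seed),
        "adaboost": BaseModelSpec("adaboost", seed=seed),
    }


@dataclass(frozen=True)
class SplitPlan:
    """Train/test split and cross-validation layout."""

    train_fraction: float = 0.8
    n_folds: int = 5
    stratified: bool = True
    seed: int = 42

    def outer_split(self, X, y):
        idx = np.arange(len(y))
        strat = y if self.stratified else None
        train_idx, test_idx = train_test_split(
            idx, train_size=self.train_fraction, stratify=strat, random_state=self.seed
        )
        return train_idx, test_idx

    def folds(self, X, y):
        cv = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        return list(cv.split(np.zeros(len(y)), y))


class ClinicalPreprocessor(BaseEstimator, TransformerMixin):
    """Zero-as-missing median imputation plus min-max scaling.

    Both the per-column medians and the min/max parameters are computed on
    the rows seen at ``fit`` time only, so fold discipline is enforced by
    fitting on each training partition. Values outside the training range
    scale outside [0, 1] and are deliberately not clipped. A constant
    column maps to 0 with a warning.

    Parameters
    ----------
    zero_missing_columns : tuple of str or None
        Columns where zeros are treated as missing (None disables
        imputation, the HFGDD-style path).
    """

    def __init__(self, zero_missing_columns=ZERO_MISSING_COLUMNS):
        self.zero_missing_columns = zero_missing_columns

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float),
                            columns=list(getattr(self, "feature_names_in_", [])) or None)

    def fit(self, X, y=None):
        df = self._frame(X).copy()
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            for col in df.columns:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    row = int(np.argmax(bad.to_numpy()))
                    raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
        if len(df) == 0:
            raise ValueError("cannot fit preprocessing on an empty training set")
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.medians_ = {}
        for col in self.zero_missing_columns or ():
            if col in df.columns:
                nonzero = df.loc[df[col] != 0, col]
                self.medians_[col] = float(nonzero.median()) if len(nonzero) else 0.0
                df.loc[df[col] == 0, col] = self.medians_[col]
        self.data_min_ = df.min(axis=0).to_numpy(dtype=float)
        self.data_max_ = df.max(axis=0).to_numpy(dtype=float)
        span = self.data_max_ - self.data_min_
        for j, col in enumerate(df.columns):
            if span[j] == 0:
                warnings.warn(f"constant column {col!r}: min-max scaling maps it to 0")
        self.scale_ = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        df = self._frame(X).copy()
        if list(df.columns) != list(self.feature_names_in_):
            if set(df.columns) == set(self.feature_names_in_):
                df = df[list(self.feature_names_in_)]
            else:
                raise ValueError(
                    f"feature columns {list(df.columns)} do not match the "
                    f"training schema {list(self.feature_names_in_)}"
                )
        for col, med in self.medians_.items():
            df.loc[df[col] == 0, col] = med
        arr = df.to_numpy(dtype=float)
        return (arr - self.data_min_) / self.scale_


@dataclass
class EnsembleHandle:
    """A fitted preprocessor plus the four fitted base models."""

    preprocessor: ClinicalPreprocessor
    models: dict
    feature_names: tuple

    @property
    def model_ids(self) -> tuple:
        return tuple(self.models)

    def predict_confidences(self, X) -> ConfidenceMatrix:
        """Positive-class probabilities from every base model."""
        Xt = pd.DataFrame(
            self.preprocessor.transform(self._check_schema(X)),
            columns=list(self.feature_names),
        )
        cols = [m.predict_proba(Xt)[:, 1] for m in self.models.values()]
        return ConfidenceMatrix(np.column_stack(cols), model_ids=self.model_ids)

    def _check_schema(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            return X[list(self.feature_names)]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
            )
        return pd.DataFrame(X, columns=list(self.feature_names))


def fit_ensemble(
    X,
    y,
    specs: dict[str, BaseModelSpec] | None = None,
    zero_missing_columns=ZERO_MISSING_COLUMNS,
) -> EnsembleHandle:
    """Fit the preprocessor and all four base models on one training set."""
    if specs is None:
        specs = default_model_specs()
    missing = [k for k in MODEL_ORDER if k not in specs]
    if missing:
        raise ValueError(f"missing base-model specs: {missing}")
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class; check stratification")
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=list(FEATURE_COLUMNS)[: X.shape[1]])
    pre = ClinicalPreprocessor(zero_missing_columns=zero_missing_columns).fit(X)
    Xt = pd.DataFrame(pre.transform(X), columns=list(X.columns))
    models = {}
    for kind in MODEL_ORDER:
        models[kind] = specs[kind].build().fit(Xt, y)
    return EnsembleHandle(preprocessor=pre, models=models,
                          feature_names=tuple(X.columns))


def train_base_models(cohort: CohortTable, specs=None, plan: SplitPlan | None = None):
    """Train on the cohort's training partition per the split plan.

    Returns ``(handle, train_idx, test_idx)``.
    """
    plan = plan or SplitPlan()
    train_idx, test_idx = plan.outer_split(cohort.features, cohort.outcome)
    handle = fit_ensemble(
        cohort.features.iloc[train_idx], cohort.outcome[train_idx], specs=specs
    )
    return handle, train_idx, test_idx


class MMFDEClassifier(BaseEstimator, ClassifierMixin):
    """Multi-metric fuzzy distance-based ensemble classifier.

    Trains the four boosted-tree base models on min-max-scaled features,
    then fuses their probability outputs through the multi-metric distance
    geometry: distances to the all-ones / all-zeros ideal confidence
    vectors are blended by ``weights``, decayed into fuzzy memberships by
    ``beta``, and normalised into a score thresholded at 0.5.

    Parameters
    ----------
    weights : tuple of 4 floats, default (0.30, 0.30, 0.20, 0.20)
        Convex weights for (Euclidean, Manhattan, cosine, Chebyshev).
    beta : float, default 2.0
        Exponential-decay sensitivity of the membership transform.
    normalize : bool, default True
        Use [0, 1]-commensurate distance metrics.
    impute_zeros : bool, default True
        Treat zeros in the PIDD-affected columns as missing.
    seed : int, default 42
        Random seed shared by every base model.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    handle_ : EnsembleHandle
        Fitted preprocessor and base models.
    """

    def __init__(self, weights=DEFAULT_WEIGHTS, beta=DEFAULT_BETA, normalize=True,
                 impute_zeros=True, seed=42):
        self.weights = weights
        self.beta = beta
        self.normalize = normalize
        self.impute_zeros = impute_zeros
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if not set(classes) <= {0, 1} or len(classes) < 2:
            raise ValueError("MMFDEClassifier requires binary 0/1 outcomes, both present")
        DistanceWeights.from_iterable(self.weights)
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta!r}")
        zero_cols = ZERO_MISSING_COLUMNS if self.impute_zeros else None
        self.handle_ = fit_ensemble(
            X, y, specs=default_model_specs(seed=self.seed),
            zero_missing_columns=zero_cols,
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(self.handle_.feature_names)
        return self

    def fuse_results(self, X) -> list[FusionResult]:
        check_is_fitted(self, "handle_")
        matrix = self.handle_.predict_confidences(X)
        return fuse(matrix, weights=DistanceWeights.from_iterable(self.weights),
                    beta=self.beta, normalize=self.normalize)

    def predict_confidences(self, X) -> ConfidenceMatrix:
        check_is_fitted(self, "handle_")
        return self.handle_.predict_confidences(X)

    def predict_proba(self, X) -> np.ndarray:
        scores = np.array([r.fuzzy_score for r in self.fuse_results(X)])
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        return np.array([r.label for r in self.fuse_results(X)])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] - 0.5
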