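"""Synthetic clinical cohorts and the embedded worked-example fixture.

The generator emulates the schema and value ranges of the two diabetes
benchmarks (Frankfurt hospital cohort, Pima Indians cohort): truncated
normal feature marginals inside the declared attribute ranges, a logistic
outcome model on standardised features with controllable per-feature
effects (glucose strongest, then BMI, then the pedigree function), logit
noise to tune difficulty, a target prevalence hit by calibrating the
intercept, and optional PIDD-style zero-coding of physiologically
impossible values.

``worked_example_fixture`` embeds the five-sample worked example (four base-model
probabilities per sample together with the printed distance, membership,
score, confidence-level and prediction rows) used across the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ensemble import FEATURE_COLUMNS, TABLE3_SCHEMA, ZERO_MISSING_COLUMNS, CohortTable

__all__ = ["GeneratorSpec", "WorkedExampleFixture", "generate_cohort", "worked_example_fixture"]

#: Truncated-normal marginals (mean, sd, low, high) chosen inside the
#: declared attribute ranges; adult age range despite the schema's 1-120.
FEATURE_MARGINALS = {
    "Pregnancies": (3.0, 3.0, 0.0, 17.0),
    "Glucose": (120.0, 30.0, 44.0, 199.0),
    "BloodPressure": (70.0, 12.0, 24.0, 122.0),
    "SkinThickness": (29.0, 10.0, 7.0, 99.0),
    "Insulin": (125.0, 95.0, 14.0, 846.0),
    "BMI": (32.0, 7.0, 18.0, 67.0),
    "DPF": (0.5, 0.33, 0.078, 2.42),
    "Age": (38.0, 12.0, 21.0, 81.0),
}

#: Per-SD log-odds effects; ordering glucose > BMI > DPF mirrors the
#: global feature-importance ranking the fused model should recover.
DEFAULT_EFFECTS = {
    "Pregnancies": 0.15,
    "Glucose": 2.0,
    "BloodPressure": 0.1,
    "SkinThickness": 0.1,
    "Insulin": 0.4,
    "BMI": 1.2,
    "DPF": 0.8,
    "Age": 0.5,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Cohort-generation parameters.

    Attributes
    ----------
    n : int
        Cohort size (default 2000, the Frankfurt cohort size).
    prevalence : float
        Target diabetic fraction in (0, 1); default 0.44.
    effect_sizes : dict
        Per-feature log-odds coefficients on standardised features.
    noise_sd : float
        SD of additive logit noise; larger values emulate the harder
        (PIDD-like) regime.
    zero_inflation : dict
        Per-column probability of zero-coding; only the five
        physiologically-constrained columns are allowed.
    seed : int
    """

    n: int = 2000
    prevalence: float = 0.44
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 1.0
    zero_inflation: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence!r}")
        bad = set(self.zero_inflation) - set(ZERO_MISSING_COLUMNS)
        if bad:
            raise ValueError(
                f"zero_inflation only applies to {ZERO_MISSING_COLUMNS}, got {sorted(bad)}"
            )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-free truncated normal via inverse-CDF sampling."""
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: GeneratorSpec) -> CohortTable:
    """Draw a cohort from the generator's logistic outcome model.

    Deterministic given ``spec.seed``. The intercept is solved so the mean
    outcome probability matches ``spec.prevalence``; if the realised
    diabetic fraction still misses the target by more than 3 binomial SDs
    a warning reports the achieved prevalence.
    """
    if spec.n <= 0:
        raise ValueError(f"cohort size must be positive, got {spec.n}")
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name in FEATURE_COLUMNS:
        mean, sd, lo, hi = FEATURE_MARGINALS[name]
        vals = _truncated_normal(rng, mean, sd, lo, hi, spec.n)
        if name in ("Pregnancies", "Age"):
            vals = np.round(vals)
        cols[name] = vals
    X = pd.DataFrame(cols)

    # Logistic outcome on standardised features plus logit noise.
    logits = np.zeros(spec.n)
    for name in FEATURE_COLUMNS:
        beta = spec.effect_sizes.get(name, 0.0)
        if beta:
            v = X[name].to_numpy()
            logits += beta * (v - v.mean()) / v.std()
    if spec.noise_sd > 0:
        logits += rng.normal(0.0, spec.noise_sd, spec.n)

    def mean_prob(intercept):
        return expit(logits + intercept).mean() - spec.prevalence

    intercept = brentq(mean_prob, -30.0, 30.0)
    p = expit(logits + intercept)
    y = (rng.uniform(size=spec.n) < p).astype(int)

    achieved = y.mean()
    tol = 3.0 * np.sqrt(spec.prevalence * (1 - spec.prevalence) / spec.n)
    if abs(achieved - spec.prevalence) > tol:
        warnings.warn(
            f"achieved prevalence {achieved:.3f} misses target {spec.prevalence:.3f}"
        )

    # Zero-coding is applied after outcome generation, so the missingness
    # carries no outcome information.
    for col, rate in spec.zero_inflation.items():
        mask = rng.uniform(size=spec.n) < rate
        X.loc[mask, col] = 0.0

    return CohortTable(X, y)


@dataclass(frozen=True)
class WorkedExampleFixture:
    """The five-sample worked example, verbatim printed values.

    ``probabilities`` holds the positive-class outputs of the four base
    models (LightGBM, XGBoost, GBM, AdaBoost) for each sample; the
    remaining fields are the printed distance, membership, score,
    confidence-level and prediction rows for assertion.
    """

    probabilities: pd.DataFrame
    labels: tuple
    d_pos: tuple
    d_neg: tuple
    mu_pos: tuple
    mu_neg: tuple
    fuzzy_scores: tuple
    confidence_levels: tuple
    predictions: tuple


def worked_example_fixture() -> WorkedExampleFixture:
    """The embedded worked example (five test samples, four base models)."""
    probs = pd.DataFrame(
        {
            "lightgbm": [0.0118, 0.0931, 0.3406, 0.1175, 0.7920],
            "xgboost": [0.0104, 0.0410, 0.3200, 0.0629, 0.6680],
            "gbm": [0.0073, 0.0747, 0.3291, 0.5170, 0.6115],
            "adaboost": [0.1277, 0.4521, 0.0826, 0.2896, 0.5948],
        },
        index=[1, 2, 3, 4, 5],
    )
    return WorkedExampleFixture(
        probabilities=probs,
        labels=(0, 0, 0, 0, 1),
        d_pos=(0.5688, 0.5672, 0.3544, 0.4960, 0.1264),
        d_neg=(0.0060, 0.0429, 0.2333, 0.0668, 0.4888),
        mu_pos=(0.3383, 0.3394, 0.5090, 0.3887, 0.7860),
        mu_neg=(0.9887, 0.9214, 0.6411, 0.8805, 0.3941),
        fuzzy_scores=(0.3429, 0.3585, 0.4670, 0.3795, 0.5967),
        # Sample 2's mu_neg = 0.9214 > 0.9: the threshold table places it
        # in the VeryHigh band.
        confidence_levels=("VeryHigh", "VeryHigh", "Moderate", "High", "High"),
        predictions=(0, 0, 0, 0, 1),
    )
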