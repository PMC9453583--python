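"""Shapley additive explanations for the early-fusion logistic model.

For a linear decision function the Shapley values under background-mean
marginalization have the closed form phi_ij = w_j (x_ij - mean_j(background))
on the log-odds scale, where additivity (base value + sum of contributions =
model output) holds exactly. A model-agnostic Monte-Carlo permutation
estimator is also provided, along with a summary ranking of features by mean
absolute contribution and the sign of their value/contribution association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models import LogisticModel, fit_logistic, undersample_majority
from . import windows as win


@dataclass
class ShapExplanation:
    """Per-instance additive contributions on the linear-predictor scale."""

    base_value: float
    values: np.ndarray  # (n_instances, n_features)
    feature_names: tuple[str, ...]
    instances: np.ndarray  # (n_instances, n_features) raw feature values

    def model_output(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


def _linear_params(model) -> tuple[np.ndarray, float]:
    if isinstance(model, LogisticModel):
        return model.coef_raw, model.intercept_raw
    w, b = model  # (weights, intercept) pair
    return np.asarray(w, dtype=float), float(b)


def shap_exact_linear(model, instances: np.ndarray, background: np.ndarray,
                      feature_names=None) -> ShapExplanation:
    """Exact Shapley values of a linear decision function.

    ``model`` is a fitted :class:`LogisticModel` or a ``(weights, intercept)``
    pair on the raw feature scale. The background set defines the expected
    feature values features are marginalized to.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be nonempty")
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    w, b = _linear_params(model)
    mu = background.mean(axis=0)
    values = (instances - mu) * w
    names = tuple(feature_names) if feature_names is not None else tuple(f"x{i}" for i in range(w.size))
    base = float(mu @ w + b)
    return ShapExplanation(base, values, names, instances)


def shap_sampling(
    model_fn,
    instance: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo permutation estimate of Shapley values for one instance.

    ``model_fn`` maps an (n, p) array to model outputs. Each draw picks a
    random feature permutation and background row; features are switched from
    the background value to the instance value in permutation order and the
    marginal output changes are credited to the switched feature. Returns
    (values, standard errors).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = instance.size
    draws = np.zeros((n_samples, p))
    for s in range(n_samples):
        perm = rng.permutation(p)
        z = background[rng.integers(0, background.shape[0])].copy()
        prev = float(model_fn(z[None, :])[0])
        for j in perm:
            z[j] = instance[j]
            cur = float(model_fn(z[None, :])[0])
            draws[s, j] = cur - prev
            prev = cur
    values = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / np.sqrt(n_samples) if n_samples > 1 else np.zeros(p)
    return values, se


def summary_ranking(explanation: ShapExplanation) -> pd.DataFrame:
    """Features sorted by mean |contribution| with direction-of-effect signs.

    ``association`` is the sign of the Spearman correlation between the raw
    feature value and its contribution: positive means higher feature values
    push toward the decompensated class.
    """
    if explanation.values.shape[0] < 1:
        raise ValueError("need at least one explained instance")
    mean_abs = np.abs(explanation.values).mean(axis=0)
    assoc = np.zeros(mean_abs.size)
    for j in range(mean_abs.size):
        x = explanation.instances[:, j]
        v = explanation.values[:, j]
        if np.ptp(x) == 0 or np.ptp(v) == 0:
            assoc[j] = 0.0
        else:
            rho = spearmanr(x, v).statistic
            assoc[j] = np.sign(rho) if np.isfinite(rho) else 0.0
    out = pd.DataFrame(
        {"feature": list(explanation.feature_names), "mean_abs_shap": mean_abs, "association": assoc}
    )
    return out.sort_values("mean_abs_shap", ascending=False, kind="stable").reset_index(drop=True)


def explain_early_fusion(
    features: pd.DataFrame,
    modalities=("kccq", "motion", "social"),
    kccq_feature_set: str = "sum",
    seed: int = 0,
    C: float = 1.0,
) -> tuple[ShapExplanation, pd.DataFrame, LogisticModel]:
    """Fit an early-fusion logistic model and explain it.

    The model uses every feature of the requested modalities (no forward
    selection, so the ranking covers the full measured feature set); the
    training set is majority-undersampled and doubles as the SHAP background.
    Returns (explanation of all complete rows, summary ranking, model).
    """
    complete, _ = win.filter_complete_cases(features, modalities)
    cols = [c for m, cs in win.modality_columns(modalities, kccq_feature_set).items() for c in cs]
    X = complete[cols].to_numpy(dtype=float)
    y = complete["label"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = undersample_majority(y, rng)
    model = fit_logistic(X[idx], y[idx], cols, C=C)
    expl = shap_exact_linear(model, X, X[idx], feature_names=cols)
    return expl, summary_ranking(expl), model
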