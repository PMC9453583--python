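"""Classification of decompensated vs compensated events.

L2-regularized logistic regression under leave-one-subject-out (LOSO)
cross-validation with majority undersampling of the training fold,
per-modality sequential forward feature selection (SFS), and three model
forms: single-modality, early fusion (feature concatenation) and late
fusion (per-modality probabilities stacked into a second-level logistic).
Analyses are repeated over seeds and summarized as mean (SD) of accuracy,
AUC, AUCPr, PPV, TPR and specificity.

The logistic fit is a damped Newton solver for the standard objective
``sum log(1+exp(-y_i z_i)) + (1/2C) ||w||^2`` (intercept unpenalized),
numerically equivalent to scikit-learn's ``LogisticRegression(C=C)`` but
without per-call overhead — the LOSO x SFS x 50-repeat design performs on
the order of a million fits on ~100-row tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import GroupKFold

from . import windows as win

METRIC_NAMES = ("accuracy", "AUC", "AUCPr", "PPV", "TPR", "specificity")

FUSION_MODES = ("single", "early", "late")


@dataclass
class ModelConfig:
    """Configuration of one classification analysis."""

    modalities: tuple[str, ...] = ("kccq", "motion", "social")
    fusion: str = "late"
    sfs_k: int | None = 3
    n_repeats: int = 50
    base_seed: int = 0
    threshold: float = 0.5
    standardize: bool = True
    C: float = 1.0
    sfs_inner_folds: int = 5
    kccq_mode: str = "most_recent"
    kccq_feature_set: str = "sum"
    n_days: int = 14
    lead_days: int = 0

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}")
        if self.fusion == "single" and len(self.modalities) != 1:
            raise ValueError("single-modality fusion needs exactly one modality")
        if self.sfs_k is not None and self.sfs_k < 1:
            raise ValueError("sfs_k must be >= 1 (or None for all features)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


# ---------------------------------------------------------------------------
# logistic regression core


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _nll(z: np.ndarray, y: np.ndarray) -> float:
    # log(1+exp(-s z)) with s = +-1, numerically stable
    s = 2.0 * y - 1.0
    m = -s * z
    return float(np.sum(np.logaddexp(0.0, m)))


def _newton_logistic(X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-9, max_iter: int = 100):
    """Return (coef, intercept) minimizing the L2 logistic objective."""
    n, d = X.shape
    A = np.concatenate([X, np.ones((n, 1))], axis=1)
    lam = np.zeros(d + 1)
    lam[:d] = 1.0 / C
    w = np.zeros(d + 1)
    z = A @ w
    loss = _nll(z, y) + 0.5 * np.sum(lam * w * w)
    for _ in range(max_iter):
        p = _sigmoid(z)
        g = A.T @ (p - y) + lam * w
        if np.max(np.abs(g)) < tol * max(1.0, n):
            break
        r = np.clip(p * (1.0 - p), 1e-10, None)
        H = (A * r[:, None]).T @ A
        H[np.diag_indices_from(H)] += lam
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped update: halve the step until the objective decreases
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            z_new = A @ w_new
            loss_new = _nll(z_new, y) + 0.5 * np.sum(lam * w_new * w_new)
            if loss_new <= loss + 1e-12:
                break
            t *= 0.5
        w, z, loss = w_new, z_new, loss_new
    return w[:d], float(w[d])


@dataclass
class LogisticModel:
    """Fitted standardized L2 logistic classifier."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    C: float = 1.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.scale @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    @property
    def coef_raw(self) -> np.ndarray:
        """Weights on the original (unstandardized) feature scale."""
        return self.coef / self.scale

    @property
    def intercept_raw(self) -> float:
        return float(self.intercept - np.sum(self.coef * self.mean / self.scale))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names=None,
    standardize: bool = True,
    C: float = 1.0,
    warn_constant: bool = True,
) -> LogisticModel:
    """Fit the L2 logistic model on (optionally) z-scored features.

    Constant features are retained but contribute nothing (their standardized
    values are 0); a warning is emitted since they usually indicate an
    upstream problem.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if np.unique(y).size < 2:
        raise ValueError("need both classes to fit the classifier")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    degenerate = scale == 0
    if np.any(degenerate):
        if warn_constant:
            warnings.warn("constant feature(s) dropped from the fit", stacklevel=2)
        scale = np.where(degenerate, 1.0, scale)
    Xs = (X - mean) / scale
    coef, intercept = _newton_logistic(Xs, y, C=C)
    names = tuple(feature_names) if feature_names is not None else tuple(f"x{i}" for i in range(X.shape[1]))
    return LogisticModel(names, mean, scale, coef, intercept, C)


# ---------------------------------------------------------------------------
# metrics


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic with ties averaged."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float((np.sum(ranks[y_true == 1]) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """Threshold-free (AUC, AUCPr) and thresholded confusion metrics."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    auc = auc_score(labels, probs)  # raises on single-class input
    aucpr = float(average_precision_score(labels, probs))
    pred = (probs >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (labels == 1)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    tn = float(np.sum((pred == 0) & (labels == 0)))
    return {
        "accuracy": (tp + tn) / labels.size,
        "AUC": auc,
        "AUCPr": aucpr,
        "PPV": tp / (tp + fp) if tp + fp > 0 else 0.0,
        "TPR": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


# ---------------------------------------------------------------------------
# resampling and feature selection


def undersample_majority(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset: all minority rows plus an
    equal-sized random subset of the majority rows."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling needs both classes present")
    minority = classes[np.argmin(counts)]
    keep_min = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    keep_maj = rng.choice(maj_idx, size=keep_min.size, replace=False)
    return np.sort(np.concatenate([keep_min, keep_maj]))


def _grouped_folds(groups: np.ndarray, n_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    uniq = np.unique(groups)
    n_folds = min(n_folds, uniq.size)
    if n_folds < 2:
        # single participant: fall back to leave-none-out; SFS scores on train
        idx = np.arange(groups.size)
        return [(idx, idx)]
    gkf = GroupKFold(n_splits=n_folds)
    return list(gkf.split(np.zeros(groups.size), groups=groups))


def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    cols: list[int],
    C: float,
    standardize: bool,
) -> float:
    probs = np.full(y.size, np.nan)
    for tr, te in folds:
        y_tr = y[tr]
        if np.unique(y_tr).size < 2:
            continue
        model = fit_logistic(X[np.ix_(tr, cols)], y_tr, standardize=standardize, C=C, warn_constant=False)
        probs[te] = model.predict_proba(X[np.ix_(te, cols)])
    have = ~np.isnan(probs)
    if not np.any(have) or np.unique(y[have]).size < 2:
        return 0.5
    return auc_score(y[have], probs[have])


def sfs_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    feature_names,
    k: int,
    inner_folds: int = 5,
    C: float = 1.0,
    standardize: bool = True,
) -> list[str]:
    """Greedy sequential forward selection of up to ``k`` features.

    The objective is the pooled out-of-fold AUC of the logistic model under a
    participant-grouped inner CV; ties are broken by candidate order (feature
    name order). Deterministic given the training set.
    """
    feature_names = list(feature_names)
    if X.shape[1] == 0:
        raise ValueError("no candidate features")
    k = min(k, X.shape[1])
    folds = _grouped_folds(np.asarray(groups), inner_folds)
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in remaining:
            score = _cv_auc(X, y, folds, selected + [j], C, standardize)
            if score > best_score:  # strict: earlier candidate wins ties
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return [feature_names[j] for j in selected]


# ---------------------------------------------------------------------------
# LOSO cross-validation with fusion


def _inner_loso_probs(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, C: float, standardize: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-level out-of-fold probabilities inside a training set (NaN where
    a left-out participant's complement is single-class).

    Each inner training set is re-undersampled to exact class balance:
    leaving one participant out of an already balanced set leaves a residual
    imbalance opposite to that participant's class mix, and first-level
    models would otherwise encode it as a base-rate shift that
    anti-correlates with the held-out labels, biasing the stacker."""
    probs = np.full(y.size, np.nan)
    for q in np.unique(groups):
        te = groups == q
        tr = np.flatnonzero(~te)
        if np.unique(y[tr]).size < 2:
            continue
        sub = tr[undersample_majority(y[tr], rng)]
        model = fit_logistic(X[sub], y[sub], standardize=standardize, C=C, warn_constant=False)
        probs[te] = model.predict_proba(X[te])
    return probs


def loso_cv(
    features: pd.DataFrame,
    config: ModelConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-subject-out predictions.

    Per fold: majority-undersample the training rows, run SFS per modality,
    fit the configured model form, and predict the held-out participant's
    rows. Returns pooled (probabilities, labels, participant ids) over all
    scored rows. Folds whose training set lacks a class are skipped with a
    warning.
    """
    pids = features["participant_id"].to_numpy()
    y = features["label"].to_numpy(dtype=float)
    cols = win.modality_columns(config.modalities, config.kccq_feature_set)
    Xm = {m: features[c].to_numpy(dtype=float) for m, c in cols.items()}
    participants = np.unique(pids)
    if participants.size < 2:
        raise ValueError("LOSO needs at least two participants")

    out_p, out_y, out_pid = [], [], []
    for fold_i, p in enumerate(participants):
        te = pids == p
        tr = ~te
        if np.unique(y[tr]).size < 2:
            warnings.warn(f"fold for participant {p} skipped: single-class training set", stacklevel=2)
            continue
        rng = np.random.default_rng([seed, fold_i])
        sub = undersample_majority(y[tr], rng)
        tr_idx = np.flatnonzero(tr)[sub]
        y_tr = y[tr_idx]
        g_tr = pids[tr_idx]

        sel: dict[str, list[str]] = {}
        for m in config.modalities:
            names = cols[m]
            if config.sfs_k is None or len(names) <= config.sfs_k:
                sel[m] = list(names)
            else:
                sel[m] = sfs_select(
                    Xm[m][tr_idx], y_tr, g_tr, names, config.sfs_k,
                    config.sfs_inner_folds, config.C, config.standardize,
                )

        def _matrix(m: str, idx) -> np.ndarray:
            j = [cols[m].index(n) for n in sel[m]]
            return Xm[m][np.ix_(idx, j)]

        te_idx = np.flatnonzero(te)
        if config.fusion in ("single", "early"):
            Xtr = np.concatenate([_matrix(m, tr_idx) for m in config.modalities], axis=1)
            Xte = np.concatenate([_matrix(m, te_idx) for m in config.modalities], axis=1)
            model = fit_logistic(
                Xtr, y_tr, [n for m in config.modalities for n in sel[m]],
                config.standardize, config.C, warn_constant=False,
            )
            p_te = model.predict_proba(Xte)
        else:  # late fusion
            first_level = {}
            meta_cols = []
            for m in config.modalities:
                Xtr_m = _matrix(m, tr_idx)
                first_level[m] = fit_logistic(Xtr_m, y_tr, sel[m], config.standardize, config.C, warn_constant=False)
                meta_cols.append(_inner_loso_probs(Xtr_m, y_tr, g_tr, config.C, config.standardize, rng))
            meta_X = np.stack(meta_cols, axis=1)
            have = ~np.isnan(meta_X).any(axis=1)
            meta = fit_logistic(meta_X[have], y_tr[have], list(config.modalities), config.standardize, config.C,
                                warn_constant=False)
            meta_te = np.stack([first_level[m].predict_proba(_matrix(m, te_idx)) for m in config.modalities], axis=1)
            p_te = meta.predict_proba(meta_te)

        out_p.append(p_te)
        out_y.append(y[te_idx])
        out_pid.append(pids[te_idx])
    if not out_p:
        raise ValueError("no LOSO fold could be scored")
    return np.concatenate(out_p), np.concatenate(out_y), np.concatenate(out_pid)


# ---------------------------------------------------------------------------
# repeated experiments and summaries


@dataclass
class MetricsSummary:
    """Mean and SD of each metric over seeded repeats."""

    per_repeat: pd.DataFrame
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {m: float(self.per_repeat[m].mean()) for m in METRIC_NAMES}
        ddof = 1 if len(self.per_repeat) > 1 else 0
        self.sd = {m: float(self.per_repeat[m].std(ddof=ddof)) for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(METRIC_NAMES),
             "mean": [self.mean[m] for m in METRIC_NAMES],
             "sd": [self.sd[m] for m in METRIC_NAMES]}
        )


def repeat_experiment(features: pd.DataFrame, config: ModelConfig) -> MetricsSummary:
    """Run the LOSO pipeline with seeds base_seed .. base_seed+n_repeats-1."""
    rows = []
    for r in range(config.n_repeats):
        probs, labels, _ = loso_cv(features, config, seed=config.base_seed + r)
        metrics = evaluate(probs, labels, config.threshold)
        metrics["seed"] = config.base_seed + r
        rows.append(metrics)
    return MetricsSummary(pd.DataFrame(rows))


def horizon_analysis(
    cohort,
    config: ModelConfig,
    leads: list[int],
    mode: str = "time_to_event",
    fixed_lead: int = 0,
) -> dict[int, MetricsSummary]:
    """Performance as a function of prediction horizon.

    ``time_to_event`` mode uses 1-day windows whose distance to the event is
    swept over ``leads``; ``window_size`` mode sweeps the window length at a
    fixed lead. Only participants contributing a complete-case row at every
    setting (and therefore comparable across settings) are retained.
    """
    if not leads:
        raise ValueError("leads must be nonempty")
    if mode not in ("time_to_event", "window_size"):
        raise ValueError("mode must be 'time_to_event' or 'window_size'")
    settings = [(1, l) for l in leads] if mode == "time_to_event" else [(n, fixed_lead) for n in leads]

    tables: dict[int, pd.DataFrame] = {}
    retained: set | None = None
    for (n_days, lead), key in zip(settings, leads):
        wlist = win.build_windows(cohort.events, n_days=n_days, lead_days=lead)
        table = win.assemble_dataset(cohort, wlist, config.modalities, config.kccq_mode, config.kccq_feature_set)
        complete, _ = win.filter_complete_cases(table, config.modalities)
        tables[key] = complete
        have = set(complete["participant_id"].unique())
        retained = have if retained is None else retained & have

    out: dict[int, MetricsSummary] = {}
    for key in leads:
        table = tables[key]
        table = table.loc[table["participant_id"].isin(retained)].reset_index(drop=True)
        out[key] = repeat_experiment(table, config)
    return out
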