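"""Logistic core, metrics, undersampling, SFS, LOSO CV, and fusion."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

import hfsense.models as M
import hfsense.windows as W


def toy_table(seed=0, n_participants=12, rows_per=8, effects=None):
    """Grouped binary data in the pipeline's feature-table layout.

    ``effects`` maps modality -> signal strength added to its first feature
    for positive rows; remaining features are noise.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    cols = W.modality_columns(("kccq", "motion", "social"))
    rows = []
    for p in range(n_participants):
        for _ in range(rows_per):
            label = int(rng.random() < 0.4)
            row = {"participant_id": f"P{p:02d}", "label": label}
            for m, names in cols.items():
                for j, c in enumerate(names):
                    bump = effects.get(m, 0.0) if j == 0 and label else 0.0
                    row[c] = rng.normal() + bump
                row[f"has_{m}"] = True
            rows.append(row)
    return pd.DataFrame(rows)


class TestLogisticCore:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 4))
        y = (X @ rng.normal(size=4) + 0.3 * rng.normal(size=120) > 0).astype(float)
        model = M.fit_logistic(X, y, standardize=False)
        ref = LogisticRegression(C=1.0, tol=1e-10, max_iter=5000).fit(X, y)
        assert np.allclose(model.coef, ref.coef_[0], atol=1e-4)
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)
        assert np.allclose(model.predict_proba(X), ref.predict_proba(X)[:, 1], atol=1e-5)

    def test_separable_toy_perfect_training_auc(self):
        X = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        y = np.concatenate([np.zeros(10), np.ones(10)])
        model = M.fit_logistic(X, y)
        assert M.auc_score(y, model.predict_proba(X)) == 1.0

    def test_null_coefficients_shrink(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 3))
        y = (rng.random(4000) < 0.5).astype(float)
        model = M.fit_logistic(X, y)
        assert np.max(np.abs(model.coef)) < 0.1

    def test_probabilities_in_open_interval(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        y = (rng.random(50) < 0.5).astype(float)
        p = M.fit_logistic(X, y).predict_proba(X)
        assert np.all((p > 0) & (p < 1))

    def test_constant_feature_warns_and_is_inert(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=40), np.full(40, 7.0)])
        y = (X[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            model = M.fit_logistic(X, y)
        assert model.coef[1] == pytest.approx(0.0, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            M.fit_logistic(np.zeros((5, 1)), np.ones(5))


class TestMetrics:
    def test_auc_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = (rng.random(60) < 0.4).astype(float)
            if y.sum() in (0, 60):
                continue
            s = np.round(rng.random(60), 1)  # coarse scores force ties
            assert M.auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_perfect_separation(self):
        m = M.evaluate(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert m["AUC"] == 1.0 and m["AUCPr"] == 1.0 and m["PPV"] == 1.0

    def test_confusion_arithmetic(self):
        # TP=3 FP=1 FN=2 TN=4
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.4, 0.1])
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        m = M.evaluate(probs, labels)
        assert m["PPV"] == pytest.approx(0.75)
        assert m["TPR"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        y = (rng.random(1000) < 0.3).astype(float)
        m = M.evaluate(rng.random(1000), y)
        assert abs(m["AUC"] - 0.5) < 0.05

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            M.evaluate(np.array([0.3, 0.6]), np.array([1, 1]))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = (rng.random(200) < 0.4).astype(float)
        p = rng.random(200)
        assert M.auc_score(y, p) == pytest.approx(M.auc_score(y, np.exp(3 * p)), abs=1e-12)


class TestUndersampling:
    def test_balances_to_minority_size(self):
        y = np.array([0] * 10 + [1] * 4)
        idx = M.undersample_majority(y, np.random.default_rng(0))
        assert idx.size == 8
        assert y[idx].sum() == 4

    def test_balanced_input_unchanged(self):
        y = np.array([0, 1, 0, 1])
        idx = M.undersample_majority(y, np.random.default_rng(0))
        assert sorted(idx) == [0, 1, 2, 3]

    def test_seeds_vary_subset_not_counts(self):
        y = np.array([0] * 20 + [1] * 5)
        a = M.undersample_majority(y, np.random.default_rng(1))
        b = M.undersample_majority(y, np.random.default_rng(2))
        assert a.size == b.size == 10
        assert y[a].sum() == y[b].sum() == 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            M.undersample_majority(np.ones(6), np.random.default_rng(0))


class TestSFS:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(7)
        y = (rng.random(60) < 0.5).astype(float)
        X = rng.normal(size=(60, 4))
        X[:, 2] = y * 2 - 1  # separates perfectly
        groups = np.repeat(np.arange(6), 10)
        names = ["a", "b", "winner", "d"]
        sel = M.sfs_select(X, y, groups, names, k=2)
        assert sel[0] == "winner"

    def test_k_equals_candidates_returns_all(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(float)
        groups = np.repeat(np.arange(4), 10)
        assert sorted(M.sfs_select(X, y, groups, ["a", "b", "c"], k=3)) == ["a", "b", "c"]

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            M.sfs_select(np.empty((10, 0)), np.zeros(10), np.zeros(10), [], k=1)


class TestLoso:
    def test_all_rows_scored_once(self):
        table = toy_table(seed=10)
        cfg = M.ModelConfig(modalities=("social",), fusion="single", n_repeats=1)
        probs, labels, pids = M.loso_cv(table, cfg, seed=0)
        assert probs.size == len(table)
        assert sorted(pids) == sorted(table["participant_id"])

    def test_leakage_guard_mutating_heldout_labels(self):
        """Flipping one participant's labels must not change that fold's predictions."""
        table = toy_table(seed=11, effects={"social": 1.0})
        cfg = M.ModelConfig(modalities=("social",), fusion="single", n_repeats=1)
        probs, _, pids = M.loso_cv(table, cfg, seed=3)
        victim = table["participant_id"].iloc[0]
        mutated = table.copy()
        mask = mutated["participant_id"] == victim
        mutated.loc[mask, "label"] = 1 - mutated.loc[mask, "label"]
        probs2, _, pids2 = M.loso_cv(mutated, cfg, seed=3)
        assert np.array_equal(probs[pids == victim], probs2[pids2 == victim])

    def test_late_fusion_tracks_informative_modality(self):
        table = toy_table(seed=12, n_participants=14, effects={"kccq": 2.5})
        single = M.ModelConfig(modalities=("kccq",), fusion="single")
        late = M.ModelConfig(modalities=("kccq", "motion", "social"), fusion="late")
        auc_single = np.mean([M.evaluate(*M.loso_cv(table, single, s)[:2])["AUC"] for s in range(5)])
        auc_late = np.mean([M.evaluate(*M.loso_cv(table, late, s)[:2])["AUC"] for s in range(5)])
        assert auc_late >= auc_single - 0.05

    def test_early_fusion_single_modality_equals_single(self):
        table = toy_table(seed=13, effects={"social": 1.0})
        single = M.ModelConfig(modalities=("social",), fusion="single")
        early = M.ModelConfig(modalities=("social",), fusion="early")
        ps, _, _ = M.loso_cv(table, single, 1)
        pe, _, _ = M.loso_cv(table, early, 1)
        assert np.array_equal(ps, pe)

    def test_two_participants_minimum(self):
        table = toy_table(seed=14, n_participants=1)
        with pytest.raises(ValueError):
            M.loso_cv(table, M.ModelConfig(modalities=("social",), fusion="single"), 0)


class TestRepeats:
    def test_single_repeat_sd_zero(self):
        table = toy_table(seed=15)
        cfg = M.ModelConfig(modalities=("social",), fusion="single", n_repeats=1)
        s = M.repeat_experiment(table, cfg)
        assert all(v == 0.0 for v in s.sd.values())

    def test_identical_base_seed_identical_summary(self):
        table = toy_table(seed=16)
        cfg = M.ModelConfig(modalities=("social",), fusion="single", n_repeats=3, base_seed=9)
        a, b = M.repeat_experiment(table, cfg), M.repeat_experiment(table, cfg)
        assert a.mean == b.mean and a.sd == b.sd


class TestHorizon:
    def test_one_summary_per_lead_and_common_retention(self, small_cohort):
        cfg = M.ModelConfig(modalities=("social",), fusion="single", n_repeats=2)
        leads = [1, 2, 4, 6]
        out = M.horizon_analysis(small_cohort, cfg, leads)
        assert sorted(out) == leads
        assert all(isinstance(v, M.MetricsSummary) for v in out.values())

    def test_empty_leads_rejected(self, small_cohort):
        cfg = M.ModelConfig(modalities=("social",), fusion="single")
        with pytest.raises(ValueError):
            M.horizon_analysis(small_cohort, cfg, [])
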