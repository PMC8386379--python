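"""Complete cases, imputation, elastic-net fit and grouped CV."""

import numpy as np
import pandas as pd
import pytest

from phenoweek.config import ElasticNetSpec
from phenoweek.model import (
    complete_cases,
    fit_elasticnet_logistic,
    grouped_cv_auc,
    impute_within_participant,
    roc_auc,
)
from phenoweek.registry import FEATURE_NAMES
from phenoweek.simulate import simulate_feature_matrix
from phenoweek import CohortConfig


def toy_matrix(n=10, seed=0, missing_rows=()):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.normal(size=n) for name in FEATURE_NAMES})
    df.insert(0, "participant_id", [f"P{i%3}" for i in range(n)])
    df.insert(1, "week_index", range(n))
    df["phq9_sum"] = rng.integers(0, 28, n).astype(float)
    for i in missing_rows:
        df.loc[i, FEATURE_NAMES[i % 34]] = np.nan
    df["depressed_week"] = (df["phq9_sum"] >= 10).astype(float)
    return df


class TestCompleteCases:
    def test_no_missingness_is_identity(self):
        df = toy_matrix()
        pd.testing.assert_frame_equal(complete_cases(df), df)

    def test_any_missing_cell_drops_row(self):
        df = toy_matrix(missing_rows=(0, 4, 7))
        cc = complete_cases(df)
        assert len(cc) == 7
        assert set(cc["week_index"]) == set(range(10)) - {0, 4, 7}

    def test_missing_phq9_drops_row(self):
        df = toy_matrix()
        df.loc[2, "phq9_sum"] = np.nan
        assert len(complete_cases(df)) == 9


class TestImputation:
    def participant_frame(self, values):
        df = toy_matrix(n=len(values), seed=1)
        df["participant_id"] = "P0"
        df["battery_percentage"] = values
        return df

    def test_missing_cell_gets_participant_mean(self):
        df = self.participant_frame([2.0, np.nan, 4.0])
        imp = impute_within_participant(df)
        assert imp["battery_percentage"].tolist() == [2.0, 3.0, 4.0]

    def test_feature_missing_all_weeks_cannot_be_recovered(self):
        df = self.participant_frame([np.nan, np.nan, np.nan])
        assert len(impute_within_participant(df)) == 0

    def test_observed_cells_never_change(self):
        df = toy_matrix(n=12, seed=2, missing_rows=(1, 5))
        imp = impute_within_participant(df)
        merged = imp.merge(df, on=["participant_id", "week_index"], suffixes=("_imp", "_raw"))
        for name in FEATURE_NAMES:
            raw = merged[f"{name}_raw"]
            got = merged[f"{name}_imp"]
            ok = raw.notna()
            assert np.allclose(got[ok], raw[ok])

    def test_imputed_rowcount_at_least_complete_case(self):
        cfg = CohortConfig(n_participants=25, n_weeks=6, seed=31)
        m = simulate_feature_matrix(cfg)
        assert len(impute_within_participant(m)) >= len(complete_cases(m))


class TestElasticNetFit:
    def test_separable_limit_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(-2, 0.3, (40, 2)), rng.normal(2, 0.3, (40, 2))]
        y = np.r_[np.zeros(40), np.ones(40)]
        X = (X - X.mean(0)) / X.std(0)
        model = fit_elasticnet_logistic(X, y, ElasticNetSpec(C=1e6))
        assert roc_auc(model.decision(X), y) == 1.0

    def test_heavy_l1_shrinks_to_intercept_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 5))
        y = (rng.random(300) < 0.25).astype(float)
        model = fit_elasticnet_logistic(X, y, ElasticNetSpec(C=1e-4, l1_ratio=1.0))
        assert np.allclose(model.coefficients, 0.0)
        base = y.mean()
        assert model.intercept == pytest.approx(np.log(base / (1 - base)), abs=0.05)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_elasticnet_logistic(X, np.ones(10))

    def test_returned_optimum_beats_random_perturbations(self):
        """Local-optimality probe of the penalized objective."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        beta_true = np.array([1.0, -1.0, 0.5, 0.0, 0.0, 0.0])
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        X = (X - X.mean(0)) / X.std(0)
        spec = ElasticNetSpec(C=1.0, l1_ratio=0.5, tol=1e-10, max_iter=20000)
        model = fit_elasticnet_logistic(X, y, spec)

        def objective(b0, b):
            loss = np.logaddexp(0.0, -(2 * y - 1) * (b0 + X @ b)).sum()
            penalty = (1 / spec.C) * (
                spec.l1_ratio * np.abs(b).sum() + (1 - spec.l1_ratio) / 2 * (b * b).sum()
            )
            return loss + penalty

        best = objective(model.intercept, model.coefficients)
        for _ in range(1000):
            d0 = rng.normal(0, 1e-3)
            db = rng.normal(0, 1e-3, size=6)
            assert objective(model.intercept + d0, model.coefficients + db) >= best - 1e-9


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_counted_pairs(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = np.round(rng.normal(size=50), 1)  # rounding forces ties
            labels = (rng.random(50) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.5).astype(int)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(a)


class TestGroupedCV:
    def cohort(self, seed=0, effects=None, n=40, weeks=6):
        kwargs = {} if effects is None else {"effect_sizes": effects}
        cfg = CohortConfig(n_participants=n, n_weeks=weeks, seed=seed, **kwargs)
        return complete_cases(simulate_feature_matrix(cfg))

    def test_no_participant_in_both_train_and_test(self):
        df = self.cohort(seed=10)
        cv = grouped_cv_auc(df, n_folds=10, seed=3)
        folds = pd.Series(cv.fold_assignment)
        assert folds.index.nunique() == len(folds)  # one fold per participant
        assert set(folds.unique()) <= set(range(10))
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1  # near-equal folds

    def test_oracle_feature_gives_auc_one_every_fold(self):
        df = self.cohort(seed=11)
        df["battery_percentage"] = df["depressed_week"] * 10.0
        cv = grouped_cv_auc(df, n_folds=10, seed=4)
        assert all(a == 1.0 for a in cv.fold_aucs)

    def test_mean_sd_recomputable_from_folds(self):
        df = self.cohort(seed=12)
        cv = grouped_cv_auc(df, n_folds=10, seed=5)
        assert cv.mean_auc == pytest.approx(np.mean(cv.fold_aucs))
        assert cv.sd_auc == pytest.approx(np.std(cv.fold_aucs, ddof=1))

    def test_too_few_participants_rejected(self):
        df = self.cohort(seed=13, n=5, weeks=4)
        with pytest.raises(ValueError):
            grouped_cv_auc(df, n_folds=10)

    def test_label_permuted_cohort_scores_near_chance(self):
        cfg = CohortConfig(n_participants=100, n_weeks=6, seed=601)
        df = complete_cases(simulate_feature_matrix(cfg, apply_missingness=False))
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(6):
            perm = df.copy()
            perm["depressed_week"] = rng.permutation(perm["depressed_week"].to_numpy())
            aucs.append(grouped_cv_auc(perm, n_folds=10, seed=seed).mean_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)
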