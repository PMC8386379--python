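"""Multivariate depressed-week model: elastic-net logistic regression
with participant-grouped cross-validation.

Weeks are complete cases when all 34 features and the PHQ-9 are present;
an alternative path recovers weeks by within-participant mean imputation
(a participant's missing feature-week is replaced by the mean of their
observed weeks for that feature; weeks that stay incomplete are dropped).
Features are standardized, the penalized model is fit with C (inverse
regularization) and elastic-net mixing rho, and performance is the ROC
AUC over 10 participant-grouped folds: all of a participant's weeks land
in the same fold, so no individual contributes to both training and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .config import ElasticNetSpec
from .registry import FEATURE_NAMES

__all__ = [
    "FittedModel",
    "CVReport",
    "complete_cases",
    "impute_within_participant",
    "fit_elasticnet_logistic",
    "roc_auc",
    "grouped_cv_auc",
]


@dataclass
class FittedModel:
    intercept: float
    coefficients: np.ndarray
    converged: bool

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.decision(X))


@dataclass
class CVReport:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    fold_assignment: dict[str, int]
    n_rows: int
    n_participants: int
    excluded_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "n_rows": int(self.n_rows),
            "n_participants": int(self.n_participants),
            "excluded_folds": list(self.excluded_folds),
            "fold_assignment": {str(k): int(v) for k, v in self.fold_assignment.items()},
        }


def complete_cases(table: pd.DataFrame, features: tuple[str, ...] = FEATURE_NAMES) -> pd.DataFrame:
    """Rows where every feature and the PHQ-9 sum are present."""
    return table.dropna(subset=list(features) + ["phq9_sum"]).reset_index(drop=True)


def impute_within_participant(
    table: pd.DataFrame, features: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Within-participant mean imputation, then drop still-incomplete rows.

    Observed cells are never altered; a feature missing in *all* of a
    participant's weeks cannot be imputed this way, so those weeks drop
    out if the gap remains.  Weeks without a PHQ-9 are dropped (the label
    cannot be imputed).
    """
    out = table.copy()
    cols = list(features)
    out[cols] = out.groupby("participant_id")[cols].transform(lambda s: s.fillna(s.mean()))
    return complete_cases(out, features)


def fit_elasticnet_logistic(X: np.ndarray, y: np.ndarray, spec: ElasticNetSpec | None = None) -> FittedModel:
    """Fit the penalized logistic model on standardized features.

    Minimizes the logistic loss plus (1/C) * [rho * ||b||_1 +
    (1 - rho)/2 * ||b||_2^2] with an unpenalized intercept (saga solver,
    fixed seed, deterministic for fixed input).
    """
    spec = spec or ElasticNetSpec()
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit the model")
    if np.isnan(X).any():
        raise ValueError("X must have no missing cells")
    clf = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        C=spec.C,
        l1_ratio=spec.l1_ratio,
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return FittedModel(
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].copy(),
        converged=bool(clf.n_iter_[0] < spec.max_iter),
    )


def roc_auc(scores, labels) -> float:
    """ROC AUC in the Mann-Whitney form P(s+ > s-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def grouped_cv_auc(
    table: pd.DataFrame,
    spec: ElasticNetSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> CVReport:
    """Participant-grouped cross-validated ROC AUC.

    Participants are randomly split (seeded) into ``n_folds`` near-equal
    folds.  Per fold, standardization parameters and the model are fit on
    training rows only and evaluated on the held-out rows.  A test fold
    holding a single class has no defined AUC; it is excluded from the
    mean/SD with a warning.
    """
    spec = spec or ElasticNetSpec()
    pids = np.asarray(sorted(table["participant_id"].unique()))
    if pids.size < n_folds:
        raise ValueError(f"need at least {n_folds} participants, got {pids.size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pids.size)
    folds = np.array_split(order, n_folds)
    assignment = {str(pids[i]): k for k, fold in enumerate(folds) for i in fold}

    X_all = table[list(features)].to_numpy(dtype=float)
    y_all = table["depressed_week"].to_numpy(dtype=float)
    fold_of_row = table["participant_id"].map(assignment).to_numpy()

    aucs: list[float] = []
    excluded: list[int] = []
    for k in range(n_folds):
        test = fold_of_row == k
        train = ~test
        if not test.any():
            excluded.append(k)
            continue
        if np.unique(y_all[test]).size < 2:
            warnings.warn(f"fold {k} test labels are single-class; AUC undefined, excluded")
            excluded.append(k)
            continue
        scaler = StandardScaler().fit(X_all[train])
        model = fit_elasticnet_logistic(scaler.transform(X_all[train]), y_all[train], spec)
        scores = model.decision(scaler.transform(X_all[test]))
        aucs.append(roc_auc(scores, y_all[test]))
    arr = np.asarray(aucs, dtype=float)
    return CVReport(
        fold_aucs=aucs,
        mean_auc=float(arr.mean()) if arr.size else float("nan"),
        sd_auc=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        fold_assignment=assignment,
        n_rows=int(len(table)),
        n_participants=int(pids.size),
        excluded_folds=excluded,
    )
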