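"""Univariate screen: pairwise Spearman correlations with weekly PHQ-9
and Benjamini-Hochberg adjustment across the 34 tests.

Each feature is correlated with the PHQ-9 sum over all participant-weeks
where both are available (pairwise-complete); repeated weeks per
participant are pooled, so the correlations describe population-level
association, not within-person change.  P values use the large-sample t
approximation (an exact permutation option exists for tiny n); the 34 raw
P values are adjusted with the step-up false-discovery-rate procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .registry import FEATURE_NAMES

__all__ = [
    "ScreenResult",
    "spearman_correlation",
    "spearman_screen",
    "bh_adjust",
    "significant_features",
]

MIN_PAIRS = 3


@dataclass
class ScreenResult:
    feature_name: str
    spearman_r: float
    p_raw: float
    p_adjusted: float
    n_weeks: int
    n_participants: int
    defined: bool


def spearman_correlation(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman r and two-sided p over pairwise-complete observations.

    ``exact=True`` enumerates all rank permutations (only sensible for
    n < 10) and returns the exact two-sided permutation p for |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < MIN_PAIRS or np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(r)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rp = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(rp) >= obs - 1e-12
            total += 1
        p = count / total
    return float(r), float(p)


def spearman_screen(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    outcome: str = "phq9_sum",
) -> pd.DataFrame:
    """Per-feature Spearman r against the outcome, with BH adjustment.

    Returns one row per feature in registry order with columns
    ``spearman_r``, ``p_raw``, ``p_adjusted``, ``n_weeks``,
    ``n_participants`` and ``defined``.  Features with fewer than three
    complete pairs (or a constant column) are flagged undefined and
    excluded from the adjustment.
    """
    y = table[outcome].to_numpy(dtype=float)
    rows = []
    for name in features:
        x = table[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        r, p = spearman_correlation(x, y)
        n_participants = table.loc[ok, "participant_id"].nunique() if "participant_id" in table else int(ok.sum())
        rows.append(
            {
                "feature": name,
                "spearman_r": r,
                "p_raw": p,
                "n_weeks": int(ok.sum()),
                "n_participants": int(n_participants),
                "defined": not np.isnan(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    defined = out["defined"].to_numpy()
    if defined.any():
        out.loc[defined, "p_adjusted"] = bh_adjust(out.loc[defined, "p_raw"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg (nonnegative) step-up adjusted p values.

    q(i) = min_{j >= i} p(j) * m / j over the ascending order, capped at
    1, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_features(screen: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Features with adjusted p < alpha, ordered by |r| descending."""
    sel = screen[screen["defined"] & (screen["p_adjusted"] < alpha)].copy()
    sel["abs_r"] = sel["spearman_r"].abs()
    sel = sel.sort_values(["abs_r", "feature"], ascending=[False, True], kind="stable")
    return sel.drop(columns="abs_r").reset_index(drop=True)
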