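"""Completion-normalized linear trends of the cluster indices.

Participants reach exhaustion after different numbers of sets, so set
position is expressed as a percentage of completion, ``100 * i / (S - 1)``
for set ``i`` of ``S`` (the last set, at complete fatigue, maps to 100%).
Index values are z-scored within each participant's series first, so that
participants with different index ranges contribute on a common scale.

For each (exercise, index) cell, the standardized values of all participants
are pooled and regressed on completion percentage by ordinary least squares;
the slope's two-sided t-test p-value is compared with a significance level
alpha (default 0.05).  With K cross-validation folds this yields
K x 4 exercises x 4 indices fold-level regressions per model variant (64 at
K = 4), summarized as the count of significant slopes ("p-value counter");
averaging each participant's index values across the K folds first gives the
4 x 4 = 16 "ensemble" regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .latent_eval import INDEX_NAMES

ALPHA = 0.05


@dataclass
class TrendResult:
    """One index-vs-completion ordinary-least-squares fit."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n_points: int


def completion_percentage(set_index: int, total_sets: int) -> float:
    """Set position as percent of completion: 100 * i / (S - 1)."""
    if total_sets < 2:
        raise ValueError("completion percentage needs >= 2 sets")
    if not 0 <= set_index < total_sets:
        raise ValueError("set_index out of range")
    return 100.0 * set_index / (total_sets - 1)


def standardize_per_participant(indices: pd.DataFrame) -> pd.DataFrame:
    """Z-score index values within each participant's series.

    A series is one (variant, fold, participant, exercise, index) group.
    Flagged-missing rows are dropped first; zero-variance series are dropped
    with a warning.
    """
    df = indices[~indices["missing"]].copy() if "missing" in indices.columns else indices.copy()
    keys = [k for k in ("variant", "fold", "participant", "exercise", "index")
            if k in df.columns]
    out = []
    for key, g in df.groupby(keys, dropna=False):
        v = g["value"].to_numpy(dtype=float)
        if len(v) < 2:
            continue
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"zero-variance index series {key}; dropped")
            continue
        g = g.copy()
        g["value"] = (v - v.mean()) / sd
        out.append(g)
    if not out:
        return df.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def fit_trend(x: np.ndarray, y: np.ndarray) -> TrendResult:
    """OLS of standardized index values on completion percentage."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("fit_trend requires >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("completion percentages are constant")
    res = linregress(x, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                       n_points=len(x))


def add_completion(indices: pd.DataFrame) -> pd.DataFrame:
    """Attach the completion percentage of each row's set.

    The total number of sets of each (participant, exercise) is taken from
    the ellipse-area rows, which exist for every set.
    """
    df = indices.copy()
    totals = (df.groupby(["participant", "exercise"])["set"].max() + 1).to_dict()
    df["completion"] = [
        completion_percentage(int(s), int(totals[(p, e)]))
        for p, e, s in zip(df["participant"], df["exercise"], df["set"])
    ]
    return df


def trend_table(std_indices: pd.DataFrame) -> pd.DataFrame:
    """Fold-level regressions: one row per (variant, fold, exercise, index).

    Values are pooled over participants within each cell; regressions never
    mix exercises or indices.
    """
    df = add_completion(std_indices)
    keys = [k for k in ("variant", "fold") if k in df.columns]
    rows = []
    for key, g in df.groupby(keys + ["exercise", "index"], dropna=False):
        key = dict(zip(keys + ["exercise", "index"], key))
        try:
            t = fit_trend(g["completion"], g["value"])
        except ValueError as e:
            rows.append({**key, "slope": np.nan, "intercept": np.nan, "r2": np.nan,
                         "p_value": np.nan, "n_points": len(g), "error": str(e)})
            continue
        rows.append({**key, "slope": t.slope, "intercept": t.intercept, "r2": t.r2,
                     "p_value": t.p_value, "n_points": t.n_points, "error": ""})
    return pd.DataFrame(rows)


def ensemble_table(std_indices: pd.DataFrame) -> pd.DataFrame:
    """Ensemble regressions: index values averaged across folds first.

    Each (participant, exercise, set, index) value is the mean of that cell
    over the K folds, giving 4 exercises x 4 indices regressions per variant.
    """
    df = std_indices.copy()
    keys = [k for k in ("variant",) if k in df.columns]
    mean_df = (df.groupby(keys + ["participant", "exercise", "set", "index"],
                          dropna=False)["value"].mean().reset_index())
    mean_df["missing"] = False
    out = trend_table(mean_df)
    out.insert(len(keys), "fold", "ensemble")
    return out


def assessment(trends: pd.DataFrame, ensemble: pd.DataFrame,
               alpha: float = ALPHA) -> pd.DataFrame:
    """Significance counts per variant: fold-level counter and ensemble.

    With K folds the counter is out of K x 4 exercises x 4 indices (64 at
    K = 4); the ensemble count is out of 16.  Cells whose regression failed
    are reported as missing, not counted as significant.
    """
    rows = []
    variants = trends["variant"].unique() if "variant" in trends.columns else [None]
    for variant in variants:
        t = trends if variant is None else trends[trends["variant"] == variant]
        e = ensemble if variant is None else ensemble[ensemble["variant"] == variant]
        rows.append({
            "variant": variant,
            "p_value_counter": int((t["p_value"] < alpha).sum()),
            "counter_total": len(t),
            "counter_missing": int(t["p_value"].isna().sum()),
            "p_value_ensemble": int((e["p_value"] < alpha).sum()),
            "ensemble_total": len(e),
            "ensemble_missing": int(e["p_value"].isna().sum()),
        })
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """BH step-up rejection mask (optional correction, off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask
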