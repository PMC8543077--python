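"""Distributional comparisons of factor scores: quantile gaps, KS tests,
bootstrap intervals and covariate gap tables.

Because intercept invariance fails across cohorts, every statistic here is
location-free (quantile differences, variances, within-group contrasts,
shape tests): adding a constant to one group's scores changes nothing.
Cross-cohort *mean* levels are never reported.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .scoring import ScoreSet

__all__ = [
    "DEFAULT_QUANTILE_PAIRS",
    "quantile_gaps",
    "bootstrap_ci",
    "ks_between",
    "group_gap_table",
]

DEFAULT_QUANTILE_PAIRS: tuple[tuple[int, int], ...] = (
    (90, 10),
    (75, 25),
    (50, 10),
    (90, 50),
)


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, ScoreSet):
        return scores.data[scores.data["converged"]]
    return scores


def quantile_gaps(
    scores,
    pairs: Sequence[tuple[int, int]] = DEFAULT_QUANTILE_PAIRS,
    factors: Sequence[str] = ("ext", "int"),
    min_n: int = 50,
) -> pd.DataFrame:
    """Sample-quantile differences (and the variance) per group and skill.

    Quantiles use the linear-interpolation convention.  Returns a tidy frame
    with columns group, skill, statistic, value.
    """
    df = _scores_frame(scores)
    for hi, lo in pairs:
        for q in (hi, lo):
            if not 0 < q < 100:
                raise ValueError(f"quantile {q} outside (0, 100)")
    rows = []
    for g, sub in df.groupby("group", sort=False):
        for f in factors:
            y = sub[f].dropna().to_numpy()
            if len(y) < min_n:
                raise ValueError(
                    f"group {g!r} has {len(y)} scores < floor {min_n}"
                )
            for hi, lo in pairs:
                gap = float(
                    np.quantile(y, hi / 100.0) - np.quantile(y, lo / 100.0)
                )
                rows.append(
                    {"group": g, "skill": f, "statistic": f"q{hi}-q{lo}",
                     "value": gap}
                )
            rows.append(
                {"group": g, "skill": f, "statistic": "variance",
                 "value": float(np.var(y, ddof=1))}
            )
    return pd.DataFrame(rows)


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    group_col: str = "group",
    alpha: float = 0.05,
    refit: Callable[[pd.DataFrame, np.random.Generator], pd.DataFrame] | None = None,
    max_failed_frac: float = 0.01,
) -> dict:
    """Percentile bootstrap interval, resampling children within group.

    ``refit`` optionally re-runs an estimation stage (e.g. the factor model)
    on each resampled panel before the statistic is evaluated; by default
    the statistic is applied directly to the resampled rows.  Replicates on
    which the statistic fails are dropped and counted; more than
    ``max_failed_frac`` failures is an error.  Deterministic given the seed.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    groups = {g: sub.index.to_numpy() for g, sub in data.groupby(group_col, sort=False)}
    draws = []
    failed = 0
    for _ in range(B):
        idx = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in groups.values()]
        )
        boot = data.loc[idx]
        try:
            if refit is not None:
                boot = refit(boot, rng)
            draws.append(statistic(boot))
        except Exception:
            failed += 1
    if failed > max_failed_frac * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return {
        "estimate": float(statistic(data)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "se": float(draws.std(ddof=1)),
        "draws": draws,
        "n_failed": failed,
    }


def ks_between(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and p-value.

    Asymptotic p by default; with fewer than 10 observations on either side
    the exact small-sample distribution is used (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "asymp"
    if min(len(a), len(b)) < 10:
        warnings.warn("small sample: using exact KS distribution", stacklevel=2)
        method = "exact"
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def group_gap_table(
    scores,
    panel_data: pd.DataFrame,
    covariate: str,
    reference_category,
    factors: Sequence[str] = ("ext", "int"),
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-group mean-score gaps by covariate category, reference at zero.

    For each group and skill, reports mean(score | category) minus
    mean(score | reference category) with a percentile bootstrap interval.
    Normalising to the reference category removes the (non-comparable)
    cross-cohort location, so only gradients are compared across cohorts.
    """
    df = (
        _scores_frame(scores)
        .drop(columns=[covariate], errors="ignore")
        .merge(panel_data[["child_id", covariate]], on="child_id", how="left")
    )
    rng = np.random.default_rng(seed)
    rows = []
    for g, sub in df.groupby("group", sort=False):
        cats = sub[covariate].dropna().unique()
        if reference_category not in cats:
            raise ValueError(
                f"reference category {reference_category!r} absent in group {g!r}"
            )
        for f in factors:
            ref_vals = sub.loc[sub[covariate] == reference_category, f].to_numpy()
            for cat in sorted(cats, key=str):
                vals = sub.loc[sub[covariate] == cat, f].to_numpy()
                gap = float(vals.mean() - ref_vals.mean())
                if cat == reference_category:
                    rows.append(
                        {"group": g, "skill": f, "category": cat, "gap": 0.0,
                         "ci_low": 0.0, "ci_high": 0.0, "n": len(vals)}
                    )
                    continue
                boots = np.empty(B)
                for b in range(B):
                    rv = rng.choice(ref_vals, size=len(ref_vals), replace=True)
                    cv = rng.choice(vals, size=len(vals), replace=True)
                    boots[b] = cv.mean() - rv.mean()
                lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
                rows.append(
                    {"group": g, "skill": f, "category": cat, "gap": gap,
                     "ci_low": float(lo), "ci_high": float(hi), "n": len(vals)}
                )
    return pd.DataFrame(rows)
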