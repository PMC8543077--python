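"""Approximate fit indices, delta-AFI comparisons and the invariance decision.

Chi-squared difference tests are known to reject trivial misspecification at
cohort-study sample sizes, so the invariance decision rests on changes in
approximate fit indices (AFIs) relative to the configural model.  The default
cutoff set combines the classic continuous-case rules (reject when
dCFI < -.010, dRMSEA > .015, dSRMR > .010) with the stricter categorical-case
dRMSEA > .010 rule recommended for large samples; every cutoff lives in
configuration, never in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .items import ItemPanel, REFERENCE_GROUP
from .mgcfa import (
    LEVELS,
    OrdinalFactorModel,
    OrdinalFactorResults,
    build_model,
    fit_baseline,
    scaled_difference,
)
from .polychoric import SampleMoments, sample_moments

__all__ = [
    "AFI_NAMES",
    "DEFAULT_CUTOFFS",
    "afi",
    "compare_nested",
    "InvarianceLadder",
    "run_ladder",
]

AFI_NAMES = ("cfi", "tli", "rmsea", "srmr", "mfi", "gamma_hat")

#: default rejection rules on (AFI at level) - (AFI at configural);
#: rmsea_categorical is the large-sample categorical-measurement rule.
DEFAULT_CUTOFFS: dict[str, float] = {
    "cfi": -0.010,        # reject if dCFI <= cutoff
    "rmsea": 0.015,       # reject if dRMSEA >= cutoff
    "rmsea_categorical": 0.010,
    "srmr": 0.010,        # reject if dSRMR >= cutoff
}


def _srmr(fit: OrdinalFactorResults, bias_correct: bool = True) -> float:
    """Root mean squared residual over thresholds and correlations.

    By default each squared residual is reduced by its sampling variance
    (diagonal of the asymptotic covariance over n).  The naive index has a
    noise floor of order sqrt(p/n) that attenuates differences between
    nested models at moderate sample sizes; the corrected version estimates
    the population root mean squared residual.
    """
    implied = fit.implied()
    resid = np.concatenate(
        [
            fit.model.moments[g].stack() - np.concatenate(implied[g])
            for g in fit.spec.groups
        ]
    )
    sq = resid**2
    if bias_correct:
        sq = sq - fit._robust_quantities()["resid_var"]
    return float(np.sqrt(max(float(sq.sum()), 0.0) / len(sq)))


def afi(
    fit: OrdinalFactorResults, baseline: OrdinalFactorResults
) -> dict[str, float]:
    """CFI, TLI, RMSEA (+90% CI), SRMR, McDonald NCI, Gamma-hat.

    Computed from the scaled (mean-and-variance-adjusted) statistics; the
    baseline is the per-group independence model on the same moments.
    CFI/TLI are flagged missing (NaN) when the baseline statistic does not
    exceed its df.
    """
    T, df = fit.scaled_statistic, fit.scaled_df
    Tb, dfb = baseline.scaled_statistic, baseline.scaled_df
    n = fit.n_total
    p = len(fit.spec.items)
    ncy = max(T - df, 0.0)
    ncb = max(Tb - dfb, 0.0)
    out: dict[str, float] = {}
    if ncb <= 0 and ncy <= 0:
        out["cfi"] = 1.0
        out["tli"] = 1.0
    elif Tb <= dfb:
        out["cfi"] = float("nan")
        out["tli"] = float("nan")
    else:
        out["cfi"] = 1.0 - ncy / max(ncb, ncy)
        out["tli"] = ((Tb / dfb) - (T / df)) / max((Tb / dfb) - 1.0, 1e-12) if df > 0 else 1.0
    out["rmsea"] = float(np.sqrt(ncy / (df * (n - 1)))) if df > 0 else 0.0
    out["rmsea_ci"] = _rmsea_ci(T, df, n)
    out["srmr"] = _srmr(fit)
    out["mfi"] = float(np.exp(-0.5 * ncy / n))
    out["gamma_hat"] = p / (p + 2.0 * ncy / n)
    return out


def _rmsea_ci(T: float, df: float, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% confidence interval for RMSEA by noncentral chi-squared inversion."""
    from scipy.stats import ncx2, chi2

    if df <= 0:
        return (0.0, 0.0)
    alpha = (1.0 - level) / 2.0

    def solve(prob: float) -> float:
        # find lambda with P(chi2_df(lambda) <= T) = prob
        if chi2.cdf(T, df) <= prob:
            return 0.0
        lo, hi = 0.0, max(10.0, 2 * T)
        while ncx2.cdf(T, df, hi) > prob:
            hi *= 2
            if hi > 1e7:
                break
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if ncx2.cdf(T, df, mid) > prob:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lam_lo = solve(1.0 - alpha)
    lam_hi = solve(alpha)
    return (
        float(np.sqrt(lam_lo / (df * (n - 1)))),
        float(np.sqrt(lam_hi / (df * (n - 1)))),
    )


def compare_nested(
    fits: Mapping[str, OrdinalFactorResults],
    baseline: OrdinalFactorResults,
    cutoffs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Delta-AFI table of each nested level against the configural model.

    One row per model: level, statistics, AFIs, deltas vs configural, and a
    ``rejected`` flag tripped when any enabled cutoff fires.  The decision is
    a pure function of the delta table and the configured cutoffs.
    """
    if "configural" not in fits:
        raise ValueError("the comparison requires the configural model")
    mom0 = fits["configural"].model.moments
    for lvl, f in fits.items():
        if f.model.moments is not mom0 and any(
            not np.allclose(f.model.moments[g].stack(), mom0[g].stack())
            for g in f.spec.groups
        ):
            raise ValueError(f"model {lvl!r} was fitted to different moments")
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    base_afi = afi(fits["configural"], baseline)
    rows = []
    for lvl in LEVELS:
        if lvl not in fits:
            continue
        f = fits[lvl]
        a = afi(f, baseline)
        delta = {k: a[k] - base_afi[k] for k in AFI_NAMES}
        rejected = False
        reasons = []
        if lvl != "configural":
            if "cfi" in cutoffs and delta["cfi"] <= cutoffs["cfi"]:
                rejected, _ = True, reasons.append("cfi")
            rmsea_cut = min(
                cutoffs.get("rmsea", np.inf),
                cutoffs.get("rmsea_categorical", np.inf),
            )
            if np.isfinite(rmsea_cut) and delta["rmsea"] >= rmsea_cut:
                rejected, _ = True, reasons.append("rmsea")
            if "srmr" in cutoffs and delta["srmr"] >= cutoffs["srmr"]:
                rejected, _ = True, reasons.append("srmr")
        dtest = (
            scaled_difference(f, fits["configural"])
            if lvl != "configural"
            else {"statistic": 0.0, "scaled_statistic": 0.0, "scaled_df": 0.0,
                  "pvalue": 1.0, "df": 0}
        )
        rows.append(
            {
                "level": lvl,
                "n_free": f.n_free,
                "statistic": f.scaled_statistic,
                "df": f.scaled_df,
                "pvalue": f.pvalue,
                **{k: a[k] for k in AFI_NAMES},
                "rmsea_lo": a["rmsea_ci"][0],
                "rmsea_hi": a["rmsea_ci"][1],
                **{f"d_{k}": delta[k] for k in AFI_NAMES},
                "dchi2": dtest["statistic"],
                "dchi2_scaled": dtest["scaled_statistic"],
                "dchi2_df": dtest["df"],
                "dchi2_p": dtest["pvalue"],
                "rejected": rejected,
                "reject_reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class InvarianceLadder:
    """Ordered nested fits, their AFIs and the invariance decision."""

    fits: dict[str, OrdinalFactorResults]
    baseline: OrdinalFactorResults
    table: pd.DataFrame
    cutoffs: dict[str, float]
    incomplete: bool = False

    @property
    def highest_level(self) -> str:
        """Highest rung whose delta-AFIs stay within every enabled cutoff."""
        attained = "configural"
        for lvl in LEVELS[1:]:
            row = self.table[self.table["level"] == lvl]
            if row.empty or bool(row["rejected"].iloc[0]):
                break
            attained = lvl
        return attained

    @property
    def means_comparable(self) -> bool:
        return self.highest_level == "thresholds_loadings_intercepts"

    @property
    def variances_comparable(self) -> bool:
        return self.highest_level in (
            "thresholds_loadings",
            "thresholds_loadings_intercepts",
        )

    def decision_narrative(self) -> str:
        lvl = self.highest_level
        lines = [f"Highest invariance level supported: {lvl}."]
        if self.variances_comparable:
            lines.append("Latent variances (inequality) are comparable across groups.")
        else:
            lines.append("Latent variances are NOT comparable across groups.")
        if self.means_comparable:
            lines.append("Latent means are comparable across groups.")
        else:
            lines.append(
                "Latent means are NOT comparable across groups: raw score "
                "differences may reflect reporting differences, not skills."
            )
        return "\n".join(lines)

    def summary(self) -> str:
        cols = [
            "level", "statistic", "df", "pvalue", "cfi", "tli", "rmsea",
            "srmr", "mfi", "gamma_hat", "d_cfi", "d_rmsea", "d_srmr", "rejected",
        ]
        with pd.option_context("display.width", 200):
            return (
                self.table[cols].to_string(index=False, float_format="%.4f")
                + "\n\n" + self.decision_narrative()
            )


def run_ladder(
    panel_or_moments: ItemPanel | Mapping[str, SampleMoments],
    groups: Sequence[str] | None = None,
    reference: str = REFERENCE_GROUP,
    cutoffs: Mapping[str, float] | None = None,
    min_n: int = 200,
    levels: Sequence[str] = LEVELS,
) -> InvarianceLadder:
    """Fit the full configural -> thresholds -> +loadings -> +intercepts ladder.

    Accepts a panel (moments are computed per group) or precomputed moments.
    A non-convergent rung marks the ladder incomplete; the rungs that did
    converge are still reported.
    """
    if isinstance(panel_or_moments, ItemPanel):
        panel = panel_or_moments
        groups = tuple(groups or panel.groups)
        if len(groups) < 2:
            raise ValueError("invariance requires >= 2 groups")
        moments = {g: sample_moments(panel, g, min_n=min_n) for g in groups}
        items = tuple(panel.items)
    else:
        moments = dict(panel_or_moments)
        groups = tuple(groups or moments.keys())
        if len(groups) < 2:
            raise ValueError("invariance requires >= 2 groups")
        items = tuple(next(iter(moments.values())).items)

    fits: dict[str, OrdinalFactorResults] = {}
    incomplete = False
    for lvl in levels:
        spec = build_model(items, groups, lvl, reference=reference)
        try:
            fit = OrdinalFactorModel(moments, spec).fit(check_identification=False)
        except Exception:
            incomplete = True
            continue
        if not fit.converged:
            incomplete = True
        fits[lvl] = fit

    baseline = fit_baseline(moments, groups, items, reference)
    table = compare_nested(fits, baseline, cutoffs)
    # monotonicity of the discrepancy along the nested ladder
    stats = [fits[l].discrepancy for l in LEVELS if l in fits]
    if any(np.diff(stats) < -1e-6 * max(stats)) if len(stats) > 1 else False:
        incomplete = True
    return InvarianceLadder(
        fits=fits,
        baseline=baseline,
        table=table,
        cutoffs=dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs),
        incomplete=incomplete,
    )
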