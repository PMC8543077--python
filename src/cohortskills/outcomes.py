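"""Two-step outcome regressions on estimated skills, with a bootstrap that
repeats the measurement stage.

Later outcomes (smoking, BMI, education, employment, pay) are regressed by
least squares on the EBM skill scores, an optional per-cohort cognitive
score, and family-background covariates.  Binary outcomes run as linear
probability models.  Standard errors come from a bootstrap in which every
replicate resamples children within group, re-fits the measurement model,
re-scores, and re-runs the regression — so the uncertainty of the factor
estimation stage propagates into the coefficient SEs.

The cognitive score is a one-factor minres fit on the Pearson correlations
of the continuous cognitive measures, Bartlett-scored and standardised per
cohort; it is deliberately *not* comparable across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .items import ItemPanel, REFERENCE_GROUP
from .mgcfa import OrdinalFactorModel, build_model
from .scoring import ScoreSet, ebm_scores

__all__ = [
    "cognitive_scores",
    "OutcomeFit",
    "TwoStepOutcomeModel",
    "two_step_regression",
    "coefficient_equality_test",
]


def _minres_onefactor(R: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """One-factor minimum-residual loadings for a correlation matrix."""
    p = R.shape[0]
    lam = np.sqrt(np.clip(np.abs(R - np.eye(p)).max(axis=1), 0.05, 0.95))
    for _ in range(n_iter):
        # conditional update: lam_i = sum_j!=i R_ij lam_j / sum_j!=i lam_j^2
        new = np.empty(p)
        for i in range(p):
            mask = np.arange(p) != i
            denom = (lam[mask] ** 2).sum()
            new[i] = (R[i, mask] @ lam[mask]) / max(denom, 1e-10)
        if np.abs(new - lam).max() < 1e-10:
            lam = new
            break
        lam = new
    return np.clip(lam, -0.999, 0.999)


def cognitive_scores(
    panel: ItemPanel,
    measure_prefix: str = "cog_m",
    cohorts: Sequence[Sequence[str]] | None = None,
) -> pd.Series:
    """Per-cohort one-factor score from continuous cognitive measures.

    ``cohorts`` groups the panel's group labels into cohorts sharing a test
    battery (default: split on the label prefix before ``_``).  Scores are
    Bartlett factor scores, standardised within cohort — comparable within
    but not across cohorts.
    """
    cols = [c for c in panel.data.columns if c.startswith(measure_prefix)]
    if not cols:
        raise ValueError(f"no cognitive measures with prefix {measure_prefix!r}")
    if cohorts is None:
        prefixes: dict[str, list[str]] = {}
        for g in panel.groups:
            prefixes.setdefault(g.split("_")[0], []).append(g)
        cohorts = list(prefixes.values())
    out = pd.Series(np.nan, index=panel.data.index, name="cognitive")
    for members in cohorts:
        mask = panel.data["group"].isin(members)
        M = panel.data.loc[mask, cols].to_numpy(dtype=float)
        Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
        R = np.corrcoef(Z, rowvar=False)
        lam = _minres_onefactor(R)
        psi = np.clip(1.0 - lam**2, 1e-3, None)
        # Bartlett: (lam' Psi^-1 lam)^-1 lam' Psi^-1 z
        w = lam / psi
        score = Z @ w / (lam @ w)
        out.loc[mask] = (score - score.mean()) / score.std(ddof=1)
    return out


@dataclass
class OutcomeFit:
    """Least-squares fit of one outcome in one group with bootstrap SEs."""

    outcome: str
    group: str
    params: pd.Series
    bse: pd.Series
    draws: pd.DataFrame  # bootstrap draws, one row per replicate
    n: int
    adj_r2: float
    n_failed: int = 0

    def summary(self) -> str:
        lines = [
            f"{self.outcome} ~ skills + covariates   [{self.group}]  "
            f"n={self.n}  adj.R2={self.adj_r2:.3f}"
        ]
        for k in self.params.index:
            z = self.params[k] / max(self.bse[k], 1e-12)
            p = 2 * norm.sf(abs(z))
            lines.append(
                f"  {k:>24s} {self.params[k]: .4f} ({self.bse[k]:.4f})  p={p:.3f}"
            )
        return "\n".join(lines)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    Xc = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    n, k = Xc.shape
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / max(tss, 1e-300)
    adj = 1 - (1 - r2) * (n - 1) / max(n - k, 1)
    return beta, adj


class TwoStepOutcomeModel:
    """Outcome regression whose scores come from a refittable measurement stage.

    ``score_pipeline(panel) -> ScoreSet`` encapsulates the measurement stage
    (defaults to fitting the thresholds+loadings invariance model on the
    panel and EBM-scoring it); the bootstrap re-runs it per replicate.
    """

    def __init__(
        self,
        panel: ItemPanel,
        outcome: str,
        covariates: Sequence[str] = (),
        include_cognition: bool = False,
        score_pipeline: Callable[[ItemPanel], ScoreSet] | None = None,
        reference: str = REFERENCE_GROUP,
    ):
        if outcome not in panel.data.columns:
            raise ValueError(f"outcome {outcome!r} not in panel")
        self.panel = panel
        self.outcome = outcome
        self.covariates = list(covariates)
        self.include_cognition = include_cognition
        self.reference = reference
        self.score_pipeline = score_pipeline or self._default_pipeline

    def _default_pipeline(self, panel: ItemPanel) -> ScoreSet:
        model = OrdinalFactorModel.from_panel(
            panel, level="thresholds_loadings", reference=self.reference,
            min_n=50,
        )
        return ebm_scores(model.fit(check_identification=False), panel)

    def _design(
        self, panel: ItemPanel, scores: ScoreSet, group: str
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        df = scores.data.merge(panel.data, on=["child_id", "group"], how="inner")
        df = df[(df["group"] == group) & df["converged"]]
        cols = ["ext"]
        names = ["externalising"]
        if df["int"].notna().any():
            cols.append("int")
            names.append("internalising")
        if self.include_cognition:
            cog = pd.DataFrame(
                {
                    "child_id": panel.data["child_id"].to_numpy(),
                    "cognitive": cognitive_scores(panel).to_numpy(),
                }
            )
            df = df.merge(cog, on="child_id", how="left")
            cols.append("cognitive")
            names.append("cognitive")
        cols += self.covariates
        names += self.covariates
        sub = df.dropna(subset=[self.outcome, *cols])
        y = sub[self.outcome].to_numpy(dtype=float)
        X = sub[cols].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError(f"outcome {self.outcome!r} is constant in {group!r}")
        return y, X, names

    def fit(self, group: str, B: int = 1000, seed: int = 0) -> OutcomeFit:
        """Point estimates plus measurement-aware bootstrap SEs."""
        return self.fit_groups([group], B=B, seed=seed)[group]

    def fit_groups(
        self, groups: Sequence[str], B: int = 1000, seed: int = 0
    ) -> dict[str, OutcomeFit]:
        """Fit several groups sharing one bootstrap loop.

        Each replicate resamples the whole panel once, refits the
        measurement stage once, and runs every group's regression on it, so
        the replicate draws are paired across groups — the pairing the
        cross-group coefficient-equality test relies on.
        """
        if B < 100:
            raise ValueError("B must be at least 100")
        scores = self.score_pipeline(self.panel)
        point: dict[str, tuple] = {}
        for g in groups:
            y, X, names = self._design(self.panel, scores, g)
            point[g] = (_ols(y, X), len(y), names)

        rng = np.random.default_rng(seed)
        draws: dict[str, list] = {g: [] for g in groups}
        failed = 0
        base = self.panel.data
        group_idx = {
            g: base.index[base["group"] == g].to_numpy() for g in self.panel.groups
        }
        for _ in range(B):
            take = np.concatenate(
                [rng.choice(ix, len(ix), replace=True) for ix in group_idx.values()]
            )
            bdata = base.loc[take].copy()
            bdata["child_id"] = np.arange(len(bdata))  # resampled ids
            bpanel = ItemPanel(
                data=bdata.reset_index(drop=True),
                items=self.panel.items,
                covariate_columns=self.panel.covariate_columns,
            )
            try:
                bscores = self.score_pipeline(bpanel)
                reps = {}
                for g in groups:
                    by, bX, _ = self._design(bpanel, bscores, g)
                    reps[g] = _ols(by, bX)[0]
            except Exception:
                failed += 1
                continue
            for g in groups:
                draws[g].append(reps[g])
        if failed > max(1, 0.05 * B):
            raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
        out = {}
        for g in groups:
            (beta, adj), n, names = point[g]
            index = ["const"] + names
            D = pd.DataFrame(draws[g], columns=index)
            out[g] = OutcomeFit(
                outcome=self.outcome,
                group=g,
                params=pd.Series(beta, index=index),
                bse=D.std(ddof=1),
                draws=D,
                n=n,
                adj_r2=adj,
                n_failed=failed,
            )
        return out


def two_step_regression(
    panel: ItemPanel,
    outcome: str,
    group: str,
    covariates: Sequence[str] = (),
    include_cognition: bool = False,
    B: int = 1000,
    seed: int = 0,
    score_pipeline: Callable[[ItemPanel], ScoreSet] | None = None,
) -> OutcomeFit:
    """Functional front-end for :class:`TwoStepOutcomeModel`."""
    model = TwoStepOutcomeModel(
        panel, outcome, covariates, include_cognition, score_pipeline
    )
    return model.fit(group, B=B, seed=seed)


def coefficient_equality_test(
    fit_a: OutcomeFit,
    fit_b: OutcomeFit,
    regressor: str,
    method: str = "normal",
) -> float:
    """p-value for equality of one coefficient across two fitted groups.

    Bootstrap draws are paired by replicate index.  ``normal`` uses a z-test
    on the bootstrap SE of the difference; ``percentile`` inverts the
    centred bootstrap distribution of the difference.
    """
    if regressor not in fit_a.params.index or regressor not in fit_b.params.index:
        raise ValueError(f"regressor {regressor!r} missing from a fit")
    if len(fit_a.draws) != len(fit_b.draws):
        raise ValueError("bootstrap replicate counts differ between fits")
    diff = fit_a.params[regressor] - fit_b.params[regressor]
    d_draws = fit_a.draws[regressor].to_numpy() - fit_b.draws[regressor].to_numpy()
    if method == "normal":
        se = d_draws.std(ddof=1)
        if se <= 0:
            return 1.0 if abs(diff) < 1e-12 else 0.0
        return float(2 * norm.sf(abs(diff) / se))
    if method == "percentile":
        centred = d_draws - d_draws.mean()
        p = 2 * min(
            (centred >= abs(diff)).mean() + 0.5 / len(centred),
            (centred <= -abs(diff)).mean() + 0.5 / len(centred),
        )
        return float(min(p, 1.0))
    raise ValueError(f"unknown method {method!r}")
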