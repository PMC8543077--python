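"""Reweighted RIF (recentered influence function) Oaxaca-Blinder decomposition.

Splits the change in a distributional statistic (quantile gap or variance)
between a source and a target group into four exactly-additive parts:

* **composition** — covariate-distribution shifts, valued at source-group
  returns, detailed covariate by covariate;
* **specification error** — the unexplained part of the source-vs-
  counterfactual comparison (departures from RIF-regression linearity);
* **coefficient** — changes in returns, valued at target covariates,
  detailed covariate by covariate;
* **reweighting error** — the explained part of the target-vs-
  counterfactual comparison (quality of the propensity reweighting).

The counterfactual is the source sample reweighted to the target covariate
distribution with logit propensity odds weights.  All statistics are
evaluated as means of RIF values, which makes the four-term adding-up exact
by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "rif_values",
    "reweight",
    "RIFDecompositionModel",
    "RIFDecomposition",
    "DEFAULT_STATISTICS",
]

DEFAULT_STATISTICS = ("q90-q10", "q75-q25", "q50-q10", "q90-q50", "variance")


def _weighted_quantile(y: np.ndarray, q: float, w: np.ndarray | None) -> float:
    if w is None:
        return float(np.quantile(y, q))
    order = np.argsort(y)
    ys, ws = y[order], w[order]
    cw = np.cumsum(ws)
    # midpoint positions; reduces to standard interpolation as weights even out
    pos = (cw - 0.5 * ws) / cw[-1]
    return float(np.interp(q, pos, ys))


def _silverman_bw(y: np.ndarray, w: np.ndarray | None) -> float:
    if w is None:
        n_eff = len(y)
        mu = y.mean()
        sd = y.std(ddof=1)
        q75, q25 = np.quantile(y, [0.75, 0.25])
    else:
        n_eff = w.sum() ** 2 / (w**2).sum()
        mu = np.average(y, weights=w)
        sd = np.sqrt(np.average((y - mu) ** 2, weights=w))
        q75 = _weighted_quantile(y, 0.75, w)
        q25 = _weighted_quantile(y, 0.25, w)
    spread = min(sd, (q75 - q25) / 1.349) if q75 > q25 else sd
    return 0.9 * spread * n_eff ** (-0.2)


def _kde_at(
    x0: float, y: np.ndarray, w: np.ndarray | None,
    bw: float | None, kernel: str,
) -> float:
    h = bw if bw is not None else _silverman_bw(y, w)
    u = (x0 - y) / h
    if kernel == "gaussian":
        k = np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)
    elif kernel == "epanechnikov":
        k = np.where(np.abs(u) <= 1.0, 0.75 * (1 - u**2), 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    if w is None:
        return float(k.mean() / h)
    return float(np.average(k, weights=w) / h)


def _parse_statistic(statistic: str) -> tuple[str, tuple[float, ...]]:
    if statistic == "variance":
        return "variance", ()
    parts = statistic.split("-")
    taus = []
    for p in parts:
        if not p.startswith("q"):
            raise ValueError(f"unknown statistic {statistic!r}")
        taus.append(float(p[1:]) / 100.0)
    if len(taus) == 1:
        return "quantile", (taus[0],)
    if len(taus) == 2:
        return "gap", (taus[0], taus[1])
    raise ValueError(f"unknown statistic {statistic!r}")


def rif_values(
    y: np.ndarray,
    statistic: str,
    weights: np.ndarray | None = None,
    bandwidth: float | None = None,
    kernel: str = "gaussian",
    density_floor: float = 1e-6,
) -> np.ndarray:
    """Per-observation recentered influence function of a statistic.

    For a quantile q_t:  RIF_i = q_t + (t - 1{y_i <= q_t}) / f(q_t) with the
    density kernel-estimated at the quantile; for a quantile gap the
    difference of the two quantile RIFs; for the variance (y_i - mean)^2.
    The (weighted) mean of the RIF values equals the statistic.
    """
    y = np.asarray(y, dtype=float)
    kind, taus = _parse_statistic(statistic)
    if kind == "variance":
        mu = y.mean() if weights is None else np.average(y, weights=weights)
        return (y - mu) ** 2
    if len(y) < 100:
        raise ValueError("quantile RIFs require n >= 100 for density estimation")

    def one(tau: float) -> np.ndarray:
        q = _weighted_quantile(y, tau, weights)
        f = _kde_at(q, y, weights, bandwidth, kernel)
        if f < density_floor:
            raise ValueError(
                f"density too thin at quantile {tau:.2f} (f={f:.2e})"
            )
        return q + (tau - (y <= q).astype(float)) / f

    if kind == "quantile":
        return one(taus[0])
    return one(taus[0]) - one(taus[1])


def reweight(
    X_source: np.ndarray,
    X_target: np.ndarray,
    trim: tuple[float, float] = (0.01, 0.99),
    max_trim_frac: float = 0.02,
) -> np.ndarray:
    """Propensity odds weights making the source resemble the target.

    Fits a logit of target membership on the stacked covariates; source
    observation i gets weight proportional to p(x_i)/(1 - p(x_i)),
    normalised to sum to the source sample size.  Propensities outside the
    trimming bounds get weight zero (counted; a warning fires if more than
    ``max_trim_frac`` of the source is trimmed).
    """
    X_source = np.asarray(X_source, dtype=float)
    X_target = np.asarray(X_target, dtype=float)
    X = np.vstack([X_source, X_target])
    z = np.concatenate([np.zeros(len(X_source)), np.ones(len(X_target))])
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(z, Xc).fit(disp=0, maxiter=200)
        except Exception as err:  # includes perfect separation
            raise ValueError(f"propensity logit failed: {err}") from err
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise ValueError("perfect separation in the propensity logit")
    p = res.predict(Xc[: len(X_source)])
    keep = (p >= trim[0]) & (p <= trim[1])
    n_trimmed = int((~keep).sum())
    if n_trimmed > max_trim_frac * len(X_source):
        warnings.warn(
            f"{n_trimmed}/{len(X_source)} source observations trimmed "
            f"(propensity outside {trim})",
            stacklevel=2,
        )
    w = np.where(keep, p / (1 - p), 0.0)
    if w.sum() <= 0:
        raise ValueError("all source observations trimmed")
    return w * (len(X_source) / w.sum())


def _check_collinear(X: np.ndarray, names: Sequence[str]) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        _, r = np.linalg.qr(Xc)
        bad = [
            (["const"] + list(names))[j]
            for j in np.where(np.abs(np.diag(r)) < 1e-8)[0]
        ]
        raise ValueError(f"collinear covariates: {bad}")


def _wols(y: np.ndarray, X: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    Xc = np.column_stack([np.ones(len(X)), X])
    if w is None:
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    else:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xc * sw[:, None], y * sw, rcond=None)
    return beta


def _wmean_X(X: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    Xc = np.column_stack([np.ones(len(X)), X])
    if w is None:
        return Xc.mean(axis=0)
    return np.average(Xc, axis=0, weights=w)


@dataclass
class RIFDecomposition:
    """Four-component split of one distributional change, with detail.

    ``total = composition + specification_error + coefficient +
    reweighting_error`` holds exactly, and the per-covariate detail columns
    sum exactly to their aggregate components.
    """

    statistic: str
    total: float
    composition: float
    specification_error: float
    coefficient: float
    reweighting_error: float
    detail: pd.DataFrame  # per-covariate composition/coefficient contributions
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0

    @property
    def components(self) -> dict[str, float]:
        return {
            "total": self.total,
            "composition": self.composition,
            "specification_error": self.specification_error,
            "coefficient": self.coefficient,
            "reweighting_error": self.reweighting_error,
        }

    def summary(self) -> str:
        lines = [f"RIF decomposition of {self.statistic}"]
        for k, v in self.components.items():
            se = self.se.get(k)
            p = self.pvalues.get(k)
            extra = ""
            if se is not None:
                extra = f"   (se {se:.4f}" + (f", p {p:.3f})" if p is not None else ")")
            lines.append(f"  {k:>20s}: {v: .4f}{extra}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"statistic": self.statistic, "component": k, "covariate": "",
             "value": v, "se": self.se.get(k, np.nan),
             "pvalue": self.pvalues.get(k, np.nan)}
            for k, v in self.components.items()
        ]
        out = pd.DataFrame(rows)
        det = self.detail.copy()
        det.insert(0, "statistic", self.statistic)
        return pd.concat([out, det], ignore_index=True)


class RIFDecompositionModel:
    """Two-stage reweighted RIF decomposition between two groups.

    Parameters
    ----------
    y_source, y_target
        Outcome (factor score) vectors for the source (earlier cohort) and
        target (later cohort) samples.
    X_source, X_target
        Covariate matrices with identical column sets.
    names
        Covariate names (columns of X).
    statistic
        One of ``q90-q10``, ``q75-q25``, ``q50-q10``, ``q90-q50``,
        ``variance`` (or a single quantile ``q50``).
    """

    def __init__(
        self,
        y_source: np.ndarray,
        X_source: np.ndarray,
        y_target: np.ndarray,
        X_target: np.ndarray,
        names: Sequence[str],
        statistic: str = "q90-q10",
        kernel: str = "gaussian",
        bandwidth: float | None = None,
        trim: tuple[float, float] = (0.01, 0.99),
    ):
        self.y_s = np.asarray(y_source, dtype=float)
        self.X_s = np.asarray(X_source, dtype=float)
        self.y_t = np.asarray(y_target, dtype=float)
        self.X_t = np.asarray(X_target, dtype=float)
        if self.X_s.shape[1] != self.X_t.shape[1]:
            raise ValueError("source and target must share the covariate set")
        self.names = list(names)
        self.statistic = statistic
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.trim = trim
        _check_collinear(self.X_s, self.names)
        _check_collinear(self.X_t, self.names)

    # -- core algebra ---------------------------------------------------------

    def _point(
        self, y_s, X_s, y_t, X_t
    ) -> dict:
        w_c = reweight(X_s, X_t, trim=self.trim)
        rif_s = rif_values(y_s, self.statistic, kernel=self.kernel,
                           bandwidth=self.bandwidth)
        rif_c = rif_values(y_s, self.statistic, weights=w_c,
                           kernel=self.kernel, bandwidth=self.bandwidth)
        rif_t = rif_values(y_t, self.statistic, kernel=self.kernel,
                           bandwidth=self.bandwidth)
        b_s = _wols(rif_s, X_s, None)
        b_c = _wols(rif_c, X_s, w_c)
        b_t = _wols(rif_t, X_t, None)
        xb_s = _wmean_X(X_s, None)
        xb_c = _wmean_X(X_s, w_c)
        xb_t = _wmean_X(X_t, None)
        comp_detail = (xb_c - xb_s) * b_s
        coef_detail = xb_t * (b_t - b_c)
        nu_s = float(xb_s @ b_s)
        nu_c = float(xb_c @ b_c)
        nu_t = float(xb_t @ b_t)
        return {
            "total": nu_t - nu_s,
            "composition": float(comp_detail.sum()),
            "specification_error": float(xb_c @ (b_c - b_s)),
            "coefficient": float(coef_detail.sum()),
            "reweighting_error": float((xb_t - xb_c) @ b_c),
            "comp_detail": comp_detail,
            "coef_detail": coef_detail,
            "nu": (nu_s, nu_c, nu_t),
        }

    def fit(self, bootstrap: int = 0, seed: int = 0) -> RIFDecomposition:
        """Point decomposition, optionally with full-procedure bootstrap SEs.

        Each bootstrap replicate resamples children within group and re-runs
        reweighting, RIF estimation and the regressions end to end.
        """
        pt = self._point(self.y_s, self.X_s, self.y_t, self.X_t)
        names_c = ["const"] + self.names
        detail = pd.DataFrame(
            {
                "component": (["composition"] * len(names_c))
                + (["coefficient"] * len(names_c)),
                "covariate": names_c * 2,
                "value": np.concatenate([pt["comp_detail"], pt["coef_detail"]]),
                "se": np.nan,
                "pvalue": np.nan,
            }
        )
        se: dict[str, float] = {}
        pv: dict[str, float] = {}
        if bootstrap:
            if bootstrap < 100:
                raise ValueError("bootstrap must use at least 100 replications")
            rng = np.random.default_rng(seed)
            keys = ["total", "composition", "specification_error",
                    "coefficient", "reweighting_error"]
            draws = {k: [] for k in keys}
            det_draws = []
            failed = 0
            for _ in range(bootstrap):
                i_s = rng.integers(0, len(self.y_s), len(self.y_s))
                i_t = rng.integers(0, len(self.y_t), len(self.y_t))
                try:
                    b = self._point(
                        self.y_s[i_s], self.X_s[i_s],
                        self.y_t[i_t], self.X_t[i_t],
                    )
                except Exception:
                    failed += 1
                    continue
                for k in keys:
                    draws[k].append(b[k])
                det_draws.append(
                    np.concatenate([b["comp_detail"], b["coef_detail"]])
                )
            if failed > 0.01 * bootstrap:
                raise RuntimeError(f"{failed}/{bootstrap} replicates failed")
            for k in keys:
                d = np.asarray(draws[k])
                se[k] = float(d.std(ddof=1))
                z = abs(pt[k]) / max(se[k], 1e-12)
                from scipy.stats import norm as _norm

                pv[k] = float(2 * _norm.sf(z))
            D = np.asarray(det_draws)
            detail["se"] = D.std(axis=0, ddof=1)
            from scipy.stats import norm as _norm

            detail["pvalue"] = 2 * _norm.sf(
                np.abs(detail["value"].to_numpy())
                / np.maximum(detail["se"].to_numpy(), 1e-12)
            )
        return RIFDecomposition(
            statistic=self.statistic,
            total=pt["total"],
            composition=pt["composition"],
            specification_error=pt["specification_error"],
            coefficient=pt["coefficient"],
            reweighting_error=pt["reweighting_error"],
            detail=detail,
            se=se,
            pvalues=pv,
            n_boot=bootstrap,
        )
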