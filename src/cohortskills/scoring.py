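"""Empirical Bayes Modal (EBM) factor scores on the reference-group scale.

A child's score is the posterior mode of the latent skill vector given the
child's item responses and the child's *group-specific* measurement
parameters: ordinal-probit likelihood times the group's normal prior
N(kappa_g, Phi_g).  Group-specific intercepts and factor covariances are
used deliberately — intercepts are not invariant across cohorts, so scores
are comparable in spread but not in cross-cohort location.

Scores are reported in units of the reference group's score distribution
(mean 0, SD 1 among reference-group children).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .items import ItemPanel, REFERENCE_GROUP
from .mgcfa import OrdinalFactorResults
from .params import GroupParameterSet, factor_index

__all__ = ["ScoreSet", "ebm_scores", "posterior_logdensity"]


@dataclass
class ScoreSet:
    """Per-child factor scores with convergence flags.

    ``data`` columns: child_id, group, ext, int, converged.  Scores are in
    reference-group standard-deviation units (reference mean subtracted).
    """

    data: pd.DataFrame
    reference: str
    ref_mean: np.ndarray
    ref_sd: np.ndarray

    def group_scores(self, group: str, factor: str = "ext") -> np.ndarray:
        sub = self.data[(self.data["group"] == group) & self.data["converged"]]
        return sub[factor].to_numpy()

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def plot_densities(self, factor: str = "ext", groups=None, ax=None):
        """Score densities per group (Epanechnikov kernel, Silverman rule).

        Remember that only the *shapes* are comparable across cohorts, not
        the locations.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g in groups or self.groups:
            y = self.group_scores(g, factor)
            sd = y.std(ddof=1)
            iqr = np.subtract(*np.quantile(y, [0.75, 0.25]))
            h = 0.9 * min(sd, iqr / 1.349 if iqr > 0 else sd) * len(y) ** -0.2
            grid = np.linspace(y.min() - 3 * h, y.max() + 3 * h, 400)
            u = (grid[:, None] - y[None, :]) / h
            dens = np.where(np.abs(u) <= 1, 0.75 * (1 - u**2), 0.0).mean(axis=1) / h
            ax.plot(grid, dens, label=g)
        ax.set_xlabel(f"{factor} score (reference-group SD units)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def _item_tables(gps: GroupParameterSet):
    """Per-item lookup tables: (a_lo, a_up) per category, slope b = lam/psi_sd."""
    psi_sd = np.sqrt(gps.psi)
    a_lo, a_up, b = [], [], []
    for i, m in enumerate(gps.items):
        bounds = np.concatenate(([-np.inf], gps.tau[i], [np.inf]))
        a_lo.append((bounds[:-1] - gps.nu[i]) / psi_sd[i])
        a_up.append((bounds[1:] - gps.nu[i]) / psi_sd[i])
        b.append(gps.lam[i] / psi_sd[i])
    return a_lo, a_up, np.array(b)


def _phi_terms(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Phi(z), phi(z), z*phi(z)) with infinities handled."""
    from scipy.special import ndtr

    finite = np.isfinite(z)
    zc = np.where(finite, z, 0.0)
    cdf = np.where(finite, ndtr(zc), (z > 0).astype(float))
    pdf = np.where(
        finite, np.exp(-0.5 * zc * zc) / np.sqrt(2.0 * np.pi), 0.0
    )
    zpdf = np.where(finite, zc * pdf, 0.0)
    return cdf, pdf, zpdf


def posterior_logdensity(
    theta: np.ndarray, codes: np.ndarray, gps: GroupParameterSet
) -> np.ndarray:
    """Log posterior kernel at latent points ``theta`` (m x 2) for one child.

    Used by the estimator's tests as well as by grid-based diagnostics; kept
    separate from the Newton iteration so the two paths stay independent.
    """
    theta = np.atleast_2d(theta)
    a_lo, a_up, b = _item_tables(gps)
    fidx = factor_index(gps.items)
    ll = np.zeros(theta.shape[0])
    for i in range(len(gps.items)):
        s = codes[i]
        z_up = a_up[i][s] - b[i] * theta[:, fidx[i]]
        z_lo = a_lo[i][s] - b[i] * theta[:, fidx[i]]
        p = norm.cdf(z_up) - norm.cdf(z_lo)
        ll += np.log(np.maximum(p, 1e-300))
    dev = theta - gps.kappa
    phi_inv = np.linalg.inv(gps.phi)
    ll -= 0.5 * np.einsum("mi,ij,mj->m", dev, phi_inv, dev)
    return ll


def _newton_scores(
    X: np.ndarray, gps: GroupParameterSet, tol: float = 1e-10, max_iter: int = 80
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes for all response patterns in X (n x p); vectorised.

    The ordinal-probit log-likelihood is log-concave in theta and the prior
    is Gaussian, so damped Newton from the prior mean finds the global mode.
    """
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    m = patterns.shape[0]
    a_lo, a_up, b = _item_tables(gps)
    fidx = factor_index(gps.items)
    nfac = gps.phi.shape[0]
    phi_inv = np.linalg.inv(gps.phi)
    theta = np.tile(gps.kappa[:nfac], (m, 1))
    converged = np.zeros(m, dtype=bool)

    # per-pattern category bound lookups
    AU = np.column_stack([a_up[i][patterns[:, i]] for i in range(len(b))])
    AL = np.column_stack([a_lo[i][patterns[:, i]] for i in range(len(b))])

    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        th = theta[active]
        lin = th[:, fidx] * b  # (ma, p)
        cu, pu, zu = _phi_terms(AU[active] - lin)
        cl, pl, zl = _phi_terms(AL[active] - lin)
        p = np.maximum(cu - cl, 1e-12)
        g_item = -b * (pu - pl) / p
        h_item = -(b**2) * ((zu - zl) / p + ((pu - pl) / p) ** 2)
        G = np.zeros((th.shape[0], nfac))
        Hd = np.zeros((th.shape[0], nfac))
        for f in range(nfac):
            cols = fidx == f
            G[:, f] = g_item[:, cols].sum(axis=1)
            Hd[:, f] = h_item[:, cols].sum(axis=1)
        dev = th - gps.kappa[:nfac]
        G -= dev @ phi_inv
        # Hessian: diag(Hd) - phi_inv (negative definite)
        if nfac == 1:
            step = -G / (Hd - phi_inv[0, 0])
        else:
            h11 = Hd[:, 0] - phi_inv[0, 0]
            h22 = Hd[:, 1] - phi_inv[1, 1]
            h12 = np.full_like(h11, -phi_inv[0, 1])
            det = h11 * h22 - h12**2
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            step = np.empty_like(G)
            step[:, 0] = -(h22 * G[:, 0] - h12 * G[:, 1]) / det
            step[:, 1] = -(h11 * G[:, 1] - h12 * G[:, 0]) / det
        # dampen large steps
        nrm = np.abs(step).max(axis=1, keepdims=True)
        step = step / np.maximum(nrm, 1.0)
        theta[active] = np.clip(th + step, -8.0, 8.0)
        done = np.abs(step).max(axis=1) < tol
        idx = np.where(active)[0]
        converged[idx[done]] = True
        active[idx[done]] = False

    return theta[inverse], converged[inverse]


def ebm_scores(
    fit: OrdinalFactorResults | Mapping[str, GroupParameterSet],
    panel: ItemPanel,
    reference: str | None = None,
) -> ScoreSet:
    """Score every child in the panel and standardise to the reference group.

    ``fit`` is a fitted invariance model (typically at the
    thresholds+loadings level) or a per-group parameter mapping.  Children
    whose inner optimisation fails are flagged and excluded from the
    reference standardisation.
    """
    if isinstance(fit, OrdinalFactorResults):
        if not fit.converged:
            raise ValueError("measurement model did not converge")
        group_params = fit.group_parameters()
        reference = reference or fit.spec.reference
    else:
        group_params = dict(fit)
        reference = reference or REFERENCE_GROUP
    panel_groups = panel.groups
    unknown = [g for g in panel_groups if g not in group_params]
    if unknown:
        raise ValueError(f"panel groups {unknown} not in the fitted model")
    if reference not in group_params:
        raise ValueError(f"reference group {reference!r} not in the fitted model")

    frames = []
    for g in panel_groups:
        sub = panel.group_frame(g)
        X = sub[panel.item_cols].to_numpy(dtype=np.int64)
        theta, conv = _newton_scores(X, group_params[g])
        frames.append(
            pd.DataFrame(
                {
                    "child_id": sub["child_id"].to_numpy(),
                    "group": g,
                    "ext": theta[:, 0],
                    "int": theta[:, 1] if theta.shape[1] > 1 else np.nan,
                    "converged": conv,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)

    ref = data[(data["group"] == reference) & data["converged"]]
    cols = ["ext", "int"] if data["int"].notna().any() else ["ext"]
    ref_mean = ref[cols].mean().to_numpy()
    ref_sd = ref[cols].std(ddof=1).to_numpy()
    if np.any(ref_sd <= 0):
        raise ValueError("reference group has degenerate score dispersion")
    data[cols] = (data[cols] - ref_mean) / ref_sd
    return ScoreSet(
        data=data, reference=reference, ref_mean=ref_mean, ref_sd=ref_sd
    )
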