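"""Polychoric sample moments: thresholds, correlations, asymptotic covariance.

Two-step (Olsson-style) estimation.  Stage 1 fixes each item's thresholds at
the inverse-normal-CDF of its cumulative category proportions; stage 2
maximises, pair by pair, the bivariate-normal multinomial likelihood over the
correlation with thresholds held fixed.  The asymptotic covariance of the
stacked (thresholds, correlations) vector is assembled from per-observation
influence functions, with the stage-2 influences corrected for the estimated
thresholds — this is the full weight matrix that mean-and-variance-adjusted
weighted least squares (WLSMV) exploits.

Empty bivariate cells contribute nothing to the likelihood (no continuity
correction is applied: silent smoothing would change the test statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._bvn import (
    _RHO_MAX,
    cell_dprob_drho,
    cell_probabilities,
    bvn_dcdf_dh,
)
from .items import ItemMeta, ItemPanel
from .params import GroupParameterSet

__all__ = [
    "SampleMoments",
    "estimate_thresholds",
    "polychoric_corr",
    "sample_moments",
    "population_moments",
]


def estimate_thresholds(counts: np.ndarray) -> np.ndarray:
    """Stage-1 thresholds: inverse normal CDF of cumulative proportions.

    ``counts`` are the per-category frequencies of one item (length 2 or 3).
    Raises for an item observed in a single category.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts > 0).sum() < 2:
        raise ValueError("degenerate item: fewer than 2 observed categories")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    tau = norm.ppf(cum)
    if np.any(~np.isfinite(tau)) or np.any(np.diff(tau) <= 0):
        raise ValueError("degenerate item: empty interior category")
    return tau


def _grids(tau_i: np.ndarray, tau_k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = np.concatenate(([-np.inf], tau_i, [np.inf]))
    K = np.concatenate(([-np.inf], tau_k, [np.inf]))
    return H, K


def _fit_rho_batch(
    H: np.ndarray,
    K: np.ndarray,
    counts: np.ndarray,
    rho0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Safeguarded Fisher scoring for a batch of pairs.

    H, K: (P, gmax+1) boundary grids padded with +inf; counts: (P, gmax, gmax);
    rho0: (P,) start values.  Returns (rho_hat, converged mask).  Pairs hitting
    the open-interval bound are clipped there (callers flag them).
    """
    P = H.shape[0]
    rho = np.clip(np.asarray(rho0, dtype=float), -0.9, 0.9)
    lo = np.full(P, -_RHO_MAX)
    hi = np.full(P, _RHO_MAX)
    n = counts.sum(axis=(1, 2))
    active = np.ones(P, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        pi = cell_probabilities(H[idx], K[idx], rho[idx])
        dpi = cell_dprob_drho(H[idx], K[idx], rho[idx])
        pos = pi > 1e-300
        ratio = np.where(pos, dpi / np.where(pos, pi, 1.0), 0.0)
        score = (counts[idx] * ratio).sum(axis=(1, 2))
        info = n[idx] * (np.where(pos, dpi**2 / np.where(pos, pi, 1.0), 0.0)).sum(
            axis=(1, 2)
        )
        step = score / np.maximum(info, 1e-12)
        # bracket from the score sign (likelihood unimodal in rho)
        lo[idx] = np.where(score > 0, np.maximum(lo[idx], rho[idx]), lo[idx])
        hi[idx] = np.where(score < 0, np.minimum(hi[idx], rho[idx]), hi[idx])
        new = rho[idx] + step
        outside = (new <= lo[idx]) | (new >= hi[idx])
        new = np.where(outside, 0.5 * (lo[idx] + hi[idx]), new)
        moved = np.abs(new - rho[idx])
        rho[idx] = new
        active[idx] = (moved > tol) & (hi[idx] - lo[idx] > tol)
    return rho, ~active


def polychoric_corr(
    table: np.ndarray,
    thresholds: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Two-step polychoric correlation for one two-way table of counts.

    Thresholds default to the stage-1 estimates from the table margins.
    Raises if the table is degenerate (all mass in one row or column) or if
    the scoring iteration fails to converge.
    """
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        raise ValueError("pair inestimable: all mass in a single row or column")
    if thresholds is None:
        thresholds = (estimate_thresholds(rows), estimate_thresholds(cols))
    H, K = _grids(*thresholds)
    # moment start: Pearson correlation of category midpoints
    a = np.arange(table.shape[0])
    b = np.arange(table.shape[1])
    n = table.sum()
    ma = (rows @ a) / n
    mb = (cols @ b) / n
    cov = (table * np.outer(a - ma, b - mb)).sum() / n
    sa = np.sqrt((rows @ (a - ma) ** 2) / n)
    sb = np.sqrt((cols @ (b - mb) ** 2) / n)
    r0 = cov / (sa * sb) if sa > 0 and sb > 0 else 0.0
    gmax = max(table.shape)
    Hp = np.concatenate([H, np.full(gmax + 1 - len(H), np.inf)])
    Kp = np.concatenate([K, np.full(gmax + 1 - len(K), np.inf)])
    cpad = np.zeros((gmax, gmax))
    cpad[: table.shape[0], : table.shape[1]] = table
    rho, ok = _fit_rho_batch(
        Hp[None, :], Kp[None, :], cpad[None, :, :], np.array([r0])
    )
    if not ok[0]:
        raise RuntimeError(
            f"polychoric correlation did not converge (last iterate {rho[0]:.6f})"
        )
    return float(rho[0])


@dataclass
class SampleMoments:
    """Thresholds, polychoric correlations and their asymptotic covariance.

    ``acov`` is the per-observation asymptotic covariance of the stacked
    (thresholds, lower-triangular correlations) estimate vector, i.e.
    Cov(stack) ~ acov / n.  ``stack()`` orders thresholds item by item,
    followed by correlations in (i < k) column-major pair order.
    """

    group: str
    n: int
    thresholds: list[np.ndarray]
    corr: np.ndarray
    acov: np.ndarray
    items: Sequence[ItemMeta]
    near_singular_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        p = self.n_items
        return [(i, k) for i in range(p) for k in range(i + 1, p)]

    @property
    def n_thresholds(self) -> int:
        return sum(len(t) for t in self.thresholds)

    def stack(self) -> np.ndarray:
        rhos = np.array([self.corr[i, k] for i, k in self.pairs])
        return np.concatenate([np.concatenate(self.thresholds), rhos])

    def labels(self) -> list[str]:
        lab = [
            f"tau_{m.item_id}_{s + 1}"
            for m, t in zip(self.items, self.thresholds)
            for s in range(len(t))
        ]
        lab += [
            f"rho_{self.items[i].item_id}_{self.items[k].item_id}"
            for i, k in self.pairs
        ]
        return lab

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: group, stat_type, index1, index2, estimate, se."""
        se = np.sqrt(np.maximum(np.diag(self.acov), 0.0) / self.n)
        rows = []
        pos = 0
        for m, t in zip(self.items, self.thresholds):
            for s, v in enumerate(t):
                rows.append(
                    ("threshold", m.item_id, s + 1, v, se[pos])
                )
                pos += 1
        for i, k in self.pairs:
            rows.append(
                ("correlation", self.items[i].item_id, self.items[k].item_id,
                 self.corr[i, k], se[pos])
            )
            pos += 1
        df = pd.DataFrame(
            rows, columns=["stat_type", "index1", "index2", "estimate", "se"]
        )
        df.insert(0, "group", self.group)
        return df


def _threshold_influence(
    X: np.ndarray, thresholds: list[np.ndarray]
) -> tuple[np.ndarray, list[slice]]:
    """Per-observation influence of each threshold estimate (n x n_thr)."""
    n = X.shape[0]
    cols = []
    slices = []
    pos = 0
    for i, tau in enumerate(thresholds):
        x = X[:, i]
        for s, t in enumerate(tau):
            p = (x <= s).mean()
            cols.append(((x <= s) - p) / norm.pdf(t))
        slices.append(slice(pos, pos + len(tau)))
        pos += len(tau)
    return np.column_stack(cols), slices


def sample_moments(
    panel: ItemPanel, group: str, min_n: int = 200
) -> SampleMoments:
    """Polychoric moments and full asymptotic covariance for one group."""
    X = panel.responses(group)
    n, p = X.shape
    if n < min_n:
        raise ValueError(f"group {group!r} has n={n} < required floor {min_n}")
    ncat = np.array([m.n_categories for m in panel.items])
    gmax = int(ncat.max())

    thresholds = []
    for i, m in enumerate(panel.items):
        counts = np.bincount(X[:, i], minlength=m.n_categories)
        try:
            thresholds.append(estimate_thresholds(counts))
        except ValueError as err:
            raise ValueError(f"item {m.item_id} in group {group!r}: {err}") from err

    pairs = [(i, k) for i in range(p) for k in range(i + 1, p)]
    P = len(pairs)
    H = np.full((P, gmax + 1), np.inf)
    K = np.full((P, gmax + 1), np.inf)
    counts = np.zeros((P, gmax, gmax))
    r0 = np.zeros(P)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    for q, (i, k) in enumerate(pairs):
        H[q, 0], K[q, 0] = -np.inf, -np.inf
        H[q, 1 : ncat[i]] = thresholds[i]
        K[q, 1 : ncat[k]] = thresholds[k]
        flat = np.bincount(X[:, i] * gmax + X[:, k], minlength=gmax * gmax)
        counts[q] = flat.reshape(gmax, gmax)
        ri = counts[q].sum(axis=1)
        ck = counts[q].sum(axis=0)
        if (ri > 0).sum() < 2 or (ck > 0).sum() < 2:
            raise ValueError(
                f"pair (item {panel.items[i].item_id}, item {panel.items[k].item_id})"
                f" inestimable in group {group!r}"
            )
        r0[q] = (Xc[:, i] @ Xc[:, k]) / (n * sd[i] * sd[k])

    rho, ok = _fit_rho_batch(H, K, counts, r0)
    if not ok.all():
        bad = [pairs[q] for q in np.where(~ok)[0]]
        raise RuntimeError(f"polychoric scoring failed for pairs {bad}")
    near = [pairs[q] for q in np.where(np.abs(rho) >= _RHO_MAX - 1e-9)[0]]

    corr = np.eye(p)
    for q, (i, k) in enumerate(pairs):
        corr[i, k] = corr[k, i] = rho[q]

    # ---- influence functions -> full asymptotic covariance -----------------
    IF_tau, thr_slices = _threshold_influence(X, thresholds)
    IF_rho = np.empty((n, P))
    pi = cell_probabilities(H, K, rho)
    dpi = cell_dprob_drho(H, K, rho)
    pos = pi > 1e-300
    inv_pi = np.where(pos, 1.0 / np.where(pos, pi, 1.0), 0.0)
    sc = dpi * inv_pi  # per-cell score d log pi / d rho
    info = (dpi**2 * inv_pi).sum(axis=(1, 2))
    # derivatives of cell probabilities wrt row/col boundaries
    Dh = bvn_dcdf_dh(H[:, :, None], K[:, None, :], rho[:, None, None])
    Dk = bvn_dcdf_dh(K[:, None, :], H[:, :, None], rho[:, None, None])
    Dh = np.where(np.isfinite(H[:, :, None]), Dh, 0.0)
    Dk = np.where(np.isfinite(K[:, None, :]), Dk, 0.0)
    for q, (i, k) in enumerate(pairs):
        cell = sc[q][X[:, i], X[:, k]]
        corr_term = np.zeros(n)
        # corrections for estimated thresholds of both items
        for s in range(ncat[i] - 1):
            # d pi_ab / d tau_{i,s}: boundary index s+1 on the row grid
            dpidt = np.zeros((gmax, gmax))
            dd = Dh[q, s + 1, 1:] - Dh[q, s + 1, :-1]  # (gmax,) per column cells
            dpidt[s, :] = dd[:gmax]
            if s + 1 < gmax:
                dpidt[s + 1, :] = -dd[:gmax]
            A = -(dpi[q] * dpidt * inv_pi[q]).sum()
            corr_term += A * IF_tau[:, thr_slices[i]][:, s]
        for s in range(ncat[k] - 1):
            dpidt = np.zeros((gmax, gmax))
            dd = Dk[q, 1:, s + 1] - Dk[q, :-1, s + 1]
            dpidt[:, s] = dd[:gmax]
            if s + 1 < gmax:
                dpidt[:, s + 1] = -dd[:gmax]
            A = -(dpi[q] * dpidt * inv_pi[q]).sum()
            corr_term += A * IF_tau[:, thr_slices[k]][:, s]
        IF_rho[:, q] = (cell - cell.mean() + corr_term) / max(info[q], 1e-12)

    Z = np.hstack([IF_tau, IF_rho])
    acov = (Z.T @ Z) / n
    acov = 0.5 * (acov + acov.T)
    return SampleMoments(
        group=group,
        n=n,
        thresholds=thresholds,
        corr=corr,
        acov=acov,
        items=tuple(panel.items),
        near_singular_pairs=near,
    )


def population_moments(
    gps: GroupParameterSet, group: str = "pop", n: int = 10_000
) -> SampleMoments:
    """Exact model-implied moments with identity weight matrix.

    Used for perfect-fit checks: fitting a correctly specified model to these
    moments must drive the discrepancy to zero.
    """
    thresholds = gps.implied_standardized_thresholds()
    corr = gps.implied_corr()
    n_stats = sum(len(t) for t in thresholds) + len(corr) * (len(corr) - 1) // 2
    return SampleMoments(
        group=group,
        n=n,
        thresholds=[np.asarray(t) for t in thresholds],
        corr=corr,
        acov=np.eye(n_stats),
        items=tuple(gps.items),
    )
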