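"""Per-group measurement parameters for the two-factor ordinal model.

A child j in group c has a latent skill vector theta ~ N(kappa, Phi) with
components (EXT, INT).  Each item i has a continuous response propensity

    X*_i = nu_i + lambda_i * theta_{f(i)} + u_i,     u_i ~ N(0, psi_i)

(congeneric structure: every item loads on exactly one factor), and the
observed ordinal code is X_i = s iff tau_{s} <= X*_i < tau_{s+1} with
tau_0 = -inf and tau_S = +inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .items import EXT, INT, ItemMeta, DEFAULT_ITEMS

__all__ = ["GroupParameterSet", "factor_index"]


def factor_index(items: Sequence[ItemMeta]) -> np.ndarray:
    """0 for EXT items, 1 for INT items."""
    return np.array([0 if m.factor == EXT else 1 for m in items])


@dataclass
class GroupParameterSet:
    """Loadings, intercepts, thresholds and latent moments for one group.

    Attributes
    ----------
    lam : (n_items,) loading of each item on its dedicated factor.
    nu : (n_items,) item intercepts.
    tau : list of strictly increasing threshold arrays, one per item
        (length ``n_categories - 1``).
    kappa : (2,) factor means (EXT, INT).
    phi : (2, 2) factor covariance, symmetric positive definite.
    psi : (n_items,) error variances (diagonal of Psi), all positive.
    """

    lam: np.ndarray
    nu: np.ndarray
    tau: list[np.ndarray]
    kappa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    items: Sequence[ItemMeta] = DEFAULT_ITEMS

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        self.tau = [np.atleast_1d(np.asarray(t, dtype=float)) for t in self.tau]
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        p = len(self.items)
        if not (len(self.lam) == len(self.nu) == len(self.tau) == len(self.psi) == p):
            raise ValueError("parameter arrays do not match the item count")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("Phi must be symmetric")
        if np.any(np.linalg.eigvalsh(self.phi) <= 0):
            raise ValueError("Phi must be positive definite")
        if np.any(self.psi <= 0):
            raise ValueError("error variances must be positive")
        for m, t in zip(self.items, self.tau):
            if len(t) != m.n_categories - 1:
                raise ValueError(
                    f"item {m.item_id}: expected {m.n_categories - 1} thresholds"
                )
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"item {m.item_id}: thresholds must increase")

    # -- implied moments -------------------------------------------------------

    @property
    def loading_matrix(self) -> np.ndarray:
        """(n_items, 2) loading matrix with the congeneric zero pattern."""
        fidx = factor_index(self.items)
        nf = self.phi.shape[0]
        L = np.zeros((len(self.items), nf))
        L[np.arange(len(self.items)), np.minimum(fidx, nf - 1)] = self.lam
        return L

    def implied_sigma(self) -> np.ndarray:
        """Covariance of the latent propensities, Lambda Phi Lambda' + Psi."""
        L = self.loading_matrix
        return L @ self.phi @ L.T + np.diag(self.psi)

    def implied_mean(self) -> np.ndarray:
        return self.nu + self.loading_matrix @ self.kappa

    def implied_corr(self) -> np.ndarray:
        sigma = self.implied_sigma()
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)

    def implied_standardized_thresholds(self) -> list[np.ndarray]:
        """Thresholds on the scale of the standardised propensity."""
        mu = self.implied_mean()
        sd = np.sqrt(np.diag(self.implied_sigma()))
        return [(t - mu[i]) / sd[i] for i, t in enumerate(self.tau)]

    def copy(self) -> "GroupParameterSet":
        return GroupParameterSet(
            lam=self.lam.copy(),
            nu=self.nu.copy(),
            tau=[t.copy() for t in self.tau],
            kappa=self.kappa.copy(),
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            items=self.items,
        )
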