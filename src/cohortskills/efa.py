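"""Exploratory step: number-of-factors diagnostics and rotated solutions on
the polychoric correlation matrix.

Retention battery: Kaiser's eigenvalue-greater-than-one rule, Horn's
parallel analysis (95th percentile), Velicer's minimum average partial
(MAP), and the optimal-coordinates scree criterion.  Extraction is minimum
residual (ULS); the default rotation is oblimin via gradient projection.
A factor carried by a single item is flagged untestable-for-invariance
rather than rejected: such an item proxies the factor perfectly, leaving
nothing to constrain across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .polychoric import SampleMoments

__all__ = ["EfaSolution", "suggest_n_factors", "efa_fit"]

_METHODS = ("kaiser", "parallel", "map", "scree_oc")


@dataclass
class EfaSolution:
    """Rotated exploratory solution on a polychoric correlation matrix."""

    k: int
    loadings: np.ndarray  # (p, k), rotated
    factor_corr: np.ndarray  # (k, k)
    eigenvalues: np.ndarray  # of the input correlation matrix, descending
    uniquenesses: np.ndarray
    rotation: str
    heywood: bool = False
    single_item_factors: tuple[int, ...] = ()

    @property
    def communalities(self) -> np.ndarray:
        # for oblique solutions: diag(L Phi L')
        return np.einsum(
            "ij,jk,ik->i", self.loadings, self.factor_corr, self.loadings
        )

    def fitted_corr(self) -> np.ndarray:
        C = self.loadings @ self.factor_corr @ self.loadings.T
        return C - np.diag(np.diag(C)) + np.eye(len(C))

    @property
    def untestable_for_invariance(self) -> bool:
        return len(self.single_item_factors) > 0

    def loading_frame(self, item_ids=None) -> pd.DataFrame:
        idx = item_ids if item_ids is not None else range(1, len(self.loadings) + 1)
        df = pd.DataFrame(
            self.loadings,
            index=idx,
            columns=[f"factor_{j + 1}" for j in range(self.k)],
        )
        df.index.name = "item_id"
        return df


def _corr_of(moments: SampleMoments | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(moments, SampleMoments):
        return moments.corr, moments.n
    R = np.asarray(moments, dtype=float)
    return R, 1000


def suggest_n_factors(
    moments: SampleMoments | np.ndarray,
    methods: tuple[str, ...] = _METHODS,
    seed: int = 0,
    n_parallel: int = 100,
) -> dict[str, int]:
    """Retained-factor counts from the requested retention criteria."""
    R, n = _corr_of(moments)
    p = R.shape[0]
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown retention method {m!r}")
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    out: dict[str, int] = {}
    if "kaiser" in methods:
        out["kaiser"] = int((eig > 1.0).sum())
    if "parallel" in methods:
        rng = np.random.default_rng(seed)
        sims = np.empty((n_parallel, p))
        for b in range(n_parallel):
            Z = rng.standard_normal((n, p))
            sims[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
        thresh = np.percentile(sims, 95, axis=0)
        keep = eig > thresh
        out["parallel"] = int(np.argmin(keep)) if not keep.all() else p
    if "map" in methods:
        out["map"] = _velicer_map(R)
    if "scree_oc" in methods:
        out["scree_oc"] = _optimal_coordinates(eig)
    return out


def _velicer_map(R: np.ndarray) -> int:
    p = R.shape[0]
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    avg_sq = []
    # zero components: average squared off-diagonal correlation
    off = R - np.diag(np.diag(R))
    avg_sq.append((off**2).sum() / (p * (p - 1)))
    for m in range(1, p):
        L = vecs[:, :m] * np.sqrt(np.maximum(vals[:m], 0.0))
        resid = R - L @ L.T
        d = np.sqrt(np.clip(np.diag(resid), 1e-10, None))
        partial = resid / np.outer(d, d)
        off = partial - np.diag(np.diag(partial))
        avg_sq.append((off**2).sum() / (p * (p - 1)))
    return int(np.argmin(avg_sq))


def _optimal_coordinates(eig: np.ndarray) -> int:
    """Scree optimal coordinates: retain while eigenvalue exceeds the value
    predicted from a line through the last eigenvalue and the (i+2)-th."""
    p = len(eig)
    keep = 0
    for i in range(p - 2):
        # line through points (i+1, eig[i+1]) and (p-1, eig[p-1])
        slope = (eig[p - 1] - eig[i + 1]) / ((p - 1) - (i + 1))
        pred = eig[i + 1] + slope * (i - (i + 1))
        if eig[i] > pred and eig[i] > 1.0:
            keep += 1
        else:
            break
    return keep


def _minres_extract(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual (ULS) extraction: optimise uniquenesses, then take
    the leading k eigenpairs of the reduced matrix."""
    p = R.shape[0]

    def loadings_given(u: np.ndarray) -> np.ndarray:
        red = R - np.diag(u)
        vals, vecs = np.linalg.eigh(red)
        order = np.argsort(vals)[::-1][:k]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
        return lam

    def objective(u: np.ndarray) -> float:
        lam = loadings_given(u)
        resid = R - lam @ lam.T
        resid = resid - np.diag(np.diag(resid))
        return float((resid**2).sum())

    smc = 1.0 - 1.0 / np.clip(np.diag(np.linalg.inv(R)), 1.0, None)
    u0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        objective, u0, method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * p, options={"maxiter": 500},
    )
    lam = loadings_given(res.x)
    return lam, res.x


def _oblimin_rotate(
    L: np.ndarray, gamma: float = 0.0, max_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique oblimin rotation by gradient projection.

    Returns (rotated loadings, factor correlation matrix).
    """
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)

    def criterion(Lr: np.ndarray) -> tuple[float, np.ndarray]:
        L2 = Lr**2
        N = np.ones((k, k)) - np.eye(k)
        C = np.ones((p, p)) / p
        M = L2 - gamma * C @ L2
        f = 0.25 * float((L2 * (M @ N)).sum())
        G = Lr * ((M @ N))
        return f, G

    T = np.eye(k)
    Ti = np.linalg.inv(T)
    Lr = L @ Ti.T
    f, G = criterion(Lr)
    al = 1.0
    for _ in range(max_iter):
        Gp = -((Lr.T @ G) @ Ti).T  # gradient wrt T for oblique GP
        # project: zero out diagonal scaling directions
        Gproj = Gp - T * np.diag(np.sum(T * Gp, axis=0))
        s = np.sqrt((Gproj**2).sum())
        if s < tol:
            break
        al *= 2
        for _ in range(50):
            Tn = T - al * Gproj
            # renormalise columns of inv(T') rows? standard: scale T columns
            d = np.sqrt(np.sum(Tn**2, axis=0))
            Tn = Tn / d
            try:
                Tni = np.linalg.inv(Tn)
            except np.linalg.LinAlgError:
                al /= 2
                continue
            Lt = L @ Tni.T
            fn, Gn = criterion(Lt)
            if fn < f - 0.5 * s**2 * al * 1e-4:
                T, Ti, Lr, f, G = Tn, Tni, Lt, fn, Gn
                break
            al /= 2
        else:
            break
    phi = T.T @ T
    return Lr, phi


def efa_fit(
    moments: SampleMoments | np.ndarray,
    k: int,
    rotation: str = "oblimin",
) -> EfaSolution:
    """Minres extraction of k factors with optional oblique rotation."""
    if k > 5:
        raise ValueError("k must be at most 5")
    if rotation not in ("oblimin", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    R, _ = _corr_of(moments)
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    L, u = _minres_extract(R, k)
    heywood = bool(np.any(1.0 - u > 1.0 + 1e-6) or np.any((L**2).sum(axis=1) > 1 + 1e-6))
    if rotation == "oblimin" and k > 1:
        Lr, phi = _oblimin_rotate(L)
    else:
        Lr, phi = L, np.eye(k)
    # orient factors positively
    signs = np.sign(Lr.sum(axis=0))
    signs[signs == 0] = 1.0
    Lr = Lr * signs
    phi = phi * np.outer(signs, signs)
    dominant = np.argmax(np.abs(Lr), axis=1)
    salient = np.abs(Lr) > 0.3
    single = tuple(
        int(f) for f in range(k)
        if (salient[:, f] & (dominant == f)).sum() <= 1
    )
    return EfaSolution(
        k=k,
        loadings=Lr,
        factor_corr=phi,
        eigenvalues=eig,
        uniquenesses=u,
        rotation=rotation,
        heywood=heywood,
        single_item_factors=single,
    )
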