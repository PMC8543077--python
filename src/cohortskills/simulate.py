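"""Synthetic two-cohort x two-gender panels with the structure the analysis assumes.

The generator draws, per child: observed covariates (a mix of Bernoulli and
normal family-background variables with cohort-specific parameters), latent
skills theta | covariates (bivariate normal around a covariate-driven mean),
continuous item propensities X* = nu + Lambda theta + u, ordinal responses by
thresholding X*, a per-cohort battery of continuous cognitive measures, and
later outcomes depending on both skills and covariates.

The default specification emulates the published cohort-study setting: two
cohorts (1970 "BCS" and 2000/1 "MCS") split by gender, n = 9545 and 5572 per
cohort, standardised loadings between .5 and .8, 15-25% wider latent-skill
dispersion in the later cohort, and reporting shifts of +/-0.2 on four item
intercepts in the later cohort so that intercept invariance is genuinely
violated while threshold and loading invariance hold.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .items import DEFAULT_GROUPS, DEFAULT_ITEMS, ItemMeta, ItemPanel, item_column
from .params import GroupParameterSet, factor_index

__all__ = [
    "CovariateSpec",
    "OutcomeSpec",
    "GeneratorSpec",
    "generate_panel",
    "inject_noninvariance",
    "paper_like_spec",
    "measurement_only_spec",
    "category_probabilities",
]


@dataclass
class CovariateSpec:
    """Per-group covariate distributions.

    ``bernoulli``: name -> success probability; ``normal``: name -> (mean, sd).
    """

    bernoulli: dict[str, float] = field(default_factory=dict)
    normal: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.bernoulli) + list(self.normal)

    def means(self) -> dict[str, float]:
        out = dict(self.bernoulli)
        out.update({k: v[0] for k, v in self.normal.items()})
        return out


@dataclass
class OutcomeSpec:
    """Linear (or latent-probit) outcome model on skills and covariates."""

    kind: str  # "linear" or "probit"
    intercept: float = 0.0
    coef_theta: tuple[float, float] = (0.0, 0.0)  # (EXT, INT)
    coef_cog: float = 0.0
    coef_cov: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0


@dataclass
class GeneratorSpec:
    """Full data-generating specification for a multi-group ordinal panel."""

    items: Sequence[ItemMeta] = DEFAULT_ITEMS
    groups: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: dict[str, int] = field(default_factory=dict)
    measurement: dict[str, GroupParameterSet] = field(default_factory=dict)
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    #: per-group {factor ("EXT"/"INT") -> {covariate -> coefficient}}; the
    #: covariates enter centred at their group means, so ``kappa`` stays the
    #: marginal factor mean.
    structural: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    #: cognitive factor: coefficients on (EXT, INT), covariate effects,
    #: residual sd, and loadings/noise of the continuous measures.
    cognitive: dict | None = None

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in self.group_sizes:
                raise ValueError(f"group {g!r} has no size")
            if g not in self.measurement:
                raise ValueError(f"group {g!r} has no measurement parameters")

    def copy(self) -> "GeneratorSpec":
        return copy.deepcopy(self)

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def gps_dict(p: GroupParameterSet) -> dict:
            return {
                "lam": p.lam.tolist(),
                "nu": p.nu.tolist(),
                "tau": [t.tolist() for t in p.tau],
                "kappa": p.kappa.tolist(),
                "phi": p.phi.tolist(),
                "psi": p.psi.tolist(),
            }

        return {
            "items": [
                {
                    "item_id": m.item_id,
                    "title": m.title,
                    "factor": m.factor,
                    "n_categories": m.n_categories,
                    "positively_worded": m.positively_worded,
                }
                for m in self.items
            ],
            "groups": list(self.groups),
            "group_sizes": dict(self.group_sizes),
            "measurement": {g: gps_dict(p) for g, p in self.measurement.items()},
            "covariates": {
                g: {"bernoulli": c.bernoulli, "normal": {k: list(v) for k, v in c.normal.items()}}
                for g, c in self.covariates.items()
            },
            "structural": self.structural,
            "outcomes": {
                k: {
                    "kind": o.kind,
                    "intercept": o.intercept,
                    "coef_theta": list(o.coef_theta),
                    "coef_cog": o.coef_cog,
                    "coef_cov": o.coef_cov,
                    "noise_sd": o.noise_sd,
                }
                for k, o in self.outcomes.items()
            },
            "cognitive": self.cognitive,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorSpec":
        items = tuple(ItemMeta(**m) for m in d["items"])
        measurement = {
            g: GroupParameterSet(items=items, **p) for g, p in d["measurement"].items()
        }
        covariates = {
            g: CovariateSpec(
                bernoulli=dict(c.get("bernoulli", {})),
                normal={k: tuple(v) for k, v in c.get("normal", {}).items()},
            )
            for g, c in d.get("covariates", {}).items()
        }
        outcomes = {
            k: OutcomeSpec(
                kind=o["kind"],
                intercept=o.get("intercept", 0.0),
                coef_theta=tuple(o.get("coef_theta", (0.0, 0.0))),
                coef_cog=o.get("coef_cog", 0.0),
                coef_cov=dict(o.get("coef_cov", {})),
                noise_sd=o.get("noise_sd", 1.0),
            )
            for k, o in d.get("outcomes", {}).items()
        }
        return cls(
            items=items,
            groups=tuple(d["groups"]),
            group_sizes=dict(d["group_sizes"]),
            measurement=measurement,
            covariates=covariates,
            structural=d.get("structural", {}),
            outcomes=outcomes,
            cognitive=d.get("cognitive"),
        )

    def true_parameters_json(self) -> str:
        """Sidecar JSON of the true parameters, for recovery tests."""
        return json.dumps(self.to_dict(), indent=1)


def category_probabilities(gps: GroupParameterSet) -> list[np.ndarray]:
    """Closed-form marginal category probabilities per item (probit integral)."""
    std_tau = gps.implied_standardized_thresholds()
    out = []
    for t in std_tau:
        cum = np.concatenate(([0.0], norm.cdf(t), [1.0]))
        out.append(np.diff(cum))
    return out


def _draw_covariates(
    cov: CovariateSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    data = {}
    for name, p in cov.bernoulli.items():
        data[name] = rng.binomial(1, p, size=n).astype(float)
    for name, (mean, sd) in cov.normal.items():
        data[name] = rng.normal(mean, sd, size=n)
    return pd.DataFrame(data)


def generate_panel(
    spec: GeneratorSpec, seed: int, return_latent: bool = False
) -> ItemPanel | tuple[ItemPanel, dict]:
    """Draw a complete multi-group panel; deterministic given the seed.

    With ``return_latent=True`` additionally returns, per group, the latent
    skills ``theta`` and pre-discretisation propensities ``xstar`` (a debug
    view used to check the implied-moment structure).
    """
    rng = np.random.default_rng(seed)
    fidx = factor_index(spec.items)
    frames = []
    latent: dict[str, dict[str, np.ndarray]] = {}
    offset = 0
    for g in spec.groups:
        n = spec.group_sizes[g]
        gps = spec.measurement[g]
        covspec = spec.covariates.get(g, CovariateSpec())
        X = _draw_covariates(covspec, n, rng)

        # factor means: kappa + centred covariate effects
        mean = np.tile(gps.kappa, (n, 1))
        struct = spec.structural.get(g, {})
        if struct and len(X.columns):
            mu = covspec.means()
            for fi, fname in enumerate(("EXT", "INT")):
                for cname, beta in struct.get(fname, {}).items():
                    mean[:, fi] += beta * (X[cname].to_numpy() - mu[cname])
        chol = np.linalg.cholesky(gps.phi)
        theta = mean + rng.standard_normal((n, 2)) @ chol.T

        lam_theta = theta[:, fidx] * gps.lam
        xstar = gps.nu + lam_theta + rng.standard_normal((n, len(spec.items))) * np.sqrt(
            gps.psi
        )
        codes = np.zeros_like(xstar, dtype=np.int64)
        for i, t in enumerate(gps.tau):
            codes[:, i] = np.searchsorted(t, xstar[:, i], side="right")

        frame = pd.DataFrame(
            codes, columns=[item_column(m.item_id) for m in spec.items]
        )
        frame.insert(0, "group", g)
        frame.insert(0, "child_id", np.arange(offset, offset + n))
        frame = pd.concat([frame, X.reset_index(drop=True)], axis=1)

        # cognitive measures (per-cohort scale, not cross-cohort comparable)
        cog_theta = None
        if spec.cognitive:
            c = spec.cognitive
            cog_theta = (
                c.get("coef_theta", (0.0, 0.0))[0] * (theta[:, 0] - mean[:, 0].mean())
                + c.get("coef_theta", (0.0, 0.0))[1] * (theta[:, 1] - mean[:, 1].mean())
                + rng.normal(0.0, c.get("resid_sd", 1.0), size=n)
            )
            for cname, beta in c.get("coef_cov", {}).items():
                if cname in X.columns:
                    cog_theta += beta * (X[cname].to_numpy() - covspec.means()[cname])
            for j, load in enumerate(c.get("loadings", (0.8, 0.7, 0.6, 0.7))):
                frame[f"cog_m{j + 1}"] = load * cog_theta + rng.normal(
                    0.0, c.get("measure_sd", 0.6), size=n
                )

        for oname, om in spec.outcomes.items():
            lin = (
                om.intercept
                + om.coef_theta[0] * theta[:, 0]
                + om.coef_theta[1] * theta[:, 1]
            )
            if om.coef_cog and cog_theta is not None:
                lin = lin + om.coef_cog * cog_theta
            for cname, beta in om.coef_cov.items():
                if cname in X.columns:
                    lin = lin + beta * X[cname].to_numpy()
            if om.kind == "probit":
                frame[oname] = (
                    lin + rng.standard_normal(n) > 0
                ).astype(float)
            else:
                frame[oname] = lin + rng.normal(0.0, om.noise_sd, size=n)

        frames.append(frame)
        if return_latent:
            latent[g] = {"theta": theta, "xstar": xstar}
        offset += n

    data = pd.concat(frames, ignore_index=True)
    item_cols = {item_column(m.item_id) for m in spec.items}
    extra = tuple(
        c for c in data.columns if c not in item_cols and c not in ("child_id", "group")
    )
    panel = ItemPanel(
        data=data, items=spec.items, n_dropped=0, covariate_columns=extra
    )
    if return_latent:
        return panel, latent
    return panel


def inject_noninvariance(
    spec: GeneratorSpec,
    target_group: str,
    intercept_shift: Mapping[int, float] | None = None,
    loading_scale: Mapping[int, float] | None = None,
) -> GeneratorSpec:
    """Return a new spec whose target group has shifted nu (and scaled lambda).

    Simulates group-specific reporting behaviour as intercept (and optionally
    loading) non-invariance.  Only the target group's parameters change.
    """
    if target_group not in spec.groups:
        raise ValueError(f"unknown group {target_group!r}")
    declared = {m.item_id for m in spec.items}
    new = spec.copy()
    gps = new.measurement[target_group]
    for item_id, shift in (intercept_shift or {}).items():
        if item_id not in declared:
            raise ValueError(f"intercept shift on undeclared item {item_id}")
        gps.nu[item_id - 1] += shift
    for item_id, scale in (loading_scale or {}).items():
        if item_id not in declared:
            raise ValueError(f"loading scale on undeclared item {item_id}")
        gps.lam[item_id - 1] *= scale
    return new


# ---------------------------------------------------------------------------
# Default specifications
# ---------------------------------------------------------------------------

#: standardised loadings in the reference group, in the .5-.8 band
_STD_LOADINGS = np.array(
    [0.70, 0.65, 0.55, 0.60, 0.55, 0.60, 0.65, 0.60, 0.50, 0.70, 0.55]
)

#: reference-group thresholds chosen to give realistic category prevalences
#: (a minority of children in the problem categories; binary "applies" rates
#: between roughly .2 and .4)
_TAUS = [
    np.array([-1.10, -0.25]),
    np.array([-0.95, -0.10]),
    np.array([-1.40, -0.55]),
    np.array([-0.85, 0.05]),
    np.array([-0.30]),
    np.array([-0.45]),
    np.array([-1.25, -0.35]),
    np.array([-1.00, -0.15]),
    np.array([-1.20, -0.30]),
    np.array([-1.50, -0.60]),
    np.array([-0.70]),
]

#: reporting shifts of the later cohort: after recoding, the "distracted" and
#: "tantrums" items are reported as worse, "worried" and "unhappy" as better
_MCS_INTERCEPT_SHIFTS = {4: -0.2, 5: -0.2, 7: 0.2, 10: 0.2}

#: factor-mean effects of family background, signed as in the determinants
#: regressions (maternal education and birthweight positive, smoking in
#: pregnancy and absent father negative; employment matters more in the
#: later cohort)
_STRUCT_BCS = {
    "EXT": {
        "mother_educ": 0.09, "mother_employed": 0.02, "blue_collar": -0.18,
        "no_father": -0.28, "mother_age": 0.014, "unmarried": 0.06,
        "nonwhite": -0.12, "firstborn": -0.11, "smoked_pregnancy": -0.14,
        "log_birthweight": 0.15,
    },
    "INT": {
        "mother_educ": 0.07, "mother_employed": 0.04, "blue_collar": -0.08,
        "no_father": -0.20, "mother_age": 0.008, "unmarried": 0.10,
        "nonwhite": 0.02, "firstborn": -0.17, "smoked_pregnancy": -0.07,
        "log_birthweight": 0.10,
    },
}
_STRUCT_MCS = {
    "EXT": {
        "mother_educ": 0.12, "mother_employed": 0.13, "blue_collar": -0.10,
        "no_father": -0.20, "mother_age": 0.013, "unmarried": -0.13,
        "nonwhite": -0.22, "firstborn": -0.01, "smoked_pregnancy": -0.22,
        "log_birthweight": 0.30,
    },
    "INT": {
        "mother_educ": 0.08, "mother_employed": 0.16, "blue_collar": -0.07,
        "no_father": -0.17, "mother_age": 0.012, "unmarried": -0.03,
        "nonwhite": -0.14, "firstborn": -0.07, "smoked_pregnancy": -0.15,
        "log_birthweight": 0.20,
    },
}

_COV_BCS = CovariateSpec(
    bernoulli={
        "mother_educ": 0.38, "mother_employed": 0.42, "blue_collar": 0.61,
        "no_father": 0.05, "unmarried": 0.05, "nonwhite": 0.03,
        "firstborn": 0.38, "smoked_pregnancy": 0.39,
    },
    normal={"mother_age": (25.9, 5.35), "log_birthweight": (1.185, 0.16)},
)
_COV_MCS = CovariateSpec(
    bernoulli={
        "mother_educ": 0.57, "mother_employed": 0.62, "blue_collar": 0.41,
        "no_father": 0.17, "unmarried": 0.36, "nonwhite": 0.11,
        "firstborn": 0.42, "smoked_pregnancy": 0.20,
    },
    normal={"mother_age": (29.4, 5.67), "log_birthweight": (1.206, 0.17)},
)

DEFAULT_COVARIATE_NAMES: tuple[str, ...] = tuple(_COV_BCS.names)


def _group_params(
    factor_sds: tuple[float, float],
    factor_corr: float,
    nu_shift: Mapping[int, float] | None,
    items: Sequence[ItemMeta],
) -> GroupParameterSet:
    lam = _STD_LOADINGS.copy()
    psi = 1.0 - lam**2  # unit propensity variance in the reference scaling
    nu = np.zeros(len(items))
    for item_id, shift in (nu_shift or {}).items():
        nu[item_id - 1] = shift
    sds = np.asarray(factor_sds)
    phi = np.outer(sds, sds) * np.array([[1.0, factor_corr], [factor_corr, 1.0]])
    return GroupParameterSet(
        lam=lam,
        nu=nu,
        tau=[t.copy() for t in _TAUS],
        kappa=np.zeros(2),
        phi=phi,
        psi=psi,
        items=items,
    )


def paper_like_spec(
    intercept_shifts: bool = True,
    covariate_effects: bool = True,
    outcomes: bool = True,
    size_scale: float = 1.0,
    factor_corr: float = 0.35,
) -> GeneratorSpec:
    """The default study-like specification.

    Four groups (two cohorts x two genders, sizes 9545 and 5572 per cohort),
    invariant loadings and thresholds, later-cohort factor SDs 20% (EXT) and
    18% (INT) larger, and — unless disabled — intercept shifts of +/-0.2 on
    four items in the later cohort, covariate-dependent factor means, and
    outcomes driven by skills and covariates.  ``size_scale`` shrinks all
    group sizes proportionally (used by small simulation studies).
    """
    items = DEFAULT_ITEMS
    sizes = {"BCS_M": 4773, "BCS_F": 4772, "MCS_M": 2786, "MCS_F": 2786}
    sizes = {g: max(50, int(round(n * size_scale))) for g, n in sizes.items()}
    shifts = _MCS_INTERCEPT_SHIFTS if intercept_shifts else None
    measurement = {
        "BCS_M": _group_params((1.0, 1.0), factor_corr, None, items),
        "BCS_F": _group_params((1.0, 1.0), factor_corr, None, items),
        "MCS_M": _group_params((1.20, 1.18), factor_corr, shifts, items),
        "MCS_F": _group_params((1.20, 1.18), factor_corr, shifts, items),
    }
    covariates = {
        "BCS_M": _COV_BCS, "BCS_F": _COV_BCS, "MCS_M": _COV_MCS, "MCS_F": _COV_MCS,
    }
    structural = {}
    if covariate_effects:
        structural = {
            "BCS_M": _STRUCT_BCS, "BCS_F": _STRUCT_BCS,
            "MCS_M": _STRUCT_MCS, "MCS_F": _STRUCT_MCS,
        }
    outcome_specs: dict[str, OutcomeSpec] = {}
    cognitive = None
    if outcomes:
        cognitive = {
            "coef_theta": (0.30, 0.15),
            "coef_cov": {"mother_educ": 0.30, "blue_collar": -0.15},
            "resid_sd": 0.85,
            "loadings": (0.8, 0.7, 0.6, 0.7),
            "measure_sd": 0.6,
        }
        outcome_specs = {
            "tried_smoking": OutcomeSpec(
                kind="probit", intercept=-0.6,
                coef_theta=(-0.20, 0.10), coef_cog=0.0,
                coef_cov={"smoked_pregnancy": 0.35, "mother_educ": -0.15},
            ),
            "bmi": OutcomeSpec(
                kind="linear", intercept=20.9,
                coef_theta=(-0.35, 0.15), coef_cog=-0.05,
                coef_cov={"mother_educ": -0.20, "log_birthweight": 1.50},
                noise_sd=2.8,
            ),
            "higher_education": OutcomeSpec(
                kind="probit", intercept=-0.3,
                coef_theta=(0.08, -0.04), coef_cog=0.30,
                coef_cov={"mother_educ": 0.40, "blue_collar": -0.25},
            ),
            "log_pay": OutcomeSpec(
                kind="linear", intercept=6.1,
                coef_theta=(0.05, -0.03), coef_cog=0.10,
                coef_cov={"mother_educ": 0.12, "blue_collar": -0.10},
                noise_sd=0.55,
            ),
        }
    return GeneratorSpec(
        items=items,
        groups=DEFAULT_GROUPS,
        group_sizes=sizes,
        measurement=measurement,
        covariates=covariates,
        structural=structural,
        outcomes=outcome_specs,
        cognitive=cognitive,
    )


def measurement_only_spec(
    invariant: bool = True,
    size_scale: float = 1.0,
    factor_corr: float = 0.35,
) -> GeneratorSpec:
    """Measurement model alone (no covariate effects on skills, no outcomes).

    Latent skills are then exactly bivariate normal within each group, i.e.
    the data are drawn exactly from the fitted model; used for parameter
    recovery and test-calibration studies.
    """
    return paper_like_spec(
        intercept_shifts=not invariant,
        covariate_effects=False,
        outcomes=False,
        size_scale=size_scale,
        factor_corr=factor_corr,
    )
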