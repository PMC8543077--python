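"""Synthetic cohort generator: sizes, determinism, moments, non-invariance."""

import numpy as np
import pytest
from scipy.stats import norm

from cohortskills.params import GroupParameterSet
from cohortskills.polychoric import polychoric_corr
from cohortskills.simulate import (
    GeneratorSpec,
    category_probabilities,
    generate_panel,
    inject_noninvariance,
    measurement_only_spec,
    paper_like_spec,
)


def test_default_cohort_sizes_match_study():
    """Default spec emits the study sample sizes: 9545 BCS, 5572 MCS."""
    spec = paper_like_spec()
    sizes = spec.group_sizes
    assert sizes["BCS_M"] + sizes["BCS_F"] == 9545
    assert sizes["MCS_M"] + sizes["MCS_F"] == 5572
    panel = generate_panel(spec, seed=3)
    assert panel.group_sizes() == sizes


def test_identical_seeds_identical_panels():
    spec = measurement_only_spec(size_scale=0.05)
    a = generate_panel(spec, seed=9).data
    b = generate_panel(spec, seed=9).data
    assert a.equals(b)
    c = generate_panel(spec, seed=10).data
    assert not a.equals(c)


def test_spec_roundtrips_through_serialisation():
    spec = paper_like_spec(size_scale=0.05)
    back = GeneratorSpec.from_dict(spec.to_dict())
    a = generate_panel(spec, seed=4).data
    b = generate_panel(back, seed=4).data
    assert a.equals(b)


def test_nonpd_phi_rejected():
    spec = measurement_only_spec(size_scale=0.05)
    gps = spec.measurement["BCS_M"]
    with pytest.raises(ValueError, match="positive definite"):
        GroupParameterSet(
            lam=gps.lam, nu=gps.nu, tau=gps.tau, kappa=gps.kappa,
            phi=np.array([[1.0, 1.2], [1.2, 1.0]]), psi=gps.psi,
        )


def test_inject_noninvariance_zero_shift_is_identity():
    spec = measurement_only_spec(size_scale=0.05)
    out = inject_noninvariance(spec, "MCS_M", intercept_shift={1: 0.0})
    for g in spec.groups:
        assert np.allclose(out.measurement[g].nu, spec.measurement[g].nu)
        assert np.allclose(out.measurement[g].lam, spec.measurement[g].lam)


def test_inject_noninvariance_shift_matches_probit_change():
    """+0.5 intercept on item 1 raises its top-category rate by the normal-CDF
    difference, in the target group only."""
    spec = measurement_only_spec(size_scale=0.05)
    shifted = inject_noninvariance(spec, "MCS_M", intercept_shift={1: 0.5})
    p0 = category_probabilities(spec.measurement["MCS_M"])[0]
    p1 = category_probabilities(shifted.measurement["MCS_M"])[0]
    assert p1[-1] > p0[-1]
    # closed form: top-category probability is 1 - Phi((tau2 - nu)/sd)
    gps = spec.measurement["MCS_M"]
    sd = np.sqrt(gps.implied_sigma()[0, 0])
    tau2 = gps.tau[0][-1]
    expected = norm.sf((tau2 - 0.5) / sd) - norm.sf(tau2 / sd)
    assert abs((p1[-1] - p0[-1]) - expected) < 1e-12
    # untouched group unchanged
    pu = category_probabilities(shifted.measurement["BCS_M"])[0]
    assert np.allclose(pu, category_probabilities(spec.measurement["BCS_M"])[0])


def test_inject_noninvariance_undeclared_item_errors():
    spec = measurement_only_spec(size_scale=0.05)
    with pytest.raises(ValueError, match="undeclared item"):
        inject_noninvariance(spec, "MCS_M", intercept_shift={12: 0.1})
    with pytest.raises(ValueError, match="unknown group"):
        inject_noninvariance(spec, "NOPE", intercept_shift={1: 0.1})


def test_latent_moments_converge_to_implied():
    """Cov of pre-discretisation propensities matches Lambda Phi Lambda' + Psi."""
    spec = measurement_only_spec()
    spec.group_sizes = {g: (100_000 if g == "BCS_M" else 300) for g in spec.groups}
    _, latent = generate_panel(spec, seed=11, return_latent=True)
    xstar = latent["BCS_M"]["xstar"]
    implied = spec.measurement["BCS_M"].implied_sigma()
    err = np.linalg.norm(np.cov(xstar, rowvar=False) - implied, ord="fro")
    # delta-method oracle for the expected Frobenius error of a normal
    # sample covariance: sum of Var(sigma_ij) = (sig_ii sig_jj + sig_ij^2)/n
    n = 100_000
    var_sum = (np.outer(np.diag(implied), np.diag(implied)) + implied**2).sum() / n
    assert err < 2.0 * np.sqrt(var_sum)


def test_zero_loading_item_independent_of_factor():
    """With lambda_1 = 0, item 1 is uncorrelated with theta-driven items."""
    spec = measurement_only_spec()
    spec.group_sizes = {g: (20_000 if g == "BCS_M" else 300) for g in spec.groups}
    spec.measurement["BCS_M"].lam[0] = 0.0
    panel = generate_panel(spec, seed=13)
    X = panel.responses("BCS_M")
    gmax = 3
    table = np.bincount(X[:, 0] * gmax + X[:, 1], minlength=9).reshape(3, 3)
    rho = polychoric_corr(table)
    assert abs(rho) < 3 * (1.0 / np.sqrt(20_000)) * 1.7  # ~3 SE of a polychoric
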