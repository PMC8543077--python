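"""RIF values, propensity reweighting and the four-component decomposition."""

import numpy as np
import pytest

from cohortskills.rif import RIFDecompositionModel, reweight, rif_values


def test_mean_of_rif_recovers_statistic():
    rng = np.random.default_rng(0)
    y = rng.gamma(2.0, 1.0, 5000)
    for stat, target in [
        ("q90-q10", np.quantile(y, 0.9) - np.quantile(y, 0.1)),
        ("q75-q25", np.quantile(y, 0.75) - np.quantile(y, 0.25)),
        ("variance", y.var()),
    ]:
        r = rif_values(y, stat)
        tol = 1e-12 if stat == "variance" else 1e-6 * (y.max() - y.min())
        assert abs(r.mean() - target) <= tol


def test_median_rif_of_standard_normal_is_two_point_masses():
    """1/f(0) = sqrt(2 pi), so RIF values sit near +/- 1.2533 around q50."""
    rng = np.random.default_rng(1)
    y = rng.standard_normal(200_000)
    r = rif_values(y, "q50")
    vals = np.unique(np.round(r - np.median(r), 3))
    assert len(vals) == 2
    assert abs(abs(vals).mean() - np.sqrt(2 * np.pi) / 2) < 0.02


def test_variance_rif_of_constant_is_zero():
    assert np.allclose(rif_values(np.full(500, 3.3), "variance"), 0.0)


def test_quantile_rif_needs_enough_data():
    with pytest.raises(ValueError, match="n >= 100"):
        rif_values(np.arange(50.0), "q90-q10")


def test_reweight_identity_when_distributions_match():
    rng = np.random.default_rng(2)
    Xs = np.column_stack([rng.binomial(1, 0.4, 10_000), rng.normal(0, 1, 10_000)])
    Xt = np.column_stack([rng.binomial(1, 0.4, 10_000), rng.normal(0, 1, 10_000)])
    w = reweight(Xs, Xt)
    assert abs(w.mean() - 1.0) < 1e-9
    assert np.abs(w - 1.0).max() < 0.1


def test_reweight_balances_covariate_means():
    rng = np.random.default_rng(3)
    n = 8000
    Xs = np.column_stack([rng.binomial(1, 0.3, n), rng.normal(0.0, 1, n)])
    Xt = np.column_stack([rng.binomial(1, 0.6, n), rng.normal(0.4, 1, n)])
    w = reweight(Xs, Xt)
    for j in range(2):
        target = Xt[:, j].mean()
        got = np.average(Xs[:, j], weights=w)
        se = 3 * Xt[:, j].std() / np.sqrt(n)
        assert abs(got - target) < 3 * se


def test_reweight_single_binary_covariate_closed_form():
    """With one binary covariate the normalised weight is the probability
    ratio P_target(x) / P_source(x)."""
    rng = np.random.default_rng(4)
    n = 40_000
    xs = rng.binomial(1, 0.3, n)
    xt = rng.binomial(1, 0.6, n)
    w = reweight(xs[:, None].astype(float), xt[:, None].astype(float))
    ps, pt = xs.mean(), xt.mean()
    np.testing.assert_allclose(w[xs == 1].mean(), pt / ps, rtol=1e-6)
    np.testing.assert_allclose(w[xs == 0].mean(), (1 - pt) / (1 - ps), rtol=1e-6)


def test_reweight_perfect_separation_errors():
    Xs = np.zeros((200, 1))
    Xt = np.ones((200, 1))
    with pytest.raises(ValueError):
        reweight(Xs, Xt)


def _dgp(rng, n, p_d, beta=1.2):
    d = rng.binomial(1, p_d, n).astype(float)
    x = rng.normal(0, 1, n)
    y = beta * d + 0.3 * x + rng.standard_normal(n)
    return y, np.column_stack([d, x])


def test_null_decomposition_components_near_zero():
    rng = np.random.default_rng(5)
    ys, Xs = _dgp(rng, 6000, 0.4)
    yt, Xt = _dgp(rng, 6000, 0.4)
    res = RIFDecompositionModel(ys, Xs, yt, Xt, ["d", "x"], "q90-q10").fit(
        bootstrap=150, seed=9
    )
    for comp in ("composition", "coefficient", "specification_error",
                 "reweighting_error"):
        val = res.components[comp]
        assert abs(val) < 3.5 * res.se[comp] + 1e-12


def _hetero_dgp(rng, n, p_d):
    """Covariate moves the spread, not the location: the variance RIF is
    exactly linear in the binary covariate, so a composition-only change is
    fully attributable."""
    d = rng.binomial(1, p_d, n).astype(float)
    x = rng.normal(0, 1, n)
    y = (1.0 + 0.5 * d) * rng.standard_normal(n) + 0.1 * x
    return y, np.column_stack([d, x])


def test_composition_only_change_attributed_to_composition():
    """Groups differing only in a covariate distribution: the composition
    effect carries the change; errors are within CI of zero."""
    rng = np.random.default_rng(6)
    ys, Xs = _hetero_dgp(rng, 10_000, 0.2)
    yt, Xt = _hetero_dgp(rng, 10_000, 0.6)
    res = RIFDecompositionModel(ys, Xs, yt, Xt, ["d", "x"], "variance").fit(
        bootstrap=150, seed=10
    )
    assert res.total > 0
    assert res.composition / res.total > 0.7
    for comp in ("specification_error", "reweighting_error"):
        assert abs(res.components[comp]) < 3.5 * res.se[comp] + 1e-12
    # the covariate that changed drives the composition detail
    det = res.detail
    comp_d = det[(det.component == "composition") & (det.covariate == "d")]
    comp_x = det[(det.component == "composition") & (det.covariate == "x")]
    assert abs(comp_d["value"].iloc[0]) > 10 * abs(comp_x["value"].iloc[0])


def test_adding_up_and_detail_sums_exact():
    rng = np.random.default_rng(7)
    ys, Xs = _dgp(rng, 3000, 0.3)
    yt, Xt = _dgp(rng, 3000, 0.5, beta=1.6)
    for stat in ("q90-q10", "q50-q10", "variance"):
        res = RIFDecompositionModel(ys, Xs, yt, Xt, ["d", "x"], stat).fit()
        lhs = res.total
        rhs = (res.composition + res.specification_error + res.coefficient
               + res.reweighting_error)
        assert abs(lhs - rhs) < 1e-10
        det = res.detail
        assert abs(det[det.component == "composition"]["value"].sum()
                   - res.composition) < 1e-10
        assert abs(det[det.component == "coefficient"]["value"].sum()
                   - res.coefficient) < 1e-10


def test_bootstrap_deterministic():
    rng = np.random.default_rng(8)
    ys, Xs = _dgp(rng, 2000, 0.3)
    yt, Xt = _dgp(rng, 2000, 0.5)
    m = RIFDecompositionModel(ys, Xs, yt, Xt, ["d", "x"], "q90-q50")
    a = m.fit(bootstrap=100, seed=3)
    b = m.fit(bootstrap=100, seed=3)
    assert a.se == b.se


def test_collinear_covariates_rejected():
    rng = np.random.default_rng(9)
    ys, Xs = _dgp(rng, 500, 0.3)
    X2 = np.column_stack([Xs, Xs[:, 0] * 2.0])
    with pytest.raises(ValueError, match="collinear"):
        RIFDecompositionModel(ys, X2, ys, X2, ["d", "x", "d2"], "variance")
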