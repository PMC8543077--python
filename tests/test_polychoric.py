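"""Polychoric thresholds, correlations and asymptotic covariance."""

import numpy as np
import pytest
from scipy.stats import norm

from cohortskills.items import ItemPanel, item_column
from cohortskills.polychoric import (
    estimate_thresholds,
    polychoric_corr,
    sample_moments,
)
from cohortskills.simulate import generate_panel, measurement_only_spec


def grid_oracle_rho(table, thresholds, grid_step=0.001):
    """Independent brute-force grid maximiser of the bivariate-normal
    multinomial likelihood, with rectangle probabilities by 1-D quadrature
    of phi(x) * [Phi((k2-rho x)/s) - Phi((k1-rho x)/s)]."""
    rhos = np.arange(-0.999, 0.9991, grid_step)
    H = np.concatenate(([-7.0], thresholds[0], [7.0]))
    K = np.concatenate(([-7.0], thresholds[1], [7.0]))
    s = np.sqrt(1 - rhos**2)
    ll = np.zeros_like(rhos)
    for a in range(len(H) - 1):
        x = np.linspace(H[a], H[a + 1], 160)
        fx = norm.pdf(x)
        for b in range(len(K) - 1):
            if table[a, b] == 0:
                continue
            up = norm.cdf((K[b + 1] - rhos[:, None] * x) / s[:, None])
            lo = norm.cdf((K[b] - rhos[:, None] * x) / s[:, None])
            p = np.trapezoid(fx * (up - lo), x, axis=1)
            ll += table[a, b] * np.log(np.maximum(p, 1e-300))
    return rhos[np.argmax(ll)]


def test_threshold_examples():
    """Inverse-normal-CDF of cumulative proportions."""
    assert abs(estimate_thresholds([50, 50])[0]) < 1e-12
    t = estimate_thresholds([1587, 6826, 1587])
    assert np.allclose(t, [-1.0, 1.0], atol=2e-3)
    t = estimate_thresholds([25, 75])
    assert abs(t[0] - norm.ppf(0.25)) < 1e-12
    with pytest.raises(ValueError, match="degenerate"):
        estimate_thresholds([100, 0, 0])


def test_threshold_equivariance_under_category_reversal():
    """Reversing category labels negates and reverses the thresholds."""
    counts = np.array([200, 500, 300])
    t = estimate_thresholds(counts)
    t_rev = estimate_thresholds(counts[::-1])
    assert np.allclose(t_rev, -t[::-1], atol=1e-12)


def test_independence_table_gives_zero_rho():
    rows = np.array([30_000, 50_000, 20_000])
    cols = np.array([40_000, 60_000])
    table = np.outer(rows, cols) / (rows.sum())
    assert abs(polychoric_corr(table)) < 0.01


def test_recovers_known_rho_from_simulated_binary_pair():
    rng = np.random.default_rng(0)
    z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10_000)
    x = (z[:, 0] > 0).astype(int)
    y = (z[:, 1] > 0.3).astype(int)
    table = np.bincount(x * 2 + y, minlength=4).reshape(2, 2)
    assert abs(polychoric_corr(table) - 0.5) < 0.05


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_matches_grid_search_oracle(seed):
    """ML estimate equals the 0.001-step grid maximiser within 1e-3."""
    rng = np.random.default_rng(seed)
    rho_true = rng.uniform(-0.8, 0.8)
    z = rng.multivariate_normal([0, 0], [[1, rho_true], [rho_true, 1]], 1500)
    x = np.digitize(z[:, 0], [-0.8, 0.4])
    y = np.digitize(z[:, 1], [-0.3])
    table = np.bincount(x * 2 + y, minlength=6).reshape(3, 2).astype(float)
    thr = (
        estimate_thresholds(table.sum(axis=1)),
        estimate_thresholds(table.sum(axis=0)),
    )
    rho = polychoric_corr(table, thresholds=thr)
    oracle = grid_oracle_rho(table, thr)
    assert abs(rho - oracle) <= 1.1e-3


def test_degenerate_table_errors():
    with pytest.raises(ValueError, match="inestimable"):
        polychoric_corr(np.array([[100, 200], [0, 0]]))


def test_sample_moments_structure_and_psd(two_group_moments):
    m = two_group_moments["BCS_M"]
    assert m.corr.shape == (11, 11)
    assert np.allclose(m.corr, m.corr.T)
    assert np.all(np.diag(m.corr) == 1.0)
    assert m.acov.shape == (74, 74)
    assert np.linalg.eigvalsh(m.acov).min() > -1e-8
    assert len(m.stack()) == 74
    assert len(m.labels()) == 74


def test_invariant_groups_agree_within_3se(two_group_moments):
    """Same-parameter groups give moments equal within sampling error."""
    a, b = two_group_moments["BCS_M"], two_group_moments["MCS_M"]
    # thresholds and loadings/taus equal across these groups; only factor
    # covariance differs, which changes correlations -- compare thresholds
    sa = np.concatenate(a.thresholds)
    sb = np.concatenate(b.thresholds)
    se = np.sqrt(np.diag(a.acov)[:19] / a.n + np.diag(b.acov)[:19] / b.n)
    assert np.all(np.abs(sa - sb) < 3.8 * se)


def test_asymptotic_variance_scales_as_one_over_n():
    spec = measurement_only_spec()
    spec.group_sizes = {g: 300 for g in spec.groups}
    spec.group_sizes["BCS_M"] = 5000
    spec.group_sizes["BCS_F"] = 10000
    panel = generate_panel(spec, seed=21)
    m1 = sample_moments(panel, "BCS_M")
    m2 = sample_moments(panel, "BCS_F")
    v1 = np.diag(m1.acov) / m1.n
    v2 = np.diag(m2.acov) / m2.n
    ratio = np.median(v2 / v1)
    assert 0.4 < ratio < 0.6


def test_duplicated_item_flagged_near_singular(two_group_moments, invariant_panel):
    """A duplicated column drives rho to the boundary and is flagged."""
    df = invariant_panel.data.copy()
    df[item_column(2)] = df[item_column(1)]
    panel = ItemPanel(data=df, items=invariant_panel.items)
    m = sample_moments(panel, "BCS_M")
    assert (0, 1) in m.near_singular_pairs
    assert m.corr[0, 1] > 0.99
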