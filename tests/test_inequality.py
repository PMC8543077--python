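"""Quantile gaps, bootstrap intervals, KS tests and covariate gap tables."""

import numpy as np
import pandas as pd
import pytest

from cohortskills.inequality import (
    bootstrap_ci,
    group_gap_table,
    ks_between,
    quantile_gaps,
)


def _frame(groups_to_arrays):
    rows = []
    cid = 0
    for g, y in groups_to_arrays.items():
        for v in y:
            rows.append({"child_id": cid, "group": g, "ext": v, "int": v,
                         "converged": True})
            cid += 1
    return pd.DataFrame(rows)


def test_normal_gap_matches_quantile_function():
    """90-10 gap of N(0,1) is 2*1.28155 = 2.5631."""
    rng = np.random.default_rng(1)
    df = _frame({"A": rng.standard_normal(100_000)})
    gaps = quantile_gaps(df, factors=("ext",))
    val = gaps[(gaps.statistic == "q90-q10")]["value"].iloc[0]
    assert abs(val - 2.5631) < 0.03


def test_uniform_gap_is_analytic():
    rng = np.random.default_rng(2)
    df = _frame({"A": rng.uniform(0, 1, 100_000)})
    gaps = quantile_gaps(df, factors=("ext",))
    assert abs(gaps[gaps.statistic == "q90-q10"]["value"].iloc[0] - 0.8) < 0.01


def test_telescoping_identity_exact():
    rng = np.random.default_rng(3)
    df = _frame({"A": rng.gumbel(size=777)})
    gaps = quantile_gaps(df, factors=("ext",), min_n=10).set_index("statistic")
    total = gaps.loc["q90-q10", "value"]
    parts = gaps.loc["q90-q50", "value"] + gaps.loc["q50-q10", "value"]
    assert abs(total - parts) < 1e-12


def test_quantile_bounds_validated():
    df = _frame({"A": np.arange(100.0)})
    with pytest.raises(ValueError, match="outside"):
        quantile_gaps(df, pairs=((110, 10),), factors=("ext",))


def test_location_shift_leaves_everything_invariant(small_panel, small_ladder):
    """Adding a constant to one group's scores changes no gap, variance or
    within-group contrast: the location guard behind refusing cross-cohort
    mean comparisons."""
    from cohortskills.scoring import ebm_scores

    scores = ebm_scores(small_ladder.fits["thresholds_loadings"], small_panel)
    base = scores.data
    shifted = base.copy()
    shifted.loc[shifted.group == "MCS_M", ["ext", "int"]] += 7.5
    g0 = quantile_gaps(base)
    g1 = quantile_gaps(shifted)
    pd.testing.assert_frame_equal(g0, g1)
    t0 = group_gap_table(base, small_panel.data, "mother_educ", 0, B=100, seed=4)
    t1 = group_gap_table(shifted, small_panel.data, "mother_educ", 0, B=100, seed=4)
    pd.testing.assert_frame_equal(t0, t1)
    # KS between subgroups *within* the shifted group is unchanged
    m = shifted[shifted.group == "MCS_M"]
    half = len(m) // 2
    d_shift, _ = ks_between(m["ext"].iloc[:half], m["ext"].iloc[half:])
    m0 = base[base.group == "MCS_M"]
    d_base, _ = ks_between(m0["ext"].iloc[:half], m0["ext"].iloc[half:])
    assert abs(d_shift - d_base) < 1e-12


def test_bootstrap_deterministic_and_degenerate():
    df = _frame({"A": np.random.default_rng(5).standard_normal(500)})
    stat = lambda d: float(np.quantile(d["ext"], 0.9) - np.quantile(d["ext"], 0.1))
    a = bootstrap_ci(stat, df, B=200, seed=11)
    b = bootstrap_ci(stat, df, B=200, seed=11)
    assert a["ci_low"] == b["ci_low"] and a["ci_high"] == b["ci_high"]
    const = bootstrap_ci(lambda d: 3.14, df, B=100, seed=1)
    assert const["ci_low"] == const["ci_high"] == 3.14
    with pytest.raises(ValueError, match="at least 100"):
        bootstrap_ci(stat, df, B=10, seed=1)


def test_bootstrap_gap_coverage_sanity():
    """The percentile interval for the 90-10 gap covers the truth in most
    replications (small-scale coverage check)."""
    truth = 2 * 1.2815515655446004
    covered = 0
    for s in range(20):
        rng = np.random.default_rng(100 + s)
        df = _frame({"A": rng.standard_normal(2000)})
        stat = lambda d: float(
            np.quantile(d["ext"], 0.9) - np.quantile(d["ext"], 0.1)
        )
        ci = bootstrap_ci(stat, df, B=200, seed=s)
        covered += ci["ci_low"] <= truth <= ci["ci_high"]
    assert covered >= 16


def test_ks_examples():
    rng = np.random.default_rng(7)
    a = rng.standard_normal(5000)
    d, p = ks_between(a, a)
    assert d == 0.0 and p == 1.0
    b = rng.normal(0, 1.5, 5000)
    d, p = ks_between(a, b)
    assert p < 0.001
    with pytest.raises(ValueError):
        ks_between(a, np.array([]))
    with pytest.warns(UserWarning, match="small sample"):
        ks_between(a[:2000], np.array([0.1, 0.2, 0.3]))


def test_ks_matches_ecdf_oracle():
    """D equals the brute-force max ECDF difference on small samples."""
    rng = np.random.default_rng(9)
    a = rng.standard_normal(150)
    b = rng.normal(0.3, 1.0, 180)
    d, _ = ks_between(a, b)
    grid = np.concatenate([a, b])
    ecdf_a = (a[:, None] <= grid[None, :]).mean(axis=0)
    ecdf_b = (b[:, None] <= grid[None, :]).mean(axis=0)
    assert abs(d - np.abs(ecdf_a - ecdf_b).max()) < 1e-12


def test_group_gap_table_reference_and_known_effect():
    rng = np.random.default_rng(12)
    n = 4000
    rows = []
    for g in ("BCS_M", "MCS_M"):
        educ = rng.binomial(1, 0.5, n)
        y = 0.3 * educ + rng.standard_normal(n)
        for i in range(n):
            rows.append({"child_id": len(rows), "group": g, "ext": y[i],
                         "int": y[i], "converged": True, "mother_educ": educ[i]})
    df = pd.DataFrame(rows)
    tab = group_gap_table(df, df[["child_id", "mother_educ"]], "mother_educ",
                          0, factors=("ext",), B=150, seed=2)
    ref_rows = tab[tab.category == 0]
    assert np.all(ref_rows["gap"] == 0.0)
    eff = tab[tab.category == 1]
    assert np.all((eff["ci_low"] <= 0.3) & (0.3 <= eff["ci_high"]))
    with pytest.raises(ValueError, match="absent"):
        group_gap_table(df, df[["child_id", "mother_educ"]], "mother_educ", 9)
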