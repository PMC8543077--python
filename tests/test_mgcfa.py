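"""Multi-group ordinal CFA: constraint structure, DWLS fitting, robust tests."""

import numpy as np
import pytest

from cohortskills.items import DEFAULT_GROUPS, DEFAULT_ITEMS
from cohortskills.mgcfa import (
    LEVELS,
    OrdinalFactorModel,
    build_model,
    fit_dwls,
    robust_test,
    scaled_difference,
)
from cohortskills.polychoric import population_moments, sample_moments
from cohortskills.simulate import generate_panel, measurement_only_spec

GROUPS = list(DEFAULT_GROUPS)


def test_free_parameter_counts_by_enumeration():
    """Counts from the restriction sets and the item category layout.

    Per group at the configural level: 11 loadings + 19 thresholds (8 items
    x 2 + 3 items x 1) + 1 factor correlation = 31.
    """
    expected = {
        "configural": 4 * 31,
        "thresholds": 19 + 4 * 12 + 3 * (11 + 8),
        "thresholds_loadings": 19 + 11 + 1 + 3 * (11 + 11 + 3),
        "thresholds_loadings_intercepts": 19 + 11 + 1 + 3 * (2 + 11 + 3),
    }
    for lvl, want in expected.items():
        assert build_model(DEFAULT_ITEMS, GROUPS, lvl).n_free == want
    assert expected["configural"] == 124


def test_constraint_nesting_along_the_ladder():
    """Higher levels add substantive constraints; free counts never grow."""
    prev_constraints: frozenset = frozenset()
    prev_free = np.inf
    for lvl in LEVELS:
        spec = build_model(DEFAULT_ITEMS, GROUPS, lvl)
        assert prev_constraints <= spec.constraints
        assert spec.n_free <= prev_free
        prev_constraints = spec.constraints
        prev_free = spec.n_free
    # strict decrease once loadings are constrained
    assert (
        build_model(DEFAULT_ITEMS, GROUPS, "thresholds_loadings").n_free
        < build_model(DEFAULT_ITEMS, GROUPS, "thresholds").n_free
    )


def test_single_group_configural_is_plain_cfa(invariant_panel):
    m = sample_moments(invariant_panel, "BCS_M", min_n=100)
    spec = build_model(DEFAULT_ITEMS, ["BCS_M"], "configural")
    assert spec.n_free == 31
    fit = OrdinalFactorModel({"BCS_M": m}, spec).fit(check_identification=False)
    assert fit.converged
    with pytest.raises(ValueError, match=">= 2 groups"):
        build_model(DEFAULT_ITEMS, ["BCS_M"], "thresholds")


def test_build_model_validation():
    with pytest.raises(ValueError, match="unknown invariance level"):
        build_model(DEFAULT_ITEMS, GROUPS, "everything")
    with pytest.raises(ValueError, match="reference items"):
        build_model(DEFAULT_ITEMS, GROUPS, "configural", "anchored")
    with pytest.raises(ValueError, match="3 categories"):
        build_model(DEFAULT_ITEMS, GROUPS, "configural", "anchored", anchors=(5, 7))


@pytest.mark.parametrize("level", LEVELS)
def test_perfect_fit_on_population_moments(level):
    """Exact model-implied moments -> discrepancy 0 and exact estimates."""
    spec = measurement_only_spec()
    pop = {g: population_moments(spec.measurement[g], g) for g in GROUPS}
    ms = build_model(DEFAULT_ITEMS, GROUPS, level)
    fit = OrdinalFactorModel(pop, ms).fit(check_identification=False)
    assert fit.discrepancy < 1e-10
    assert fit.converged
    # estimates reproduce the truth (reference-standardised metric)
    gp = fit.group_parameters()["BCS_M"]
    truth = spec.measurement["BCS_M"]
    sd = np.sqrt(np.diag(truth.implied_sigma()))
    assert np.allclose(gp.lam, truth.lam / sd, atol=1e-6)
    for a, b in zip(gp.tau, truth.implied_standardized_thresholds()):
        assert np.allclose(a, b, atol=1e-6)
    # stored discrepancy is reproducible from the stored estimates
    assert abs(fit.recompute_discrepancy() - fit.discrepancy) < 1e-8


def test_identification_check_flags_rank_deficiency(two_group_moments):
    """A model with a redundant direction is reported, with the parameters
    involved, instead of being silently fitted."""
    ms = build_model(DEFAULT_ITEMS, ["BCS_M", "MCS_M"], "configural")
    model = OrdinalFactorModel(two_group_moments, ms)
    x0 = model.layout.start(model.moments)
    # zeroing every loading makes the factor correlation unidentified
    x0[model.layout._blocks[("l", "BCS_M")]] = 0.0
    with pytest.raises(ValueError, match="not identified"):
        model.fit(start=x0, check_identification=True)


def test_parameter_recovery_moderate_n(invariant_panel):
    """Estimates track the generating values at n=1500/group."""
    moments = {g: sample_moments(invariant_panel, g, min_n=100) for g in GROUPS}
    fit = fit_dwls(
        build_model(DEFAULT_ITEMS, GROUPS, "thresholds_loadings"), moments
    )
    spec = measurement_only_spec()
    lay = fit.model.layout
    lam = lay.block(fit.params, "lambda", "shared")
    assert np.abs(lam - spec.measurement["BCS_M"].lam).max() < 0.12
    tau = lay.block(fit.params, "tau", "shared")
    true_tau = np.concatenate(spec.measurement["BCS_M"].tau)
    assert np.abs(tau - true_tau).max() < 0.12


def test_sandwich_ses_match_monte_carlo_dispersion():
    """Across 200 replications the reported SEs track the empirical SD
    of the estimates within 25%."""
    spec = measurement_only_spec()
    spec.group_sizes = {g: 800 for g in spec.groups}
    spec.groups = ("BCS_M", "MCS_M")
    ms = build_model(DEFAULT_ITEMS, ["BCS_M", "MCS_M"], "thresholds_loadings")
    lams, ses = [], []
    for s in range(200):
        panel = generate_panel(spec, seed=40_000 + s)
        moments = {
            g: sample_moments(panel, g, min_n=100) for g in ["BCS_M", "MCS_M"]
        }
        fit = OrdinalFactorModel(moments, ms).fit(check_identification=False)
        lay = fit.model.layout
        sl = lay._blocks[("lambda", "shared")]
        lams.append(fit.params[sl])
        ses.append(fit.bse()[sl])
    emp = np.std(lams, axis=0, ddof=1)
    rep = np.mean(ses, axis=0)
    ratio = emp / rep
    assert np.all(ratio > 0.75) and np.all(ratio < 1.25)


def test_misfit_statistic_grows_linearly_in_n():
    """Fitting full invariance to intercept-shifted data: the statistic's
    noncentral part scales with n (ratio about 2 when n doubles)."""
    stats = {}
    for n, seeds in ((2000, range(4)), (4000, range(4, 8))):
        vals = []
        for s in seeds:
            spec = measurement_only_spec(invariant=False)
            spec.group_sizes = {g: n for g in spec.groups}
            panel = generate_panel(spec, seed=600 + s)
            moments = {g: sample_moments(panel, g) for g in GROUPS}
            fit = fit_dwls(
                build_model(
                    DEFAULT_ITEMS, GROUPS, "thresholds_loadings_intercepts"
                ),
                moments,
            )
            stat, df, _ = robust_test(fit)
            vals.append(stat - df)
        stats[n] = np.mean(vals)
    ratio = stats[4000] / stats[2000]
    assert 1.5 < ratio < 2.6


def test_scaled_difference_detects_intercept_shifts(small_ladder):
    d = scaled_difference(
        small_ladder.fits["thresholds_loadings_intercepts"],
        small_ladder.fits["configural"],
    )
    assert d["pvalue"] < 0.01
    assert d["df"] > 0
    d0 = scaled_difference(
        small_ladder.fits["thresholds"], small_ladder.fits["configural"]
    )
    assert d0["statistic"] < 1e-6  # statistically equivalent rungs
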