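"""Fit indices, delta-AFI decisions and the invariance ladder."""

import numpy as np
import pandas as pd
import pytest

from cohortskills.invariance import (
    DEFAULT_CUTOFFS,
    afi,
    compare_nested,
    run_ladder,
)
from cohortskills.mgcfa import OrdinalFactorModel, build_model
from cohortskills.items import DEFAULT_ITEMS, DEFAULT_GROUPS
from cohortskills.polychoric import population_moments


def test_perfect_fit_gives_ideal_indices():
    """Zero noncentrality (exact population moments): RMSEA 0, CFI 1, MFI 1."""
    from cohortskills.mgcfa import fit_baseline
    from cohortskills.simulate import measurement_only_spec

    spec = measurement_only_spec()
    pop = {
        g: population_moments(spec.measurement[g], g) for g in DEFAULT_GROUPS
    }
    ms = build_model(DEFAULT_ITEMS, DEFAULT_GROUPS, "configural")
    fit = OrdinalFactorModel(pop, ms).fit(check_identification=False)
    base = fit_baseline(pop, DEFAULT_GROUPS, DEFAULT_ITEMS)
    a = afi(fit, base)
    assert a["rmsea"] == 0.0
    assert a["cfi"] == 1.0
    assert a["mfi"] > 0.999999
    assert a["gamma_hat"] > 0.999999


def test_rmsea_matches_hand_formula(small_ladder):
    """RMSEA equals sqrt((chi2 - df)/(df (n-1))) on the scaled statistic."""
    fit = small_ladder.fits["thresholds_loadings_intercepts"]
    a = afi(fit, small_ladder.baseline)
    T, df, n = fit.scaled_statistic, fit.scaled_df, fit.n_total
    hand = np.sqrt(max(T - df, 0.0) / (df * (n - 1)))
    assert abs(a["rmsea"] - hand) < 1e-10
    lo, hi = a["rmsea_ci"]
    assert lo <= a["rmsea"] <= hi


def test_independence_model_against_itself_has_cfi_zero(small_ladder):
    a = afi(small_ladder.baseline, small_ladder.baseline)
    assert a["cfi"] == 0.0


def test_equivalent_rungs_have_zero_deltas(invariant_ladder):
    """Configural and threshold models are statistically equivalent: all
    deltas vanish and no cutoff fires."""
    row = invariant_ladder.table[invariant_ladder.table.level == "thresholds"]
    assert abs(row["d_cfi"].iloc[0]) < 1e-6
    assert abs(row["d_rmsea"].iloc[0]) < 1e-6
    assert not bool(row["rejected"].iloc[0])


def test_cutoffs_are_configuration_not_code(small_panel):
    """An absurdly strict cutoff rejects everything; a lax one accepts."""
    strict = run_ladder(small_panel, cutoffs={"rmsea": -1.0}, min_n=100)
    assert strict.highest_level == "configural"
    lax = run_ladder(
        small_panel, cutoffs={"cfi": -0.5, "rmsea": 0.5, "srmr": 0.5}, min_n=100
    )
    assert lax.highest_level == "thresholds_loadings_intercepts"


def test_decision_is_pure_function_of_stored_fits(small_ladder):
    """Re-running the comparison on stored fits reproduces the flags."""
    again = compare_nested(
        small_ladder.fits, small_ladder.baseline, small_ladder.cutoffs
    )
    pd.testing.assert_frame_equal(again, small_ladder.table)


def test_comparison_rejects_mismatched_moments(small_ladder, invariant_ladder):
    fits = dict(small_ladder.fits)
    fits["thresholds_loadings"] = invariant_ladder.fits["thresholds_loadings"]
    with pytest.raises(ValueError, match="different moments"):
        compare_nested(fits, small_ladder.baseline)


def test_ladder_requires_two_groups(invariant_panel):
    with pytest.raises(ValueError, match=">= 2 groups"):
        run_ladder(invariant_panel, groups=["BCS_M"])


def test_discrepancy_monotone_along_ladder(small_ladder):
    stats = [
        small_ladder.fits[lvl].discrepancy
        for lvl in (
            "configural", "thresholds", "thresholds_loadings",
            "thresholds_loadings_intercepts",
        )
    ]
    assert np.all(np.diff(stats) > -1e-6)


def test_shifted_dgp_stops_at_thresholds_loadings(small_ladder):
    """Intercept shifts in the later cohort: variances comparable, means not."""
    assert small_ladder.highest_level == "thresholds_loadings"
    assert small_ladder.variances_comparable
    assert not small_ladder.means_comparable
    assert "NOT comparable" in small_ladder.decision_narrative()


def test_invariant_dgp_attains_full_invariance(invariant_ladder):
    assert invariant_ladder.highest_level == "thresholds_loadings_intercepts"
    assert invariant_ladder.means_comparable


def test_chi2_difference_rejects_even_where_afis_accept(small_ladder):
    """Large-sample chi-squared differences flag every rung, which is why
    the decision rests on delta-AFIs."""
    row = small_ladder.table[
        small_ladder.table.level == "thresholds_loadings_intercepts"
    ].iloc[0]
    assert row["dchi2_p"] < 0.05
    assert row["statistic"] > 0
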