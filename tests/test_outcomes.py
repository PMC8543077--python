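"""Two-step outcome regressions and cross-group coefficient tests."""

import numpy as np
import pandas as pd
import pytest

from cohortskills.items import DEFAULT_ITEMS
from cohortskills.mgcfa import OrdinalFactorModel
from cohortskills.outcomes import (
    TwoStepOutcomeModel,
    coefficient_equality_test,
    cognitive_scores,
)
from cohortskills.scoring import ebm_scores
from cohortskills.simulate import (
    OutcomeSpec,
    generate_panel,
    measurement_only_spec,
    paper_like_spec,
)


def fast_pipeline(panel):
    """Light measurement stage for bootstrap-heavy tests: configural fit."""
    model = OrdinalFactorModel.from_panel(panel, level="configural", min_n=50)
    return ebm_scores(model.fit(check_identification=False), panel)


def _two_group_outcome_spec(n=400, beta_ext=0.5):
    spec = measurement_only_spec()
    spec.groups = ("BCS_M", "MCS_M")
    spec.group_sizes = {"BCS_M": n, "MCS_M": n}
    spec.outcomes = {
        "y": OutcomeSpec(kind="linear", coef_theta=(beta_ext, 0.0), noise_sd=1.0)
    }
    return spec


def test_point_estimate_matches_attenuation_oracle():
    """The EXT coefficient targets the attenuated value implied by shrunken
    EBM scores; the oracle is the mean point estimate over independent
    replications of the full two-step pipeline."""
    spec = _two_group_outcome_spec()
    oracle = []
    for s in range(25):
        p = generate_panel(spec, seed=7000 + s)
        scores = fast_pipeline(p)
        df = scores.data.merge(p.data, on=["child_id", "group"])
        df = df[df.group == "BCS_M"]
        X = np.column_stack([np.ones(len(df)), df["ext"], df["int"]])
        beta = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        oracle.append(beta[1])
    target = np.mean(oracle)
    assert 0.2 < target < 0.5  # attenuated below the structural 0.5

    panel = generate_panel(spec, seed=6000)
    fit = TwoStepOutcomeModel(
        panel, "y", score_pipeline=fast_pipeline
    ).fit("BCS_M", B=100, seed=1)
    lo = fit.params["externalising"] - 3 * fit.bse["externalising"]
    hi = fit.params["externalising"] + 3 * fit.bse["externalising"]
    assert lo < target < hi


def test_same_seed_reproduces_ses():
    spec = _two_group_outcome_spec(n=300)
    panel = generate_panel(spec, seed=123)
    m = TwoStepOutcomeModel(panel, "y", score_pipeline=fast_pipeline)
    a = m.fit("BCS_M", B=100, seed=5)
    b = m.fit("BCS_M", B=100, seed=5)
    pd.testing.assert_series_equal(a.bse, b.bse)
    assert a.n == b.n


def test_constant_outcome_rejected():
    spec = _two_group_outcome_spec(n=300)
    panel = generate_panel(spec, seed=9)
    panel.data["flat"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        TwoStepOutcomeModel(
            panel, "flat", score_pipeline=fast_pipeline
        ).fit("BCS_M", B=100, seed=0)


def test_cognition_column_toggle_purity(small_panel):
    """Adding the cognitive score only appends a regressor; the design for
    the shared columns is unchanged."""
    m0 = TwoStepOutcomeModel(small_panel, "bmi", covariates=["mother_educ"],
                             include_cognition=False,
                             score_pipeline=fast_pipeline)
    m1 = TwoStepOutcomeModel(small_panel, "bmi", covariates=["mother_educ"],
                             include_cognition=True,
                             score_pipeline=fast_pipeline)
    scores = fast_pipeline(small_panel)
    y0, X0, n0 = m0._design(small_panel, scores, "BCS_M")
    y1, X1, n1 = m1._design(small_panel, scores, "BCS_M")
    assert n0 == ["externalising", "internalising", "mother_educ"]
    assert n1 == ["externalising", "internalising", "cognitive", "mother_educ"]
    np.testing.assert_array_equal(y0, y1)
    shared = [n1.index(c) for c in n0]
    np.testing.assert_array_equal(X0, X1[:, shared])


def test_cognitive_score_standardised_within_cohort(small_panel):
    cog = cognitive_scores(small_panel)
    groups = small_panel.data["group"]
    for cohort in ("BCS", "MCS"):
        mask = groups.str.startswith(cohort)
        assert abs(cog[mask.to_numpy()].mean()) < 1e-9
        assert abs(cog[mask.to_numpy()].std(ddof=1) - 1.0) < 1e-9


def test_equality_test_self_and_validation():
    spec = _two_group_outcome_spec(n=300)
    panel = generate_panel(spec, seed=15)
    m = TwoStepOutcomeModel(panel, "y", score_pipeline=fast_pipeline)
    fit = m.fit("BCS_M", B=100, seed=2)
    assert coefficient_equality_test(fit, fit, "externalising",
                                     method="percentile") == 1.0
    with pytest.raises(ValueError, match="missing"):
        coefficient_equality_test(fit, fit, "not_a_regressor")


def test_equality_test_detects_different_coefficients():
    """Structural coefficients 0.1 vs 0.6 across groups are told apart."""
    spec = _two_group_outcome_spec(n=1200)
    spec.outcomes["y"] = OutcomeSpec(kind="linear", coef_theta=(0.1, 0.0))
    panel_a = generate_panel(spec, seed=31)
    spec2 = _two_group_outcome_spec(n=1200)
    spec2.outcomes["y"] = OutcomeSpec(kind="linear", coef_theta=(0.6, 0.0))
    panel_b = generate_panel(spec2, seed=32)
    fa = TwoStepOutcomeModel(panel_a, "y", score_pipeline=fast_pipeline).fit(
        "BCS_M", B=100, seed=3
    )
    fb = TwoStepOutcomeModel(panel_b, "y", score_pipeline=fast_pipeline).fit(
        "BCS_M", B=100, seed=4
    )
    assert coefficient_equality_test(fa, fb, "externalising") < 0.05
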