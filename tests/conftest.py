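"""Shared fixtures: synthetic panels and fitted models reused across tests.

Expensive objects (panels, polychoric moments, fitted ladders) are
session-scoped; every test that only reads them can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from cohortskills.items import DEFAULT_GROUPS, DEFAULT_ITEMS
from cohortskills.invariance import run_ladder
from cohortskills.polychoric import sample_moments
from cohortskills.simulate import (
    generate_panel,
    measurement_only_spec,
    paper_like_spec,
)


def equal_sizes(spec, n):
    out = spec.copy()
    out.group_sizes = {g: n for g in out.groups}
    return out


@pytest.fixture(scope="session")
def invariant_spec():
    return measurement_only_spec()


@pytest.fixture(scope="session")
def paper_spec():
    return paper_like_spec()


@pytest.fixture(scope="session")
def small_panel(paper_spec):
    """Paper-like panel at reduced but decision-capable size."""
    return generate_panel(equal_sizes(paper_spec, 3000), seed=1234)


@pytest.fixture(scope="session")
def invariant_panel(invariant_spec):
    return generate_panel(equal_sizes(invariant_spec, 1500), seed=77)


@pytest.fixture(scope="session")
def two_group_moments(invariant_panel):
    return {
        g: sample_moments(invariant_panel, g, min_n=100)
        for g in ("BCS_M", "MCS_M")
    }


@pytest.fixture(scope="session")
def small_ladder(small_panel):
    return run_ladder(small_panel, min_n=100)


@pytest.fixture(scope="session")
def invariant_ladder(invariant_panel):
    return run_ladder(invariant_panel, min_n=100)
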