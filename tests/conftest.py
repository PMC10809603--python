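import numpy as np
import pandas as pd
import pytest

import vscore as vs


@pytest.fixture(scope="session")
def small_panel():
    return vs.generate_place_panel(
        vs.PanelParams(n_tracts=20, years=(2009, 2012), seed=100))


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    cohort, truth = vs.generate_cohort(
        small_panel, vs.CohortParams(n_persons=80, seed=101))
    return cohort, truth


def make_cohort(rows):
    """Build a CohortTable from (person, tract, year, outcome[, weight]) tuples."""
    cols = ["person_id", "tract_id", "year", "outcome", "weight"]
    rows = [tuple(r) + (1.0,) * (5 - len(r)) for r in rows]
    return vs.CohortTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def tiny_forest_params():
    return vs.ForestParams(n_trees=20, seed=5, min_node_size=2)
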