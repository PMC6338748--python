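import numpy as np
import pandas as pd
import pytest

from filab import (SimulationConfig, code_cohort, generate_cohort,
                   load_reference_panel, panel_variables, score_cohort)


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def variables(panel):
    return panel_variables(panel)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (n=736), shared across tests."""
    return generate_cohort(SimulationConfig(seed=20240901))


@pytest.fixture(scope="session")
def scored_cohort(cohort, panel):
    deficits = code_cohort(cohort, panel)
    scores = score_cohort(deficits)
    scored = pd.concat([cohort, scores], axis=1)
    return scored, deficits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def midpoint_labs(panel, sex):
    """All 22 labs at representative in-range values for a given sex."""
    from filab.panel import panel_variables, resolve_range

    labs = {}
    for var in panel_variables(panel):
        r = resolve_range(panel, var, sex)
        if r.style == "closed_interval":
            labs[var] = 0.5 * (r.lower + r.upper)
        elif r.style == "upper_only":
            labs[var] = 0.5 * r.upper
        else:
            labs[var] = 1.5 * r.lower
    return labs
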