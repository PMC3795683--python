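import numpy as np
import pandas as pd
import pytest

from monomark import (
    CohortSimConfig,
    TwoPopSimConfig,
    simulate_subtype_reference,
    simulate_survival_cohort,
    simulate_two_population_expression,
)


@pytest.fixture(scope="session")
def small_twopop():
    """Compact two-population simulation reused across discovery tests:
    600 genes, 30 markers per direction, study-default noise and replicates."""
    cfg = TwoPopSimConfig(n_genes=600, n_marker_per_direction=30, seed=7)
    return simulate_two_population_expression(cfg)


@pytest.fixture(scope="session")
def cohort_sim():
    """Default synthetic tumor cohort (n=159) plus its subtype reference."""
    cfg = CohortSimConfig(seed=19)
    return simulate_survival_cohort(cfg), simulate_subtype_reference(cfg)


@pytest.fixture
def six_subject_cox():
    """Tiny survival fixture: distinct event times, one binary covariate."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
        },
        index=[f"P{i}" for i in range(6)],
    )


@pytest.fixture
def tied_censored_cox():
    """Eight subjects with tied event times and censoring, to exercise the
    Efron tie handling."""
    return pd.DataFrame(
        {
            "time": [2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0, 7.0],
            "event": [1, 1, 1, 0, 1, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
        },
        index=[f"Q{i}" for i in range(8)],
    )
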