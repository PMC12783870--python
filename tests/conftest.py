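import numpy as np
import pytest

from avtbw import Condition, CohortPriors, build_design, default_soa_grid, simulate_cohort


@pytest.fixture(scope="session")
def rhythmic_conditions() -> list[Condition]:
    return [
        Condition(f"rhythmic-{f}Hz", "rhythmic", float(f), "fixed_duration", 3.0)
        for f in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def exp1_design(rhythmic_conditions):
    return build_design(default_soa_grid(), rhythmic_conditions, n_reps=5, seed=20)


@pytest.fixture(scope="session")
def small_cohort():
    """20 seeded subjects on a single-condition 5-rep design, with truth."""
    design = build_design(default_soa_grid(), [Condition("c3", "rhythmic", 3.0)], 5, seed=3)
    responses, truth = simulate_cohort(20, design, CohortPriors(), seed=42)
    return responses, truth
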