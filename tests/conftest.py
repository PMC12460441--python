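import numpy as np
import pytest

from woerisk import (
    Cohort,
    CohortSpec,
    PipelineConfig,
    VariableSpec,
    fit_pipeline,
    generate_cohort,
    inject_missingness,
)


def small_spec(n=400, seed=0, missing_rate=0.0):
    """12 mixed-type predictors, 3 strongly informative, for fast end-to-end
    tests: continuous terciles, an informative categorical and a binary."""
    variables = [
        VariableSpec(name="c_inf1", vartype="continuous", informative=True,
                     effect=(-1.2, 0.0, 1.2)),
        VariableSpec(name="c_inf2", vartype="continuous", informative=True,
                     effect=(-1.0, 0.0, 1.0)),
        VariableSpec(name="cat_inf", vartype="categorical", n_categories=4,
                     informative=True, effect=(0.9, 0.2, -0.2, -0.9)),
        VariableSpec(name="b_noise", vartype="binary"),
        VariableSpec(name="cat_noise", vartype="categorical", n_categories=3),
    ] + [VariableSpec(name=f"c_noise{j}", vartype="continuous") for j in range(7)]
    return CohortSpec(n_subjects=n, variables=tuple(variables), seed=seed,
                      missing_rate=missing_rate)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(n=400, seed=11))


@pytest.fixture(scope="session")
def small_cohort_missing():
    cohort = generate_cohort(small_spec(n=400, seed=12))
    return inject_missingness(cohort, 0.2, "MCAR", seed=13)


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig(grid_size=30, seed=0)


@pytest.fixture(scope="session")
def small_fit(small_cohort, fast_config):
    return fit_pipeline(small_cohort, fast_config)
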