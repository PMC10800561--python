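import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table():
    from mncea.parameters import ParameterTable

    return ParameterTable.default()


@pytest.fixture(scope="session")
def fixture_records(table):
    """Deterministic patient-record cohort at the published counts."""
    from mncea.cohort import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig.from_table(table), fixture=True)


@pytest.fixture(scope="session")
def base_case(table):
    """Deterministic base-case traces and comparison for both arms."""
    from mncea.cea import compare_strategies
    from mncea.markov import evaluate_strategies

    traces = evaluate_strategies(table.values(), table)
    result = compare_strategies(
        traces["RTX"], traces["TAC"], table.settings["wtp_per_qaly"]
    )
    return traces, result
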