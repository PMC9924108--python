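import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def millennium():
    from vmatqa import MachineModel

    return MachineModel.from_profile("Millennium120")


@pytest.fixture(scope="session")
def hd120():
    from vmatqa import MachineModel

    return MachineModel.from_profile("HD120")


@pytest.fixture(scope="session")
def cohort500():
    """Default-configuration 500-plan cohort with a fixed seed.

    Session-scoped: shared by the calibration, ordering, ANOVA and
    hold-out evaluation tests.
    """
    from vmatqa.synthetic import default_cohort_spec, generate_qa_dataset

    return generate_qa_dataset(default_cohort_spec(500), seed=0)
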