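import pytest
from hypothesis import settings

from lundgfr import PatientRecord, default_registry

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def registry():
    return default_registry()


@pytest.fixture()
def adult_female():
    """40-year-old female with both markers, as in the worked examples."""
    return PatientRecord(
        patient_id="F40",
        age=40.0,
        sex="female",
        height=165.0,
        weight=62.0,
        creatinine=80.0,
        cystatin_c=2.0,
    )


@pytest.fixture()
def adult_male():
    return PatientRecord(
        patient_id="M55",
        age=55.0,
        sex="male",
        height=180.0,
        weight=82.0,
        creatinine=95.0,
        cystatin_c=1.1,
    )
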