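import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from humansim import make_patient, run_until_death, sample_patients
from humansim.validation import load_calibrated_setup, validation_roster


@pytest.fixture(scope="session")
def calibrated_setup():
    """(ModelConfig, preset catalog) with the frozen calibration applied."""
    return load_calibrated_setup()


@pytest.fixture(scope="session")
def scenario_results(calibrated_setup):
    """All nine untreated reference scenarios, run once per session.

    Maps patient number -> (ValidationCase, SimResult).
    """
    cfg, catalog = calibrated_setup
    out = {}
    for case in validation_roster():
        res = run_until_death(case.profile, catalog[case.preset_id], cfg)
        out[case.number] = (case, res)
    return out


@pytest.fixture(scope="session")
def cohort_10k():
    """10,000 seeded random patients for generator statistics."""
    return sample_patients(10_000, seed=42)


@pytest.fixture(scope="session")
def reference_patient():
    """An average-build middle-aged man used in engine-level tests."""
    return make_patient("male", 45, 178.4, bmi=23.0)
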