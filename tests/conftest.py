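import pytest

from carbsafe import TrialConfig, load_reference_roster
from carbsafe.trial import CarbCountingTrial


@pytest.fixture(scope="session")
def roster():
    return load_reference_roster()


@pytest.fixture(scope="session")
def calibrated_roster(roster):
    """The 33-subject roster with per-patient metabolic calibration."""
    trial = CarbCountingTrial(roster, TrialConfig(master_seed=0))
    return trial.calibrate()


@pytest.fixture(scope="session")
def full_results(calibrated_roster):
    """One full 90-day, 10-experiment study over the reference roster."""
    config = TrialConfig(days=90, master_seed=0)
    return CarbCountingTrial(calibrated_roster, config).run()
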