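import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from crisismap.pipeline import simulate_case
from crisismap.simulator import patient_like_config, simulate_trio


@pytest.fixture(scope="session")
def patient_sim():
    """One patient-like simulated trio shared across tests."""
    return simulate_trio(patient_like_config(), seed=11)


@pytest.fixture(scope="session")
def case_dir(tmp_path_factory):
    """A fully written artifact directory for the patient-like scenario."""
    d = tmp_path_factory.mktemp("case")
    simulate_case(patient_like_config(), 11, d)
    return d
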