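import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lipoptics.blood import RBCParams  # noqa: E402
from lipoptics.distributions import intralipid_distribution  # noqa: E402
from lipoptics.lipoproteins import fasting_state  # noqa: E402


@pytest.fixture(scope="session")
def intralipid_dist():
    return intralipid_distribution()


@pytest.fixture(scope="session")
def rbc():
    return RBCParams()


@pytest.fixture()
def fasting_100():
    """Fasting blood lipid state at 100 mg/dL TG, bovine hematocrit."""
    return fasting_state(100.0)
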