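import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the efm_oracle helper

from emspace import (enumerate_pathways, raspberry_network, toy_fba_model)
from emspace.fixtures import promiscuity_universe


@pytest.fixture(scope="session")
def raspberry():
    """(network, chassis seeds, target) for the raspberry-ketone case."""
    return raspberry_network()


@pytest.fixture(scope="session")
def raspberry_pathways(raspberry):
    net, seeds, target = raspberry
    return enumerate_pathways(net, seeds, target)


@pytest.fixture(scope="session")
def toy_model():
    return toy_fba_model()


@pytest.fixture(scope="session")
def keto_universe():
    """Universe where rule generality depends on the diameter."""
    return promiscuity_universe()
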