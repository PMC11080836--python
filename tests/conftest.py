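import numpy as np
import pytest

from dimerqc.adapters import ADAPTER_PRESETS, AdapterMode, AdapterSpec

ILLUMINA_3P = ADAPTER_PRESETS["illumina-truseq-smallrna"]["adapter3"].sequence
ILLUMINA_5P = ADAPTER_PRESETS["illumina-truseq-smallrna"]["adapter5"].sequence
ION_3P = ADAPTER_PRESETS["iontorrent-smallrna"]["adapter3"].sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def matcher_specs():
    """Preset adapters at the three error rates in play, all three modes."""
    specs = []
    for rate in (0.0, 0.1, 0.2):
        specs.append(AdapterSpec("ill3", ILLUMINA_3P, AdapterMode.BACK, rate))
        specs.append(AdapterSpec("ill5", ILLUMINA_5P, AdapterMode.FRONT, rate))
        specs.append(AdapterSpec("ion3", ION_3P, AdapterMode.ANYWHERE, rate))
    return specs
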