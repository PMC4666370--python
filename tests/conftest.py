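import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from srnatarget.energy_model import RnaSequence, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_rna(rng, length: int) -> RnaSequence:
    return RnaSequence(id=f"rand{length}", seq="".join(rng.choice(list("ACGU"), size=length)))
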