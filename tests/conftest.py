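import numpy as np
import pytest

from atrialab.cell import ModelSpec
from atrialab.protocols import PacingProtocol, pace_train

MUTANTS = ("KCNH2-T436M", "KCNH2-T895M", "KCNE3-V17M")
REGIONS = ("RA", "LA", "PV")


@pytest.fixture(scope="session")
def paced_models():
    """Beat-61 analyses of all 12 region x genotype models (1-Hz protocol)."""
    runs = {}
    proto = PacingProtocol()
    for region in REGIONS:
        for mut in ("WT",) + MUTANTS:
            runs[(mut, region)] = pace_train(ModelSpec(mut, region), proto)
    return runs


def pct(mutant, wt):
    return 100.0 * (mutant - wt) / wt
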