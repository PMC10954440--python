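import numpy as np
import pytest

# the two canonical worked sequences: equal-length tracts with a skippable
# fifth tract, and unequal-length tracts with multiple core placements
SEQ_FIVE_TRACTS = "CCCACCCACCCACCCACCC"
SEQ_UNEQUAL_TRACTS = "CCCCACCCACCCCCACCC"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


def random_dna(rng, n, p_c=0.4):
    """C-enriched random DNA so that iM candidates actually occur."""
    p_rest = (1 - p_c) / 3
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[p_rest, p_c, p_rest, p_rest])
    )
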