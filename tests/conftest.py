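import numpy as np
import pytest

from ms2drs import GenomeModel, OrfAnnotation, make_genome


@pytest.fixture(scope="session")
def genome():
    """Default synthetic MS2-like genome (3,569 nt, four ORFs)."""
    return make_genome(seed=1)


@pytest.fixture(scope="session")
def toy_genome():
    """Small hand-built genome with one ORF for targeted tests."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    seq = seq[:50] + "ATG" + seq[53:120] + "TAA" + seq[123:]
    return GenomeModel(name="toy", sequence=seq,
                       orfs=[OrfAnnotation(name="orf1", start=50, end=123)])
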