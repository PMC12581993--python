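import numpy as np
import pytest

from g4topo import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def record():
    def make(seq: str, contig: str = "chr1", topology: str = "linear") -> SequenceRecord:
        return SequenceRecord(contig, seq, topology)

    return make
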