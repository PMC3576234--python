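import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from srnakit.config import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def tiny_genome():
    """Two short contigs exercising multi-contig paths."""
    from srnakit.io import SequenceRecord

    return [
        SequenceRecord(id="c1", seq="ACGTACGTACGTACGTACGTACGTACGTACGT"),
        SequenceRecord(id="c2", seq="TTTTACGTGGGGACGTCCCCACGTAAAA"),
    ]
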