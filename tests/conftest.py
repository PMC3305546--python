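import numpy as np
import pytest

from snpmine.io_formats import MaskedContig, ReadAlignmentRecord
from snpmine.pileup import PileupColumn


@pytest.fixture
def unmasked_contig():
    def _make(contig_id: str, sequence: str) -> MaskedContig:
        return MaskedContig(contig_id, sequence, (False,) * len(sequence))

    return _make


@pytest.fixture
def simple_read():
    def _make(read_id, contig_id, start, cigar, seq, mask=None):
        return ReadAlignmentRecord.from_sequence(
            read_id, contig_id, start, cigar, seq, mask
        )

    return _make


def random_columns(rng: np.random.Generator, contig_id: str, length: int,
                   n_cols: int, max_depth: int = 12) -> list[PileupColumn]:
    """Random sparse pileup columns on one contig, for oracle tests."""
    positions = sorted(
        int(p) + 1
        for p in rng.choice(length, size=min(n_cols, length), replace=False)
    )
    cols = []
    for pos in positions:
        counts = {}
        for base in "ACGT":
            if rng.random() < 0.5:
                c = int(rng.integers(0, max_depth))
                if c:
                    counts[base] = c
        if counts:
            cols.append(PileupColumn(contig_id, pos, counts))
    return cols
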