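"""Per-position allele counting over read-to-contig alignments.

This is the detection stage of the pipeline: every eligible read is walked
through its CIGAR and each reference-consuming aligned base increments the
count of the read base at that contig position.  Insertions and soft clips
consume read bases without touching any column; deletions advance along the
reference without contributing an allele (indel variation is excluded from
this SNP-only analysis).  ``N`` read bases are ignored entirely.

Read eligibility implements the repeat-screen rule: a read participates
only if it contains a sufficiently long run of consecutive unmasked bases
(default 100 bp), so reads dominated by masked repeats cannot seed spurious
variant columns.  Contigs at or below the minimum length (default 100 bp)
contribute no columns at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_formats import MaskedContig, ReadAlignmentRecord, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PileupColumn:
    """Allele counts across mapped reads at one contig position (1-based)."""

    contig_id: str
    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def longest_unmasked_run(mask: Sequence[bool]) -> int:
    """Length of the longest run of consecutive False entries in ``mask``."""
    best = cur = 0
    for m in mask:
        if m:
            cur = 0
        else:
            cur += 1
            if cur > best:
                best = cur
    return best


def eligible_read(
    record: ReadAlignmentRecord, min_unmasked_run: int = 100
) -> bool:
    """A read is eligible iff it has >= ``min_unmasked_run`` consecutive
    unmasked bases.  Ineligible reads contribute nothing to the pileup."""
    return longest_unmasked_run(record.read_mask) >= min_unmasked_run


def build_pileup(
    alignments: Iterable[ReadAlignmentRecord],
    contigs: Sequence[MaskedContig],
    min_contig_len: int = 100,
) -> Iterator[PileupColumn]:
    """Stream non-empty pileup columns in (contig, position) order.

    ``alignments`` must already be sorted by (contig, start) and
    eligibility-filtered by the caller.  Contigs of length
    <= ``min_contig_len`` are skipped (the threshold is strict: a contig
    must be *longer* than the minimum).  Columns with zero depth are
    omitted from the stream.
    """
    contig_by_id = {c.contig_id: c for c in contigs}
    order = {c.contig_id: i for i, c in enumerate(contigs)}

    grouped: dict[str, list[ReadAlignmentRecord]] = {}
    prev_key: tuple[int, int] | None = None
    for rec in alignments:
        if rec.contig_id not in contig_by_id:
            raise ValidationError(f"alignment to unknown contig {rec.contig_id!r}")
        key = (order[rec.contig_id], rec.start)
        if prev_key is not None and key < prev_key:
            raise ValidationError(
                "alignments not sorted by (contig, start); sort before pileup"
            )
        prev_key = key
        grouped.setdefault(rec.contig_id, []).append(rec)

    for contig in contigs:
        if len(contig) <= min_contig_len:
            continue
        reads = grouped.get(contig.contig_id)
        if not reads:
            continue
        counts = np.zeros((4, len(contig)), dtype=np.int64)
        for rec in reads:
            _accumulate(counts, rec, len(contig))
        depth = counts.sum(axis=0)
        for pos0 in np.flatnonzero(depth):
            col_counts = {
                BASES[i]: int(counts[i, pos0])
                for i in range(4)
                if counts[i, pos0]
            }
            yield PileupColumn(contig.contig_id, int(pos0) + 1, col_counts)


def _accumulate(
    counts: np.ndarray, rec: ReadAlignmentRecord, contig_len: int
) -> None:
    ref = rec.start - 1  # 0-based
    qry = 0
    seq = rec.read_sequence
    for op, length in rec.cigar:
        if op in "M=X":
            if ref + length > contig_len:
                raise ValidationError(
                    f"read {rec.read_id!r} overruns contig at position {ref + 1}"
                )
            for k in range(length):
                base = seq[qry + k]
                idx = _BASE_INDEX.get(base)
                if idx is not None:  # N bases are ignored
                    counts[idx, ref + k] += 1
            ref += length
            qry += length
        elif op in "IS":
            qry += length
        elif op == "D":
            ref += length


def total_counted_bases(columns: Iterable[PileupColumn]) -> int:
    """Sum of all allele counts over a column stream (conservation check)."""
    return sum(c.depth for c in columns)
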