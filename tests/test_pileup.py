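"""Pileup engine: eligibility rule, CIGAR walking, conservation, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpmine.io_formats import MaskedContig, ReadAlignmentRecord, ValidationError
from snpmine.pileup import (
    build_pileup,
    eligible_read,
    longest_unmasked_run,
    total_counted_bases,
)


def _read(contig_id, start, cigar, seq, mask=None):
    return ReadAlignmentRecord.from_sequence(
        f"r_{contig_id}_{start}_{seq[:4]}", contig_id, start, cigar, seq, mask
    )


def _contig(cid, length, base="A"):
    return MaskedContig(cid, base * length, (False,) * length)


class TestEligibility:
    def test_fully_unmasked_long_read_eligible(self):
        r = _read("c", 1, [("M", 120)], "A" * 120)
        assert eligible_read(r)

    def test_longest_run_99_ineligible(self):
        # 120 bp read whose longest unmasked stretch is one base short
        mask = [False] * 99 + [True] + [False] * 20
        r = _read("c", 1, [("M", 120)], "A" * 120, mask)
        assert longest_unmasked_run(mask) == 99
        assert not eligible_read(r)

    def test_99bp_fully_unmasked_read_ineligible(self):
        r = _read("c", 1, [("M", 99)], "A" * 99)
        assert not eligible_read(r)
        assert eligible_read(r, min_unmasked_run=99)

    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_run_length_matches_brute_force(self, mask):
        brute = max(
            (len(seg) for seg in
             "".join("ux"[m] for m in mask).split("x")),
            default=0,
        )
        assert longest_unmasked_run(mask) == brute


class TestBuildPileup:
    def test_single_read_simple_match(self):
        contigs = [_contig("c1", 120)]
        cols = list(build_pileup([_read("c1", 1, [("M", 4)], "ACGT")], contigs))
        assert [(c.position, c.counts) for c in cols] == [
            (1, {"A": 1}), (2, {"C": 1}), (3, {"G": 1}), (4, {"T": 1}),
        ]

    def test_disagreeing_reads_stack_in_one_column(self):
        contigs = [_contig("c1", 120)]
        reads = [
            _read("c1", 1, [("M", 4)], "AAGA"),
            _read("c1", 1, [("M", 4)], "AATA"),
        ]
        cols = {c.position: c for c in build_pileup(reads, contigs)}
        assert cols[3].counts == {"G": 1, "T": 1} and cols[3].depth == 2

    def test_deletion_skips_reference_column(self):
        contigs = [_contig("c1", 120)]
        reads = [_read("c1", 1, [("M", 2), ("D", 1), ("M", 2)], "ACGT")]
        cols = [c.position for c in build_pileup(reads, contigs)]
        assert cols == [1, 2, 4, 5]

    def test_insertion_and_softclip_consume_read_only(self):
        contigs = [_contig("c1", 120)]
        reads = [_read("c1", 5, [("S", 2), ("M", 2), ("I", 3), ("M", 1)], "TTACGGGT")]
        cols = {c.position: c for c in build_pileup(reads, contigs)}
        assert set(cols) == {5, 6, 7}
        assert cols[7].counts == {"T": 1}

    def test_n_bases_do_not_count(self):
        contigs = [_contig("c1", 120)]
        reads = [_read("c1", 1, [("M", 3)], "ANG")]
        cols = {c.position: c for c in build_pileup(reads, contigs)}
        assert set(cols) == {1, 3}

    def test_short_contig_contributes_nothing(self):
        contigs = [_contig("short", 100), _contig("long", 101)]
        reads = [
            _read("short", 1, [("M", 4)], "ACGT"),
            _read("long", 1, [("M", 4)], "ACGT"),
        ]
        cols = list(build_pileup(reads, contigs))
        assert {c.contig_id for c in cols} == {"long"}

    def test_unsorted_input_rejected(self):
        contigs = [_contig("c1", 120)]
        reads = [
            _read("c1", 9, [("M", 4)], "ACGT"),
            _read("c1", 2, [("M", 4)], "ACGT"),
        ]
        with pytest.raises(ValidationError, match="sorted"):
            list(build_pileup(reads, contigs))

    def test_read_overrunning_contig_rejected(self):
        contigs = [_contig("c1", 120)]
        reads = [_read("c1", 119, [("M", 4)], "ACGT")]
        with pytest.raises(ValidationError):
            list(build_pileup(reads, contigs))


def _brute_force_pileup(reads, contigs, min_contig_len=100):
    """Per-base replay oracle: walk every alignment base by base."""
    lengths = {c.contig_id: len(c) for c in contigs}
    acc: dict[tuple[str, int], dict[str, int]] = {}
    for r in reads:
        if lengths[r.contig_id] <= min_contig_len:
            continue
        ref, qry = r.start, 0
        for op, n in r.cigar:
            for _ in range(n):
                if op in "M=X":
                    b = r.read_sequence[qry]
                    if b in "ACGT":
                        col = acc.setdefault((r.contig_id, ref), {})
                        col[b] = col.get(b, 0) + 1
                    ref += 1
                    qry += 1
                elif op in "IS":
                    qry += 1
                elif op == "D":
                    ref += 1
    return acc


@st.composite
def _random_alignment_set(draw):
    contigs = [
        _contig("cA", draw(st.integers(95, 160))),
        _contig("cB", draw(st.integers(95, 160))),
    ]
    reads = []
    for i in range(draw(st.integers(0, 8))):
        contig = contigs[draw(st.integers(0, 1))]
        ops = []
        seq = []
        ref_len = 0
        for _ in range(draw(st.integers(1, 4))):
            op = draw(st.sampled_from("MIDS"))
            n = draw(st.integers(1, 6))
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))
            if op in "MIS":
                seq.extend(draw(st.sampled_from("ACGTN")) for _ in range(n))
            if op in "MD":
                ref_len += n
        if not any(op == "M" for op, _ in ops):
            continue
        max_start = len(contig) - ref_len + 1
        if max_start < 1:
            continue
        start = draw(st.integers(1, max_start))
        reads.append(
            ReadAlignmentRecord.from_sequence(
                f"r{i}", contig.contig_id, start, ops, "".join(seq)
            )
        )
    reads.sort(key=lambda r: (r.contig_id, r.start, r.read_id))
    return contigs, reads


class TestPileupProperties:
    @given(_random_alignment_set())
    @settings(max_examples=150, deadline=None)
    def test_matches_per_base_replay_oracle(self, case):
        contigs, reads = case
        cols = {
            (c.contig_id, c.position): c.counts
            for c in build_pileup(reads, contigs)
        }
        assert cols == _brute_force_pileup(reads, contigs)

    @given(_random_alignment_set())
    @settings(max_examples=100, deadline=None)
    def test_conservation_of_counted_bases(self, case):
        contigs, reads = case
        long_ids = {c.contig_id for c in contigs if len(c) > 100}
        expected = sum(
            sum(1 for b in r.read_sequence[q0:q0 + n] if b in "ACGT")
            for r in reads
            if r.contig_id in long_ids
            for q0, n in _matched_read_slices(r)
        )
        assert total_counted_bases(build_pileup(reads, contigs)) == expected

    @given(_random_alignment_set())
    @settings(max_examples=50, deadline=None)
    def test_deterministic_stream(self, case):
        contigs, reads = case
        assert list(build_pileup(reads, contigs)) == list(
            build_pileup(reads, contigs)
        )


def _matched_read_slices(read):
    """(read offset, length) of each reference-consuming matched block."""
    q = 0
    for op, n in read.cigar:
        if op in "M=X":
            yield q, n
            q += n
        elif op in "IS":
            q += n
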