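"""Filter cascade: thresholds at their boundaries, audit, oracle replay."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpmine.filters import (
    FILTER_NAMES,
    FilterConfig,
    PutativeSNP,
    depth_and_minor_filter,
    detect_candidates,
    flank_filter,
    multiallelic_filter,
    run_filter_cascade,
    spacing_filter,
)
from snpmine.io_formats import MaskedContig
from snpmine.pileup import PileupColumn

from conftest import random_columns
from oracles import brute_force_cascade


def _col(counts, pos=60, cid="c1"):
    return PileupColumn(cid, pos, counts)


LENGTHS = {"c1": 500}


class TestDetectCandidates:
    def test_monomorphic_column_is_not_a_candidate(self):
        assert detect_candidates([_col({"A": 10})], LENGTHS) == []

    def test_two_allele_column(self):
        (snp,) = detect_candidates([_col({"A": 6, "G": 3})], LENGTHS)
        assert (snp.allele_major, snp.count_major) == ("A", 6)
        assert (snp.allele_minor, snp.count_minor) == ("G", 3)
        assert snp.flank_left == 59 and snp.flank_right == 440

    def test_tie_breaks_alphabetically(self):
        (snp,) = detect_candidates([_col({"G": 5, "A": 5})], LENGTHS)
        assert snp.allele_major == "A" and snp.allele_minor == "G"

    def test_tie_rule_by_exhaustive_two_allele_enumeration(self):
        # every unordered allele pair at equal counts: the alphabetically
        # smaller base must come out major
        for b1, b2 in itertools.combinations("ACGT", 2):
            (snp,) = detect_candidates([_col({b2: 4, b1: 4})], LENGTHS)
            assert snp.allele_major == min(b1, b2)
            assert snp.allele_minor == max(b1, b2)

    def test_third_allele_recorded(self):
        (snp,) = detect_candidates([_col({"A": 6, "G": 3, "T": 2, "C": 1})], LENGTHS)
        assert snp.count_third == 2 and snp.count_other == 3


class TestThresholdBoundaries:
    def test_depth5_minor2_passes(self):
        (snp,) = detect_candidates([_col({"A": 3, "G": 2})], LENGTHS)
        assert depth_and_minor_filter(snp) and snp.passed

    def test_minor_below_two_fails(self):
        (snp,) = detect_candidates([_col({"A": 3, "G": 1})], LENGTHS)
        assert not depth_and_minor_filter(snp)
        assert snp.filters_failed == {"minor_allele", "depth"}

    def test_depth_below_five_fails(self):
        (snp,) = detect_candidates([_col({"A": 2, "G": 2})], LENGTHS)
        assert not depth_and_minor_filter(snp)
        assert snp.filters_failed == {"depth"}

    def test_third_allele_below_threshold_passes(self):
        (snp,) = detect_candidates([_col({"A": 5, "G": 3, "T": 1})], LENGTHS)
        assert multiallelic_filter(snp)

    def test_third_allele_at_threshold_fails(self):
        (snp,) = detect_candidates([_col({"A": 5, "G": 3, "T": 2})], LENGTHS)
        assert not multiallelic_filter(snp)
        assert snp.filters_failed == {"multiallelic"}

    @pytest.mark.parametrize(
        "position,passes",
        [(26, True), (25, False), (75, True), (76, False)],
        ids=["left-25", "left-24", "right-25", "right-24"],
    )
    def test_flank_boundaries_on_100bp_contig(self, position, passes):
        (snp,) = detect_candidates(
            [PileupColumn("c", position, {"A": 5, "G": 3})], {"c": 100}
        )
        assert flank_filter(snp, 100) is passes


def _snp_at(pos, cid="c1"):
    return PutativeSNP(cid, pos, "A", "G", 5, 3, 0, pos - 1, 1000 - pos)


class TestSpacing:
    def test_exactly_50_apart_both_pass(self):
        snps = [_snp_at(100), _snp_at(150)]
        spacing_filter(snps)
        assert all(s.passed for s in snps)

    def test_49_apart_both_fail(self):
        snps = [_snp_at(100), _snp_at(149)]
        spacing_filter(snps)
        assert all(s.filters_failed == {"spacing"} for s in snps)

    def test_isolated_site_survives_next_to_close_pair(self):
        snps = [_snp_at(100), _snp_at(149), _snp_at(300)]
        spacing_filter(snps)
        assert [s.passed for s in snps] == [False, False, True]

    def test_drop_one_mode_keeps_earlier_member(self):
        snps = [_snp_at(100), _snp_at(149), _snp_at(300)]
        spacing_filter(snps, drop_both=False)
        assert [s.passed for s in snps] == [True, False, True]

    @given(st.sets(st.integers(1, 400), min_size=0, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_all_pairs_brute_force(self, positions):
        snps = [_snp_at(p) for p in sorted(positions)]
        spacing_filter(snps)
        for s in snps:
            close = any(
                0 < abs(s.position - q) < 50 for q in positions
            )
            assert ("spacing" in s.filters_failed) == close

    @given(st.sets(st.integers(1, 400), min_size=0, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, positions):
        snps = [_snp_at(p) for p in sorted(positions)]
        spacing_filter(snps)
        once = [set(s.filters_failed) for s in snps]
        spacing_filter(snps)
        assert [set(s.filters_failed) for s in snps] == once


def _contig(cid, length):
    return MaskedContig(cid, "A" * length, (False,) * length)


class TestCascade:
    CONTIGS = [_contig("c1", 500), _contig("c2", 300)]

    def test_no_candidates_zero_audit(self):
        accepted, audit = run_filter_cascade([], self.CONTIGS)
        assert accepted == [] and audit.n_candidates == 0
        assert audit.total_removed() == 0

    def test_three_well_spaced_sites_all_accepted(self):
        cols = [_col({"A": 12, "G": 8}, pos=p) for p in (100, 200, 300)]
        accepted, audit = run_filter_cascade(cols, self.CONTIGS)
        assert [s.position for s in accepted] == [100, 200, 300]
        assert audit.n_accepted == 3 and audit.total_removed() == 0

    def test_close_pair_both_removed_and_audited(self):
        cols = [_col({"A": 12, "G": 8}, pos=p) for p in (100, 130, 300)]
        accepted, audit = run_filter_cascade(cols, self.CONTIGS)
        assert [s.position for s in accepted] == [300]
        assert audit.removed["spacing"] == 2

    def test_weak_neighbour_cannot_veto_good_site(self):
        # the depth-failing candidate at 130 is excluded before spacing,
        # so the good site at 100 must survive — this pins the stage order
        cols = [
            _col({"A": 12, "G": 8}, pos=100),
            _col({"A": 3, "G": 1}, pos=130),
        ]
        accepted, audit = run_filter_cascade(cols, self.CONTIGS)
        assert [s.position for s in accepted] == [100]
        assert audit.removed["spacing"] == 0

    def test_audit_conservation_and_first_stage_attribution(self):
        cols = [
            _col({"A": 2, "G": 1}, pos=100),        # depth (and minor)
            _col({"A": 5, "G": 3, "T": 2}, pos=200),  # multiallelic
            _col({"A": 9, "G": 5}, pos=300),
            _col({"A": 9, "G": 5}, pos=320),        # spacing pair
            _col({"A": 9, "G": 5}, pos=490),        # flank (right 10)
        ]
        accepted, audit = run_filter_cascade(cols, self.CONTIGS)
        assert accepted == []
        assert audit.n_candidates == 5
        assert audit.removed == {
            "depth": 1, "minor_allele": 0, "multiallelic": 1,
            "spacing": 2, "flank": 1,
        }
        assert audit.n_candidates == audit.n_accepted + audit.total_removed()

    def test_accepted_is_subset_of_candidates_with_clean_audit(self):
        rng = np.random.default_rng(7)
        cols = random_columns(rng, "c1", 500, 40)
        accepted, audit = run_filter_cascade(cols, self.CONTIGS)
        cand_keys = {(c.contig_id, c.position) for c in cols}
        assert {(s.contig_id, s.position) for s in accepted} <= cand_keys
        assert all(s.passed for s in accepted)
        assert audit.n_candidates == audit.n_accepted + audit.total_removed()

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        lengths = {c.contig_id: len(c) for c in self.CONTIGS}
        for _ in range(200):
            cols = random_columns(rng, "c1", 500, int(rng.integers(0, 25)))
            cols += random_columns(rng, "c2", 300, int(rng.integers(0, 15)))
            accepted, _ = run_filter_cascade(list(cols), self.CONTIGS)
            got = {
                (s.contig_id, s.position, s.allele_major, s.allele_minor)
                for s in accepted
            }
            assert got == brute_force_cascade(cols, lengths)
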