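"""Transition/transversion classification and codon-position assignment.

Codon positions are derived purely from translated-alignment coordinates:
a translated HSP begins in-frame, so its query start coordinate sits on
codon position 1 of its reading frame.  For a plus-frame HSP with query
start ``qs`` the codon position of site ``p`` is ``((p - qs) mod 3) + 1``;
for a minus-frame HSP (where the start coordinate is the numerically
larger one) it is ``((qs - p) mod 3) + 1``.

When a query has several HSPs, a site is *exonic* if at least one HSP
covers it; the codon position is reported only if every covering HSP
agrees, otherwise the site is exonic with an uncertain codon position.
Non-covering HSPs neither support nor contradict an assignment.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from dataclasses import dataclass

from .filters import PutativeSNP
from .io_formats import ProteinAlignmentRecord, SnpTableRow, ValidationError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class CodonAssignment:
    """Consolidated exon status / codon position for one site.

    ``codon_position`` is "1"/"2"/"3"/"uncertain" when exonic and
    "not_applicable" otherwise.  ``n_supporting_alignments`` counts the
    HSPs that cover the site.
    """

    exon_status: str
    codon_position: str
    n_supporting_alignments: int


def classify_titv(allele1: str, allele2: str) -> str:
    """Classify an unordered allele pair as transition or transversion.

    Transitions are the within-class changes A<->G and C<->T; everything
    else (purine <-> pyrimidine) is a transversion.
    """
    if allele1 == allele2:
        raise ValidationError("alleles must differ")
    pair = {allele1, allele2}
    if not pair <= (_PURINES | _PYRIMIDINES):
        raise ValidationError(f"non-ACGT allele in {sorted(pair)}")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def codon_position_single(
    aln: ProteinAlignmentRecord, snp_position: int
) -> int | None:
    """Codon position (1/2/3) of a query site under one HSP, or None if the
    HSP does not cover the site."""
    if not aln.covers(snp_position):
        return None
    if aln.frame_sign > 0:
        return ((snp_position - aln.query_start) % 3) + 1
    return ((aln.query_start - snp_position) % 3) + 1


def consolidate(
    alignments: Sequence[ProteinAlignmentRecord], snp_position: int
) -> CodonAssignment:
    """Combine one query's full HSP set into a single assignment.

    Coverage by any HSP establishes exonic status; a definite codon
    position additionally requires that all covering HSPs agree.
    """
    positions = []
    for aln in alignments:
        pos = codon_position_single(aln, snp_position)
        if pos is not None:
            positions.append(pos)
    if not positions:
        return CodonAssignment("non_exonic", "not_applicable", 0)
    if len(set(positions)) == 1:
        return CodonAssignment("exonic", str(positions[0]), len(positions))
    return CodonAssignment("exonic", "uncertain", len(positions))


def annotate_snps(
    snps: Iterable[PutativeSNP],
    alignments_by_query: Mapping[str, Sequence[ProteinAlignmentRecord]],
    isogroup_map: Mapping[str, str] | None = None,
) -> list[SnpTableRow]:
    """Attach Ti/Tv class and codon assignment to every accepted SNP.

    ``alignments_by_query`` maps query (contig) id to its full HSP set; a
    contig absent from the map yields non-exonic rows.  Output is sorted
    by (contig, position).
    """
    isogroup_map = isogroup_map or {}
    rows = []
    for snp in sorted(snps, key=lambda s: (s.contig_id, s.position)):
        assignment = consolidate(
            alignments_by_query.get(snp.contig_id, ()), snp.position
        )
        rows.append(
            SnpTableRow(
                contig_id=snp.contig_id,
                position=snp.position,
                allele_major=snp.allele_major,
                allele_minor=snp.allele_minor,
                count_major=snp.count_major,
                count_minor=snp.count_minor,
                snp_class=classify_titv(snp.allele_major, snp.allele_minor),
                exon_status=assignment.exon_status,
                codon_position=assignment.codon_position,
                isogroup_id=isogroup_map.get(snp.contig_id),
            )
        )
    return rows
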