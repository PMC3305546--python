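"""Per-contig, per-isogroup and density summaries of an accepted SNP set."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

from .io_formats import SnpTableRow


@dataclass(frozen=True)
class SnpSummary:
    """Headline statistics for one SNP table.

    Means are stored at full precision; use :func:`display_round` for the
    1-decimal presentation figures.  ``bp_per_snp`` is None when no total
    base count was supplied or when there are no SNPs.
    """

    n_snps: int
    n_transitions: int
    n_transversions: int
    n_contigs_with_snp: int
    n_isogroups_with_snp: int
    mean_snps_per_contig: float
    mean_snps_per_isogroup: float
    max_per_contig: int
    max_per_isogroup: int
    n_contigs_exactly_one: int
    n_isogroups_at_least_two: int
    bp_per_snp: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def display_round(x: float) -> float:
    """Round half-even to one decimal, the precision used for reporting."""
    return float(round(x, 1))


def summarize(
    rows: Sequence[SnpTableRow],
    isogroup_map: Mapping[str, str] | None = None,
    total_bases: int | None = None,
) -> SnpSummary:
    """Aggregate a SNP table into a :class:`SnpSummary`.

    Isogroup membership comes from the row itself when present, else from
    ``isogroup_map``; contigs with neither form singleton groups (the
    contig id stands in for the group id).  ``total_bases`` is the
    denominator for SNP density — the caller chooses whether it is total
    assembled bases or bases of SNP-bearing contigs.
    """
    isogroup_map = isogroup_map or {}
    n = len(rows)
    if n == 0:
        return SnpSummary(0, 0, 0, 0, 0, 0.0, 0.0, 0, 0, 0, 0, None)

    per_contig: Counter[str] = Counter()
    per_isogroup: Counter[str] = Counter()
    n_ti = 0
    for row in rows:
        per_contig[row.contig_id] += 1
        group = row.isogroup_id or isogroup_map.get(row.contig_id) or row.contig_id
        per_isogroup[group] += 1
        if row.snp_class == "transition":
            n_ti += 1

    return SnpSummary(
        n_snps=n,
        n_transitions=n_ti,
        n_transversions=n - n_ti,
        n_contigs_with_snp=len(per_contig),
        n_isogroups_with_snp=len(per_isogroup),
        mean_snps_per_contig=n / len(per_contig),
        mean_snps_per_isogroup=n / len(per_isogroup),
        max_per_contig=max(per_contig.values()),
        max_per_isogroup=max(per_isogroup.values()),
        n_contigs_exactly_one=sum(1 for v in per_contig.values() if v == 1),
        n_isogroups_at_least_two=sum(1 for v in per_isogroup.values() if v >= 2),
        bp_per_snp=(total_bases / n) if total_bases else None,
    )


def format_summary(summary: SnpSummary) -> str:
    """Human-readable report block."""
    lines = [
        f"putative SNPs            {summary.n_snps}",
        f"  transitions            {summary.n_transitions}",
        f"  transversions          {summary.n_transversions}",
        f"contigs with >=1 SNP     {summary.n_contigs_with_snp}",
        f"  mean SNPs per contig   {display_round(summary.mean_snps_per_contig)}",
        f"  max SNPs in a contig   {summary.max_per_contig}",
        f"  contigs with one SNP   {summary.n_contigs_exactly_one}",
        f"isogroups with >=1 SNP   {summary.n_isogroups_with_snp}",
        f"  mean SNPs per isogroup {display_round(summary.mean_snps_per_isogroup)}",
        f"  max SNPs in isogroup   {summary.max_per_isogroup}",
        f"  isogroups with >=2     {summary.n_isogroups_at_least_two}",
    ]
    if summary.bp_per_snp is not None:
        lines.append(f"one SNP every            {summary.bp_per_snp:.0f} bp")
    return "\n".join(lines)
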