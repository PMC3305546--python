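"""Candidate SNP detection and the accuracy filter cascade.

A pileup column becomes a candidate as soon as two distinct bases are each
observed at least once.  Candidates then pass through the cascade, in this
order:

1. **depth / minor-allele / multiallelic** — total column depth must reach
   ``min_total`` (default 5) and the minor allele must be supported by at
   least ``min_minor`` reads (default 2); a third allele reaching the same
   evidence threshold disqualifies the site (only biallelic substitutions
   are reported).
2. **spacing** — among the survivors of stage 1 on each contig, any pair of
   sites closer than ``min_gap`` bp (default 50) is removed.  Clustered
   candidates are the signature of homopolymer-driven alignment errors in
   454 reads, and by default *both* members of a close pair are dropped
   (configurable via ``spacing_drop_both``).
3. **flank** — the site must have at least ``min_flank`` bp (default 25) of
   contig sequence on each side, so the surrounding sequence can support
   assay design.

The cascade order matters: spacing is evaluated only among sites that
survived the evidence filters, so a weakly supported neighbour cannot veto
a good site.  Every removal is attributed to the first failing stage in an
audit, and ``filters_failed`` on each candidate records all failures seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import MaskedContig
from .pileup import PileupColumn

FILTER_NAMES = ("depth", "minor_allele", "multiallelic", "spacing", "flank")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults are the study's)."""

    min_total: int = 5
    min_minor: int = 2
    min_gap: int = 50
    min_flank: int = 25
    min_unmasked_run: int = 100
    min_contig_len: int = 100
    spacing_drop_both: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)


@dataclass
class PutativeSNP:
    """A candidate biallelic site with its evidence and filter audit.

    ``count_other`` pools every base beyond the top two; ``count_third``
    is the count of the third-ranked base alone (what the multiallelic
    filter tests).
    """

    contig_id: str
    position: int
    allele_major: str
    allele_minor: str
    count_major: int
    count_minor: int
    count_other: int
    flank_left: int
    flank_right: int
    count_third: int = 0
    filters_failed: set[str] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return self.count_major + self.count_minor + self.count_other

    @property
    def passed(self) -> bool:
        return not self.filters_failed


@dataclass
class FilterAudit:
    """How many candidates each cascade stage removed.

    Each removed candidate is attributed to the *first* stage that failed
    it, so ``n_candidates == n_accepted + sum(removed.values())``.
    """

    n_candidates: int = 0
    n_accepted: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {name: 0 for name in FILTER_NAMES}
    )

    def total_removed(self) -> int:
        return sum(self.removed.values())


def detect_candidates(
    columns: Iterable[PileupColumn], contig_lengths: dict[str, int]
) -> list[PutativeSNP]:
    """Candidate sites: columns where >= 2 distinct bases are observed.

    The two highest-count bases become major/minor; at equal counts the
    alphabetically smaller base ranks first (a fixed, documented tie-break
    so output is deterministic).
    """
    out = []
    for col in columns:
        if len(col.counts) < 2:
            continue
        ranked = sorted(col.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (major, c_major), (minor, c_minor) = ranked[0], ranked[1]
        c_third = ranked[2][1] if len(ranked) > 2 else 0
        length = contig_lengths[col.contig_id]
        out.append(
            PutativeSNP(
                contig_id=col.contig_id,
                position=col.position,
                allele_major=major,
                allele_minor=minor,
                count_major=c_major,
                count_minor=c_minor,
                count_other=col.depth - c_major - c_minor,
                flank_left=col.position - 1,
                flank_right=length - col.position,
                count_third=c_third,
            )
        )
    return out


def depth_and_minor_filter(
    snp: PutativeSNP, min_total: int = 5, min_minor: int = 2
) -> bool:
    """Evidence filter: total component reads and minor-allele support.

    ``min_total`` counts *all* bases in the column (major + minor + other),
    not just the two modelled alleles.  Failures are recorded on the SNP;
    returns True iff the site passes both checks.
    """
    if snp.depth < min_total:
        snp.filters_failed.add("depth")
    if snp.count_minor < min_minor:
        snp.filters_failed.add("minor_allele")
    return not ({"depth", "minor_allele"} & snp.filters_failed)


def multiallelic_filter(snp: PutativeSNP, min_minor: int = 2) -> bool:
    """Reject sites where a third allele reaches the evidence threshold,
    i.e. the site is not a clean biallelic substitution."""
    if snp.count_third >= min_minor:
        snp.filters_failed.add("multiallelic")
    return "multiallelic" not in snp.filters_failed


def spacing_filter(
    snps: Sequence[PutativeSNP], min_gap: int = 50, drop_both: bool = True
) -> None:
    """Mark sites closer than ``min_gap`` to another surviving site.

    ``snps`` must all lie on one contig, sorted by position, and should be
    the survivors of the evidence filters.  Distance is ``|p1 - p2|`` and
    sites exactly ``min_gap`` apart both pass.  With ``drop_both`` (the
    default) both members of a close pair fail; otherwise a greedy
    left-to-right sweep keeps the earlier member of each offending pair.
    """
    positions = [s.position for s in snps]
    if positions != sorted(positions):
        raise ValueError("spacing_filter requires position-sorted input")
    if drop_both:
        for i, snp in enumerate(snps):
            left_close = i > 0 and snp.position - positions[i - 1] < min_gap
            right_close = (
                i + 1 < len(snps) and positions[i + 1] - snp.position < min_gap
            )
            if left_close or right_close:
                snp.filters_failed.add("spacing")
    else:
        last_kept: int | None = None
        for snp in snps:
            if last_kept is not None and snp.position - last_kept < min_gap:
                snp.filters_failed.add("spacing")
            else:
                last_kept = snp.position


def flank_filter(
    snp: PutativeSNP, contig_length: int, min_flank: int = 25
) -> bool:
    """Require >= ``min_flank`` bp of contig on both sides of the site."""
    if snp.position - 1 < min_flank or contig_length - snp.position < min_flank:
        snp.filters_failed.add("flank")
    return "flank" not in snp.filters_failed


def run_filter_cascade(
    columns: Iterable[PileupColumn],
    contigs: Sequence[MaskedContig],
    config: FilterConfig | None = None,
) -> tuple[list[PutativeSNP], FilterAudit]:
    """Detect candidates and run the full cascade; return survivors + audit.

    Stages run in order: evidence (depth, minor allele, multiallelic
    together), then spacing among evidence survivors per contig, then
    flanks.  Survivors carry an empty ``filters_failed`` set.
    """
    if config is None:
        config = FilterConfig()
    lengths = {c.contig_id: len(c) for c in contigs}
    candidates = detect_candidates(columns, lengths)
    audit = FilterAudit(n_candidates=len(candidates))

    stage1: list[PutativeSNP] = []
    for snp in candidates:
        ok = depth_and_minor_filter(snp, config.min_total, config.min_minor)
        ok = multiallelic_filter(snp, config.min_minor) and ok
        if ok:
            stage1.append(snp)

    by_contig: dict[str, list[PutativeSNP]] = {}
    for snp in stage1:
        by_contig.setdefault(snp.contig_id, []).append(snp)
    for contig_snps in by_contig.values():
        contig_snps.sort(key=lambda s: s.position)
        spacing_filter(contig_snps, config.min_gap, config.spacing_drop_both)

    accepted: list[PutativeSNP] = []
    for snp in stage1:
        if "spacing" in snp.filters_failed:
            continue
        if flank_filter(snp, lengths[snp.contig_id], config.min_flank):
            accepted.append(snp)

    for snp in candidates:
        if snp.filters_failed:
            for name in FILTER_NAMES:  # attribute to first failing stage
                if name in snp.filters_failed:
                    audit.removed[name] += 1
                    break
    audit.n_accepted = len(accepted)
    accepted.sort(key=lambda s: (s.contig_id, s.position))
    return accepted, audit
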