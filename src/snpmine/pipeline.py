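"""End-to-end orchestration: alignments in, annotated SNP table out."""

from __future__ import annotations

import sys
from typing import Mapping, Sequence

from .annotation import annotate_snps
from .filters import FilterAudit, FilterConfig, run_filter_cascade
from .io_formats import (
    MaskedContig,
    ProteinAlignmentRecord,
    ReadAlignmentRecord,
    SnpTableRow,
)
from .pileup import build_pileup, eligible_read


def call_snps(
    contigs: Sequence[MaskedContig],
    alignments: Sequence[ReadAlignmentRecord],
    blast_records: Sequence[ProteinAlignmentRecord] = (),
    isogroup_map: Mapping[str, str] | None = None,
    config: FilterConfig | None = None,
    log=None,
) -> tuple[list[SnpTableRow], FilterAudit]:
    """Run eligibility filtering, pileup, the filter cascade and annotation.

    ``alignments`` must be sorted by (contig, start) — the order the SAM
    reader returns.  Pass ``log=sys.stderr`` (or any file object) for
    per-stage counts.
    """
    if config is None:
        config = FilterConfig()

    eligible = [r for r in alignments if eligible_read(r, config.min_unmasked_run)]
    columns = build_pileup(eligible, contigs, config.min_contig_len)
    accepted, audit = run_filter_cascade(columns, contigs, config)

    by_query: dict[str, list[ProteinAlignmentRecord]] = {}
    for rec in blast_records:
        by_query.setdefault(rec.query_id, []).append(rec)
    rows = annotate_snps(accepted, by_query, isogroup_map)

    if log is not None:
        print(
            f"reads: {len(alignments)} total, {len(eligible)} eligible "
            f"(>= {config.min_unmasked_run} bp unmasked run)",
            file=log,
        )
        print(f"candidate sites: {audit.n_candidates}", file=log)
        for name, n in audit.removed.items():
            print(f"  removed by {name}: {n}", file=log)
        print(f"accepted SNPs: {audit.n_accepted}", file=log)
    return rows, audit
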