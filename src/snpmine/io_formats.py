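"""Readers and writers for the external formats the pipeline touches.

Conventions used throughout:

* All external coordinates are 1-based, fully closed intervals (SAM and
  BLAST tabular convention).
* Repeat masking is *soft*: lowercase bases in FASTA mean "masked by the
  upstream repeat screen".  A hard-masked dialect is also tolerated, with
  ``N`` treated as masked.  Internally sequences are stored uppercase next
  to an explicit boolean mask so coordinates are never disturbed.
* SAM ``SEQ`` case is not reliably preserved by parsers, so per-read masks
  travel in an ``XM:Z:`` optional tag (one ``0``/``1`` per read base) when
  alignments are written; lowercase read sequences are still honoured when
  records are built in memory.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a pipeline invariant."""


_VALID_BASES = frozenset("ACGTN")

# CIGAR ops the pileup understands.  N (ref skip), H (hard clip) and
# P (padding) never occur in the ungapped transcript-space alignments this
# pipeline consumes and are rejected outright.
_SUPPORTED_OPS = frozenset("M=XIDS")
_READ_CONSUMING = frozenset("M=XIS")
_REF_CONSUMING = frozenset("M=XD")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedContig:
    """An assembly contig with a per-base repeat mask.

    ``sequence`` is uppercase A/C/G/T/N; ``mask[i]`` is True where base
    ``i`` (0-based) was repeat-masked upstream.  ``isogroup_id`` links the
    contig to its gene-level group when an isogroup map is supplied.
    """

    contig_id: str
    sequence: str
    mask: tuple[bool, ...]
    isogroup_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_id!r}: empty sequence")
        if len(self.mask) != len(self.sequence):
            raise ValidationError(
                f"contig {self.contig_id!r}: mask length {len(self.mask)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r}: invalid bases {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One read-to-contig alignment (a gapped SAM record).

    ``start`` is the 1-based reference position of the first aligned base.
    ``cigar`` is a tuple of ``(op, length)`` with op in M/=/X/I/D/S.
    ``read_mask`` marks repeat-masked read bases (True = masked).
    """

    read_id: str
    contig_id: str
    start: int
    cigar: tuple[tuple[str, int], ...]
    read_sequence: str
    read_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"read {self.read_id!r}: start {self.start} < 1")
        if not self.cigar:
            raise ValidationError(f"read {self.read_id!r}: empty CIGAR")
        for op, length in self.cigar:
            if op not in _SUPPORTED_OPS:
                raise ValidationError(
                    f"read {self.read_id!r}: unsupported CIGAR op {op!r}"
                )
            if length < 1:
                raise ValidationError(
                    f"read {self.read_id!r}: CIGAR length {length} < 1"
                )
        consumed = sum(n for op, n in self.cigar if op in _READ_CONSUMING)
        if consumed != len(self.read_sequence):
            raise ValidationError(
                f"read {self.read_id!r}: CIGAR consumes {consumed} read bases "
                f"but sequence has {len(self.read_sequence)}"
            )
        if len(self.read_mask) != len(self.read_sequence):
            raise ValidationError(
                f"read {self.read_id!r}: mask/sequence length mismatch"
            )

    @property
    def reference_span(self) -> tuple[int, int]:
        """1-based closed [start, end] interval covered on the contig."""
        ref_len = sum(n for op, n in self.cigar if op in _REF_CONSUMING)
        return self.start, self.start + ref_len - 1

    @classmethod
    def from_sequence(
        cls,
        read_id: str,
        contig_id: str,
        start: int,
        cigar: Sequence[tuple[str, int]],
        read_sequence: str,
        read_mask: Sequence[bool] | None = None,
    ) -> "ReadAlignmentRecord":
        """Build a record, deriving the mask from lowercase bases if absent."""
        if read_mask is None:
            read_mask = tuple(b.islower() for b in read_sequence)
        return cls(
            read_id=read_id,
            contig_id=contig_id,
            start=start,
            cigar=tuple((op, int(n)) for op, n in cigar),
            read_sequence=read_sequence.upper(),
            read_mask=tuple(read_mask),
        )


@dataclass(frozen=True)
class ProteinAlignmentRecord:
    """One translated-nucleotide (BLASTx-style) HSP on a query contig.

    ``query_start``/``query_end`` are 1-based nucleotide coordinates on the
    query.  For minus-frame HSPs the tabular convention is
    ``query_start > query_end``; ``frame_sign`` records the reading
    direction (+1/-1).
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    evalue: float
    frame_sign: int

    def __post_init__(self) -> None:
        if self.query_start == self.query_end:
            raise ValidationError(
                f"alignment {self.query_id!r}~{self.subject_id!r}: "
                "zero-length query span"
            )
        span = abs(self.query_end - self.query_start) + 1
        if span % 3 != 0:
            raise ValidationError(
                f"alignment {self.query_id!r}~{self.subject_id!r}: "
                f"query span {span} nt is not a whole number of codons"
            )
        if self.frame_sign not in (1, -1):
            raise ValidationError("frame_sign must be +1 or -1")
        if self.evalue < 0:
            raise ValidationError("negative e-value")

    @property
    def span(self) -> tuple[int, int]:
        """Plus-strand closed interval [lo, hi] the HSP covers on the query."""
        lo, hi = sorted((self.query_start, self.query_end))
        return lo, hi

    def covers(self, position: int) -> bool:
        lo, hi = self.span
        return lo <= position <= hi


EXON_STATUSES = ("exonic", "non_exonic")
CODON_POSITIONS = ("1", "2", "3", "uncertain", "not_applicable")
SNP_CLASSES = ("transition", "transversion")


@dataclass(frozen=True)
class SnpTableRow:
    """One accepted SNP with its allele evidence and annotation."""

    contig_id: str
    position: int
    allele_major: str
    allele_minor: str
    count_major: int
    count_minor: int
    snp_class: str
    exon_status: str
    codon_position: str
    isogroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValidationError("major and minor alleles identical")
        if self.allele_major not in "ACGT" or self.allele_minor not in "ACGT":
            raise ValidationError("alleles must be A/C/G/T")
        if self.count_major < self.count_minor or self.count_minor < 0:
            raise ValidationError("allele counts out of order")
        if self.position < 1:
            raise ValidationError("position must be >= 1")
        if self.snp_class not in SNP_CLASSES:
            raise ValidationError(f"bad class {self.snp_class!r}")
        if self.exon_status not in EXON_STATUSES:
            raise ValidationError(f"bad exon_status {self.exon_status!r}")
        if self.codon_position not in CODON_POSITIONS:
            raise ValidationError(f"bad codon_position {self.codon_position!r}")
        if (self.exon_status == "exonic") != (self.codon_position != "not_applicable"):
            raise ValidationError(
                "codon_position must be 1/2/3/uncertain iff exonic"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_masked_fasta(path: str | Path) -> list[MaskedContig]:
    """Read soft-masked contigs; lowercase (or N) bases become mask=True.

    Raises :class:`ValidationError` on duplicate ids or empty sequences and
    :class:`FormatError` on unparseable input.
    """
    contigs: list[MaskedContig] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    for rec in records:
        raw = str(rec.seq)
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        mask = tuple(b.islower() or b.upper() == "N" for b in raw)
        contigs.append(MaskedContig(rec.id, raw.upper(), mask))
    return contigs


def write_masked_fasta(contigs: Iterable[MaskedContig], path: str | Path) -> None:
    """Write contigs as soft-masked FASTA (masked bases lowercased)."""
    records = []
    for c in contigs:
        seq = "".join(
            b.lower() if m else b for b, m in zip(c.sequence, c.mask)
        )
        records.append(SeqRecord(Seq(seq), id=c.contig_id, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

MASK_TAG = "XM"


def read_alignments(
    path: str | Path, contigs: Sequence[MaskedContig]
) -> list[ReadAlignmentRecord]:
    """Read a SAM file of read-to-contig alignments.

    Unmapped records are skipped.  Only CIGAR ops M/=/X/I/D/S are accepted.
    The per-read mask is taken from the ``XM:Z:`` tag (one 0/1 per base)
    when present, otherwise reads are treated as fully unmasked.  Records
    are returned sorted by (contig, start, read id).
    """
    by_id = {c.contig_id: c for c in contigs}
    out: list[ReadAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            contig_id = rec.reference_name
            if contig_id not in by_id:
                raise ValidationError(
                    f"{path}: read {rec.query_name!r} maps to unknown "
                    f"contig {contig_id!r}"
                )
            cigar = []
            for op_code, length in rec.cigartuples or ():
                op = "MIDNSHP=X"[op_code]
                if op not in _SUPPORTED_OPS:
                    raise ValidationError(
                        f"{path}: read {rec.query_name!r} has unsupported "
                        f"CIGAR op {op!r}"
                    )
                cigar.append((op, length))
            seq = rec.query_sequence or ""
            mask: Sequence[bool] | None = None
            if rec.has_tag(MASK_TAG):
                tag = rec.get_tag(MASK_TAG)
                mask = tuple(ch == "1" for ch in str(tag))
            record = ReadAlignmentRecord.from_sequence(
                read_id=rec.query_name,
                contig_id=contig_id,
                start=rec.reference_start + 1,
                cigar=cigar,
                read_sequence=seq,
                read_mask=mask,
            )
            end = record.reference_span[1]
            if end > len(by_id[contig_id]):
                raise ValidationError(
                    f"{path}: read {rec.query_name!r} extends to {end} beyond "
                    f"contig {contig_id!r} length {len(by_id[contig_id])}"
                )
            out.append(record)
    out.sort(key=lambda r: (r.contig_id, r.start, r.read_id))
    return out


def write_alignments(
    records: Iterable[ReadAlignmentRecord],
    contigs: Sequence[MaskedContig],
    path: str | Path,
) -> None:
    """Write alignments as plain-text SAM with @SQ headers and XM mask tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.contig_id, "LN": len(c)} for c in contigs],
    }
    tid = {c.contig_id: i for i, c in enumerate(contigs)}
    op_code = {op: "MIDNSHP=X".index(op) for op in _SUPPORTED_OPS}
    ordered = sorted(records, key=lambda r: (tid[r.contig_id], r.start, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for r in ordered:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.contig_id]
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            a.cigartuples = [(op_code[op], n) for op, n in r.cigar]
            a.query_sequence = r.read_sequence
            a.set_tag(MASK_TAG, "".join("1" if m else "0" for m in r.read_mask))
            sam.write(a)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tabular(
    path: str | Path, *, log: bool = True
) -> list[ProteinAlignmentRecord]:
    """Read translated-search HSPs from 12-column tabular output.

    An optional 13th column carries the explicit query frame.  When absent,
    the frame sign is inferred from the coordinate order: qstart < qend
    means +1, qstart > qend means -1 (the tabular convention for
    translated queries).  HSPs whose nucleotide span is not a whole number
    of codons are dropped with a warning count rather than aborting.
    """
    out: list[ProteinAlignmentRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                qstart, qend = int(cols[6]), int(cols[7])
                evalue = float(cols[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(cols) >= 13 and cols[12].strip():
                frame_sign = 1 if int(cols[12]) > 0 else -1
            else:
                frame_sign = 1 if qstart < qend else -1
            try:
                out.append(
                    ProteinAlignmentRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        query_start=qstart,
                        query_end=qend,
                        evalue=evalue,
                        frame_sign=frame_sign,
                    )
                )
            except ValidationError:
                n_rejected += 1
    if n_rejected and log:
        print(
            f"read_blast_tabular: rejected {n_rejected} HSP(s) with "
            "non-codon-multiple spans",
            file=sys.stderr,
        )
    return out


def write_blast_tabular(
    records: Iterable[ProteinAlignmentRecord], path: str | Path
) -> None:
    """Write HSPs as 12-column tabular + explicit 13th frame column.

    Columns 3-6, 9-10 and 12 (identity, length, mismatches, gaps, subject
    coordinates, bitscore) are not modelled and written as plausible
    placeholders derived from the span.
    """
    with open(path, "w") as fh:
        for r in records:
            aa_len = (abs(r.query_end - r.query_start) + 1) // 3
            fields = [
                r.query_id, r.subject_id, "100.00", str(aa_len), "0", "0",
                str(r.query_start), str(r.query_end), "1", str(aa_len),
                f"{r.evalue:.2g}", "100.0", str(r.frame_sign),
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SNP table (TSV and spreadsheet dialects)
# ---------------------------------------------------------------------------

SNP_TABLE_COLUMNS = [
    "contig_id", "position", "allele_major", "allele_minor",
    "count_major", "count_minor", "class", "exon_status",
    "codon_position", "isogroup_id",
]


def _rows_to_frame(rows: Iterable[SnpTableRow]) -> pd.DataFrame:
    data = [
        {
            "contig_id": r.contig_id,
            "position": r.position,
            "allele_major": r.allele_major,
            "allele_minor": r.allele_minor,
            "count_major": r.count_major,
            "count_minor": r.count_minor,
            "class": r.snp_class,
            "exon_status": r.exon_status,
            "codon_position": r.codon_position,
            "isogroup_id": r.isogroup_id if r.isogroup_id is not None else "",
        }
        for r in rows
    ]
    return pd.DataFrame(data, columns=SNP_TABLE_COLUMNS)


def _frame_to_rows(df: pd.DataFrame, source: str) -> list[SnpTableRow]:
    missing = [c for c in SNP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {missing}")
    rows = []
    for rec in df.to_dict("records"):
        iso = rec["isogroup_id"]
        iso = None if (pd.isna(iso) or str(iso) == "") else str(iso)
        rows.append(
            SnpTableRow(
                contig_id=str(rec["contig_id"]),
                position=int(rec["position"]),
                allele_major=str(rec["allele_major"]),
                allele_minor=str(rec["allele_minor"]),
                count_major=int(rec["count_major"]),
                count_minor=int(rec["count_minor"]),
                snp_class=str(rec["class"]),
                exon_status=str(rec["exon_status"]),
                codon_position=str(rec["codon_position"]),
                isogroup_id=iso,
            )
        )
    return rows


def write_snp_table(rows: Sequence[SnpTableRow], path: str | Path) -> None:
    """Write SNPs as a TSV with a fixed header (empty input → header only)."""
    _rows_to_frame(rows).to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> list[SnpTableRow]:
    """Read a SNP TSV; extra columns are tolerated, missing ones rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _frame_to_rows(df, str(path))


def read_snp_table_xlsx(
    path: str | Path, sheet: str | int = 0
) -> list[SnpTableRow]:
    """Read a SNP table from one sheet of a spreadsheet workbook.

    Supports supplementary-style SNP discovery workbooks, provided the
    sheet carries (at least) the standard columns of :data:`SNP_TABLE_COLUMNS`;
    extra columns are ignored.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    return _frame_to_rows(df, str(path))


# ---------------------------------------------------------------------------
# isogroup map
# ---------------------------------------------------------------------------

def read_isogroup_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping contig_id → isogroup_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("contig_id", "isogroup_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["contig_id"], df["isogroup_id"]))


def write_isogroup_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["contig_id", "isogroup_id"]
    ).to_csv(path, sep="\t", index=False)
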