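"""Ground-truthed simulation of a 454-style transcriptome SNP experiment.

The generator produces everything the pipeline consumes — soft-masked
contigs, pre-aligned reads, translated-search HSPs, an isogroup map — plus
a truth table of planted variant sites, so every stage can be tested
end-to-end with exact expectations and no external data.

What is emulated:

* contigs with an assembler-like log-normal length distribution (median
  ~500 bp, matching the ~502 bp average contig size of a Titanium-era
  transcriptome assembly), partially repeat-masked in contiguous blocks;
* planted biallelic substitution sites with configurable minor-allele
  frequency and a transition:transversion ratio (default 2:1);
* reads sampled along each contig with 454-like lengths (normal, mean
  350 bp, sd 100, truncated at 50), carrying the planted alleles at their
  site frequencies, uniform substitution errors, and the signature 454
  error mode — single-base insertions/deletions inside homopolymer runs
  (length >= 3), encoded either as exact I/D CIGAR ops or, for a
  configurable fraction of indel reads, as the ungapped misalignment a
  gap-unaware aligner would produce (the source of clustered artifact
  SNPs);
* in-frame translated HSPs over a fraction of contigs (both frames), with
  a configurable fraction receiving a second, frame-shifted HSP that
  conflicts at every covered position.

Reads are emitted pre-aligned — their true coordinates are known by
construction — so no mapper runs and downstream expectations are exact.
Quality strings, flowgram noise and transcript-abundance structure are
deliberately not modelled (the emulated library is normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .filters import FilterConfig
from .io_formats import (
    MaskedContig,
    ProteinAlignmentRecord,
    ReadAlignmentRecord,
    SnpTableRow,
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimulationConfig:
    """Knobs of the simulated experiment; defaults are the study conditions.

    ``snp_density`` defaults to one site per 483 bp, the density the
    pipeline is expected to operate at.  ``titv_ratio`` is the planted
    transition:transversion ratio.  ``coverage`` is mean reads-per-base.
    ``maf_min``/``maf_max`` bound the uniform minor-allele-frequency draw
    (a pool of several full-sib families yields intermediate frequencies).
    ``homopolymer_indel_rate`` applies per homopolymer run (length >= 3)
    per overlapping read.  ``seed`` fixes the whole output stream.
    """

    n_contigs: int = 100
    contig_length_median: float = 500.0
    contig_length_sigma: float = 0.45
    min_contig_length: int = 150
    gc_fraction: float = 0.45
    snp_density: float = 1.0 / 483.0
    maf_min: float = 0.2
    maf_max: float = 0.5
    titv_ratio: float = 2.0
    coverage: float = 18.0
    read_length_mean: float = 350.0
    read_length_sd: float = 100.0
    read_length_min: int = 50
    substitution_error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.005
    homopolymer_misalignment_fraction: float = 0.5
    mask_fraction: float = 0.10
    orf_fraction: float = 0.6
    conflicting_alignment_fraction: float = 0.1
    mean_contigs_per_isogroup: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "snp_density", "maf_min", "maf_max", "substitution_error_rate",
            "homopolymer_indel_rate", "homopolymer_misalignment_fraction",
            "mask_fraction", "orf_fraction",
            "conflicting_alignment_fraction", "gc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be positive")
        if self.maf_min > self.maf_max:
            raise ValueError("maf_min > maf_max")


@dataclass(frozen=True)
class TruthRecord:
    """One planted variant site with its ground-truth attributes.

    ``survivable`` flags whether the site would pass an ideal filter
    cascade (contig long enough, flanks sufficient, no other planted site
    within the spacing window) given perfect read evidence.
    """

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    minor_frequency: float
    planted_class: str
    planted_codon_position: str  # "1"/"2"/"3"/"none"
    survivable: bool


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces (reads come separately)."""

    contigs: list[MaskedContig]
    truth: list[TruthRecord]
    alignments: list[ProteinAlignmentRecord]
    isogroup_map: dict[str, str]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def generate_truth_set(config: SimulationConfig) -> SimulatedDataset:
    """Sample contigs, masks, variant sites, HSPs and isogroups from seed."""
    rng = np.random.default_rng([config.seed, 0])
    filt = FilterConfig()

    contigs: list[MaskedContig] = []
    truth: list[TruthRecord] = []
    alignments: list[ProteinAlignmentRecord] = []
    isogroup_map: dict[str, str] = {}

    # isogroup sizes: shifted geometric, mean ~= mean_contigs_per_isogroup
    p_geom = min(1.0, 1.0 / config.mean_contigs_per_isogroup)
    group_of: list[str] = []
    g = 0
    while len(group_of) < config.n_contigs:
        g += 1
        size = int(rng.geometric(p_geom))
        group_of.extend([f"ig{g:05d}"] * size)
    group_of = group_of[: config.n_contigs]

    mu = float(np.log(config.contig_length_median))
    for i in range(config.n_contigs):
        length = int(np.exp(rng.normal(mu, config.contig_length_sigma)))
        length = max(length, config.min_contig_length)
        seq = _random_sequence(rng, length, config.gc_fraction)
        mask = _plant_mask(rng, length, config.mask_fraction)
        cid = f"contig{i + 1:05d}"
        isogroup_map[cid] = group_of[i]
        contig = MaskedContig(cid, seq, tuple(mask), group_of[i])

        orf = None
        if rng.random() < config.orf_fraction and length >= 60:
            orf = _plant_orf(rng, cid, length, config, alignments)

        site_positions = _plant_sites(rng, length, config, filt)
        contig_truth = []
        for pos in site_positions:
            ref = seq[pos - 1]
            if rng.random() < config.titv_ratio / (config.titv_ratio + 1.0):
                alt, klass = _TRANSITION[ref], "transition"
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(2)]
                klass = "transversion"
            maf = float(rng.uniform(config.maf_min, config.maf_max))
            codon = _planted_codon(orf, pos)
            contig_truth.append(
                [cid, pos, ref, alt, maf, klass, codon]
            )
        # survivability: ideal cascade with perfect evidence.  The read
        # eligibility rule is part of the cascade: a site is detectable
        # only when the surrounding +/- (min_unmasked_run - 1) bp window is
        # unmasked, which guarantees every read of >= min_unmasked_run bp
        # covering the site carries a qualifying unmasked run.
        positions = [t[1] for t in contig_truth]
        halo = filt.min_unmasked_run - 1
        for rec in contig_truth:
            pos = rec[1]
            ok = length > filt.min_contig_len
            ok = ok and pos - 1 >= filt.min_flank
            ok = ok and length - pos >= filt.min_flank
            ok = ok and all(
                abs(pos - q) >= filt.min_gap for q in positions if q != pos
            )
            lo, hi = max(1, pos - halo), min(length, pos + halo)
            ok = ok and not any(mask[lo - 1 : hi])
            truth.append(TruthRecord(*rec, survivable=ok))
        contigs.append(contig)

    truth.sort(key=lambda t: (t.contig_id, t.position))
    return SimulatedDataset(contigs, truth, alignments, isogroup_map)


def _plant_mask(
    rng: np.random.Generator, length: int, fraction: float
) -> np.ndarray:
    """Masked blocks of geometric length until the target fraction is hit."""
    mask = np.zeros(length, dtype=bool)
    target = int(round(fraction * length))
    guard = 0
    while mask.sum() < target and guard < 100:
        guard += 1
        block = int(rng.geometric(1 / 30.0))  # mean repeat block ~30 bp
        start = int(rng.integers(0, length))
        mask[start : start + block] = True
    return mask


def _plant_sites(
    rng: np.random.Generator,
    length: int,
    config: SimulationConfig,
    filt: FilterConfig,
) -> list[int]:
    n = int(rng.poisson(config.snp_density * length))
    if n == 0:
        return []
    interior = length - 2 * filt.min_flank
    max_fit = 0 if interior < 0 else interior // filt.min_gap + 1
    if n > max_fit:
        warnings.warn(
            f"snp_density infeasible for a {length} bp contig "
            f"({n} sites requested, {max_fit} fit the spacing rule); clipping",
            stacklevel=2,
        )
        n = max_fit
    if n == 0:
        return []
    positions = rng.choice(length, size=min(n, length), replace=False) + 1
    return sorted(int(p) for p in positions)


@dataclass(frozen=True)
class _PlantedOrf:
    start: int  # smaller coordinate, 1-based, inclusive
    end: int    # larger coordinate, inclusive
    frame_sign: int


def _plant_orf(
    rng: np.random.Generator,
    contig_id: str,
    length: int,
    config: SimulationConfig,
    alignments: list[ProteinAlignmentRecord],
) -> _PlantedOrf:
    """Place an in-frame HSP; maybe add a frame-shifted conflicting one.

    The conflicting HSP covers a superset of the primary span with its
    phase shifted by one base, so every site inside the primary span gets
    two covering, disagreeing assignments.
    """
    margin = 3  # room for the widened conflicting HSP
    max_span = ((length - 2 * margin) // 3) * 3
    span = min(max_span, int(rng.integers(30, 301)) // 3 * 3)
    span = max(span, 30) if max_span >= 30 else max_span
    start = int(rng.integers(margin, length - margin - span + 2))
    end = start + span - 1
    sign = 1 if rng.random() < 0.5 else -1
    subject = f"sp|{contig_id}_hit"
    if sign > 0:
        qs, qe = start, end
    else:
        qs, qe = end, start
    alignments.append(
        ProteinAlignmentRecord(contig_id, subject, qs, qe, 1e-20, sign)
    )
    if rng.random() < config.conflicting_alignment_fraction:
        lo, hi = start - 1, end + 2  # span + 3, phase shifted by one
        if sign > 0:
            qs2, qe2 = lo, hi
        else:
            qs2, qe2 = hi, lo
        alignments.append(
            ProteinAlignmentRecord(
                contig_id, subject + "_alt", qs2, qe2, 1e-10, sign
            )
        )
    return _PlantedOrf(start, end, sign)


def _planted_codon(orf: _PlantedOrf | None, pos: int) -> str:
    if orf is None or not orf.start <= pos <= orf.end:
        return "none"
    if orf.frame_sign > 0:
        return str(((pos - orf.start) % 3) + 1)
    return str(((orf.end - pos) % 3) + 1)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    contigs: Sequence[MaskedContig],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
) -> list[ReadAlignmentRecord]:
    """Sample 454-like reads along each contig, pre-aligned by construction.

    At each planted site an overlapping read carries the alternate allele
    with the site's minor frequency.  Substitution errors hit each base
    independently; homopolymer runs of length >= 3 gain or lose one base
    with ``homopolymer_indel_rate`` per run per read, emitted as exact I/D
    CIGAR ops.  A fraction of indel-bearing reads
    (``homopolymer_misalignment_fraction``) is instead aligned ungapped,
    the way a gap-unaware aligner would place it: every base downstream of
    the indel lands one position off, seeding the clustered false variant
    columns that the spacing filter exists to suppress.  Read masks are
    inherited from the contig mask.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth_by_contig: dict[str, list[TruthRecord]] = {}
    for t in truth:
        truth_by_contig.setdefault(t.contig_id, []).append(t)

    reads: list[ReadAlignmentRecord] = []
    counter = 0
    mean_len = config.read_length_mean
    for contig in contigs:
        L = len(contig)
        # fragments are laid on an axis extended by one read length to the
        # left and truncated at the contig boundaries, so interior and
        # edge positions see the same expected depth (contigs are fragments
        # of longer transcripts; reads genuinely run past their ends).
        # Starts are stratified — an even grid with uniform jitter — which
        # keeps per-position depth tightly around the target coverage so
        # recovery tests are exact rather than subject to Poisson dips.
        n_frags = int(round(config.coverage * (L + mean_len - 1) / mean_len))
        if n_frags < 1:
            continue
        stride = (L + mean_len - 1) / n_frags
        sites = truth_by_contig.get(contig.contig_id, ())
        for k in range(n_frags):
            rlen = int(rng.normal(mean_len, config.read_length_sd))
            rlen = max(rlen, config.read_length_min)
            frag_start = int(2 - mean_len + k * stride + rng.uniform(0, stride))
            start = max(frag_start, 1)
            end = min(frag_start + rlen - 1, L)
            if end < start:
                continue
            counter += 1
            reads.append(
                _make_read(
                    rng, f"read{counter:07d}", contig, start,
                    end - start + 1, sites, config,
                )
            )
    reads.sort(key=lambda r: (r.contig_id, r.start, r.read_id))
    return reads


def _make_read(
    rng: np.random.Generator,
    read_id: str,
    contig: MaskedContig,
    start: int,
    rlen: int,
    sites: Sequence[TruthRecord],
    config: SimulationConfig,
) -> ReadAlignmentRecord:
    end = start + rlen - 1  # closed, 1-based
    ref = list(contig.sequence[start - 1 : end])
    msk = list(contig.mask[start - 1 : end])

    # planted alleles
    for t in sites:
        if start <= t.position <= end and rng.random() < t.minor_frequency:
            ref[t.position - start] = t.alt_allele

    # uniform substitution errors
    if config.substitution_error_rate > 0:
        hits = np.flatnonzero(
            rng.random(len(ref)) < config.substitution_error_rate
        )
        for i in hits:
            choices = [b for b in "ACGT" if b != ref[i]]
            ref[int(i)] = choices[rng.integers(3)]

    # homopolymer indels: one event max per run, at the run's end
    events: dict[int, str] = {}  # 0-based ref offset -> "I" or "D"
    if config.homopolymer_indel_rate > 0:
        i = 0
        seq0 = contig.sequence[start - 1 : end]  # runs defined on reference
        while i < len(seq0):
            j = i
            while j < len(seq0) and seq0[j] == seq0[i]:
                j += 1
            if j - i >= 3 and rng.random() < config.homopolymer_indel_rate:
                events[j - 1] = "I" if rng.random() < 0.5 else "D"
            i = j

    # compose read sequence + CIGAR
    bases: list[str] = []
    mask_out: list[bool] = []
    cigar: list[tuple[str, int]] = []

    def _push(op: str, n: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    for k in range(len(ref)):
        ev = events.get(k)
        if ev == "D":
            _push("D")
            continue
        bases.append(ref[k])
        mask_out.append(msk[k])
        _push("M")
        if ev == "I":
            bases.append(ref[k])  # lengthened homopolymer
            mask_out.append(msk[k])
            _push("I")

    if events and rng.random() < config.homopolymer_misalignment_fraction:
        # emulate a gap-unaware alignment of the indel-bearing read: one
        # all-M CIGAR, so bases downstream of each indel shift against the
        # reference and show up as clustered spurious mismatches
        contig_len = len(contig.sequence)
        keep = min(len(bases), contig_len - start + 1)
        bases = bases[:keep]
        mask_out = mask_out[:keep]
        cigar = [("M", keep)]

    return ReadAlignmentRecord.from_sequence(
        read_id=read_id,
        contig_id=contig.contig_id,
        start=start,
        cigar=cigar,
        read_sequence="".join(bases),
        read_mask=mask_out,
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    """Calling performance against the planted truth.

    Sensitivity is computed on the ideal-survivable truth subset; precision
    over all calls (a call is true iff contig, position and unordered
    allele pair match a truth record).  ``titv_estimate`` is None when no
    transversions were called; ``precision`` is None for an empty call set.
    """

    sensitivity: float | None
    precision: float | None
    titv_estimate: float | None
    codon_confusion: dict[tuple[str, str], int] = field(default_factory=dict)
    n_called: int = 0
    n_truth_survivable: int = 0


def evaluate_recovery(
    truth: Sequence[TruthRecord], called: Sequence[SnpTableRow]
) -> RecoveryMetrics:
    by_key: dict[tuple[str, int], TruthRecord] = {
        (t.contig_id, t.position): t for t in truth
    }
    survivable = [t for t in truth if t.survivable]

    n_true_calls = 0
    matched_keys: set[tuple[str, int]] = set()
    n_ti = n_tv = 0
    confusion: dict[tuple[str, str], int] = {}
    for row in called:
        if row.snp_class == "transition":
            n_ti += 1
        else:
            n_tv += 1
        key = (row.contig_id, row.position)
        t = by_key.get(key)
        if t and {row.allele_major, row.allele_minor} == {t.ref_allele, t.alt_allele}:
            n_true_calls += 1
            matched_keys.add(key)
            planted = t.planted_codon_position
            assigned = (
                row.codon_position
                if row.exon_status == "exonic"
                else "none"
            )
            confusion[(planted, assigned)] = confusion.get((planted, assigned), 0) + 1

    n_surv = len(survivable)
    n_found = sum(
        1 for t in survivable if (t.contig_id, t.position) in matched_keys
    )
    return RecoveryMetrics(
        sensitivity=(n_found / n_surv) if n_surv else None,
        precision=(n_true_calls / len(called)) if called else None,
        titv_estimate=(n_ti / n_tv) if n_tv else None,
        codon_confusion=confusion,
        n_called=len(called),
        n_truth_survivable=n_surv,
    )


# ---------------------------------------------------------------------------
# truth table serialization (TSV)
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "contig_id", "position", "ref_allele", "alt_allele",
    "minor_frequency", "planted_class", "planted_codon_position", "survivable",
]


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            [t.contig_id, t.position, t.ref_allele, t.alt_allele,
             t.minor_frequency, t.planted_class, t.planted_codon_position,
             int(t.survivable)]
            for t in truth
        ],
        columns=TRUTH_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[TruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        TruthRecord(
            contig_id=r["contig_id"],
            position=int(r["position"]),
            ref_allele=r["ref_allele"],
            alt_allele=r["alt_allele"],
            minor_frequency=float(r["minor_frequency"]),
            planted_class=r["planted_class"],
            planted_codon_position=r["planted_codon_position"],
            survivable=bool(int(r["survivable"])),
        )
        for r in df.to_dict("records")
    ]
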