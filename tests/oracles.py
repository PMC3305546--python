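"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive expected results by the most literal route
possible (string translation, all-pairs scans, set algebra) and share no
code with the implementation they check.
"""

from Bio.Seq import Seq

from snpmine.filters import FilterConfig


def oracle_codon_position(contig_seq, orf_lo, orf_hi, frame_sign, snp_pos):
    """Translate-and-diff oracle: substitute the base at ``snp_pos``,
    extract the reading frame's codons (reverse-complemented for minus
    frames), and locate which codon base changed."""
    if not orf_lo <= snp_pos <= orf_hi:
        return None
    seq = list(contig_seq)
    original = seq[snp_pos - 1]
    replacement = next(b for b in "ACGT" if b != original)
    mutated = seq.copy()
    mutated[snp_pos - 1] = replacement

    def frame_codons(s):
        sub = Seq("".join(s[orf_lo - 1 : orf_hi]))
        if frame_sign < 0:
            sub = sub.reverse_complement()
        return [str(sub[i : i + 3]) for i in range(0, len(sub), 3)]

    before, after = frame_codons(seq), frame_codons(mutated)
    (changed_codon,) = [i for i, (x, y) in enumerate(zip(before, after)) if x != y]
    (offset,) = [
        j for j in range(3) if before[changed_codon][j] != after[changed_codon][j]
    ]
    return offset + 1


def brute_force_cascade(columns, lengths, cfg=None):
    """Independent replay of the four stated filter rules, set-based:
    evidence (depth >= 5, minor >= 2, third allele < 2), all-pairs 50 bp
    spacing among evidence survivors, then 25 bp flanks."""
    cfg = cfg or FilterConfig()
    cands = []
    for col in columns:
        if len(col.counts) < 2:
            continue
        ranked = sorted(col.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cands.append((col, ranked))
    stage1 = [
        (col, ranked)
        for col, ranked in cands
        if col.depth >= cfg.min_total
        and ranked[1][1] >= cfg.min_minor
        and (len(ranked) < 3 or ranked[2][1] < cfg.min_minor)
    ]
    survivors = []
    for col, ranked in stage1:
        close = any(
            other.contig_id == col.contig_id
            and other.position != col.position
            and abs(other.position - col.position) < cfg.min_gap
            for other, _ in stage1
        )
        if not close:
            survivors.append((col, ranked))
    return {
        (col.contig_id, col.position, ranked[0][0], ranked[1][0])
        for col, ranked in survivors
        if col.position - 1 >= cfg.min_flank
        and lengths[col.contig_id] - col.position >= cfg.min_flank
    }
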