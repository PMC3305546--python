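# Methods

This note documents the model behind `snpmine`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Pipeline model and assumptions

The pipeline assumes a transcriptome assembled from pooled 454 reads of
several outbred individuals, so true polymorphisms appear as intermediate-
frequency biallelic columns in the read pileup, while sequencing errors
appear as low-count singletons and misaligned homopolymer indels appear as
*clusters* of spurious mismatch columns. The filter cascade encodes those
expectations directly rather than fitting a genotype-likelihood model:

- **Read eligibility (min_unmasked_run = 100 bp).** Reads are assumed to
  have been repeat-screened upstream; a read qualifies only if it has at
  least 100 consecutive unmasked bases. The upstream description of this
  rule is ambiguous about its direction; we implement the conventional
  reading (repeat-dominated reads are *excluded*), since mapping only
  repeat-dominated reads would be self-defeating. Once a read qualifies,
  all of its aligned bases count — the rule is per read, not per base.
- **Contig length (min_contig_len = 100, strict).** Columns are produced
  only for contigs strictly longer than 100 bp.
- **Evidence (min_total = 5, min_minor = 2).** Total column depth counts
  every non-N base at the column, not just the two modelled alleles. A
  third allele reaching the same min_minor evidence level disqualifies the
  site: only clean biallelic substitutions are reported.
- **Spacing (min_gap = 50, drop_both = true).** Distance is |p1 − p2|;
  sites exactly 50 bp apart both survive. Spacing is evaluated only among
  candidates that survived the evidence stage, so a weakly supported
  neighbour cannot veto a good site — the stage order is load-bearing and
  pinned by a test. Whether a close pair loses one member or both is not
  derivable from the upstream description; we drop both (conservative, and
  consistent with the rule's purpose of suppressing homopolymer artifact
  clusters, where *no* member of the cluster is trustworthy). A
  `spacing_drop_both=false` switch keeps the earlier member of each pair
  via a greedy left-to-right sweep.
- **Flanks (min_flank = 25).** Both flanks must be at least 25 bp, so
  accepted sites can seed assay design.
- **Audit.** Every removal is attributed to the first failing stage in the
  order depth → minor_allele → multiallelic → spacing → flank, so
  candidates = accepted + Σ removals always holds.

Indel variation is excluded by construction: deletions advance along the
reference without contributing alleles, insertions never touch a column.
Ties between equally supported alleles break alphabetically, for
determinism.

## Codon-position model

A translated-search HSP begins in-frame, so its query start sits on codon
position 1 of its reading frame. That anchoring is the core coordinate
assumption: for a plus-frame HSP, position(p) = ((p − qstart) mod 3) + 1;
for a minus-frame HSP, qstart is the numerically larger coordinate and
position(p) = ((qstart − p) mod 3) + 1. The implementation is checked at
every covered position against an independent translate-and-diff oracle
(substitute the base, extract the frame's codons, find the changed codon
base).

Consolidation across a query's HSPs: coverage by any HSP establishes
exonic status; a definite codon position requires that all covering HSPs
agree, otherwise the site is exonic/uncertain. Non-covering HSPs neither
support nor contradict. Exonic status deliberately needs no agreement —
uncertain-but-exonic is a distinct, reportable class. Queries are
annotated independently by id; no cross-query merging is attempted.

## Synthetic data: what it emulates

`SimulationConfig` defaults describe the emulated experiment:

| parameter | default | rationale |
|---|---|---|
| contig_length_median / sigma | 500 bp / 0.45 | log-normal, matching the ~502 bp average contig of a Titanium-era transcriptome assembly |
| coverage | 18× | average assembly depth of ~18× in the emulated setting (criterion runs use 25×) |
| read_length mean/sd/min | 350 / 100 / 50 bp | aligned bases per aligned read ≈ 366 bp in the emulated setting |
| snp_density | 1/483 bp | overall discovered SNP density |
| titv_ratio | 2.0 | the ~2:1 transition:transversion ratio typical of transcribed sequence |
| maf_min–maf_max | 0.2–0.5 | a pool of several full-sib families yields intermediate allele frequencies |
| substitution_error_rate | 0.001 | per-base miscall rate typical of quality-trimmed 454 reads |
| homopolymer_indel_rate | 0.005 per run ≥ 3 | the dominant 454 error mode |
| homopolymer_misalignment_fraction | 0.5 | fraction of indel reads aligned ungapped (see below) |
| mask_fraction | 0.10 | repeat-masked fraction, in ~30 bp blocks |
| orf_fraction / conflicting_alignment_fraction | 0.6 / 0.1 | contigs carrying a simulated in-frame HSP; fraction receiving a second, frame-shifted conflicting HSP |

Design choices worth calling out:

- **Reads are emitted pre-aligned.** Mapping is out of scope, and known
  coordinates make downstream expectations exact.
- **Stratified fragment starts.** Fragments are laid on an axis extended
  one read length past the contig start, on an even grid with uniform
  jitter, and truncated at contig boundaries. This keeps per-position
  depth tightly around the target coverage, including at contig edges
  (contigs are fragments of longer transcripts, so reads genuinely run
  past their ends). IID-uniform starts would leave edges undercovered and
  produce Poisson depth dips that turn the exact-recovery tests into
  coin flips; a low-dispersion sampler makes them deterministic in
  practice.
- **Two homopolymer encodings.** An indel inside a homopolymer run
  (length ≥ 3, one event per run per read, insertion/deletion 50:50 at the
  run's end) is encoded either as an exact I/D CIGAR op — which, by
  construction, creates *no* false substitution columns — or, with
  probability `homopolymer_misalignment_fraction`, as the ungapped
  alignment a gap-unaware aligner would emit, which shifts every
  downstream base by one and seeds the clustered artifact columns the
  50 bp spacing rule exists to remove. Both modes are real behaviours of
  historical 454 pipelines; without the second, the spacing filter would
  have nothing to do in simulation.
- **The `survivable` truth flag** marks sites that an ideal cascade could
  accept given perfect read evidence: contig length > 100, flanks ≥ 25,
  no other planted site within 50 bp, *and* an unmasked window of ±99 bp
  around the site. The last condition reflects the eligibility rule: it
  guarantees every read of ≥ 100 bp covering the site contains a
  qualifying unmasked run, whereas a site inside a repeat-dense region can
  never accumulate eligible depth no matter how deep the sequencing.
  Recovery metrics (sensitivity on the survivable subset, precision over
  all calls) are exact — 1.0/1.0 — for error-free runs at ≥ 20×.
- **Planted ORFs** are coordinate fictions: the HSP records are emitted
  in-frame over a subinterval of the contig, but the underlying sequence
  is random (no start/stop codon structure). The codon-position logic
  only consumes coordinates, so this loses nothing. A conflicting HSP
  covers a one-codon-wider span with its phase shifted by one base, so
  every site under the primary HSP gets two covering, disagreeing
  assignments.
- **Density clipping.** If the requested SNP density cannot fit the 50 bp
  spacing rule on a contig, the site count is clipped with a warning.

What the simulator does *not* model — and therefore what passing tests do
not show about real data: flowgram-level noise and quality strings,
transcript-abundance structure (the emulated library is normalized),
mapping ambiguity between paralogs (paralogous sequence variants will
inflate real SNP counts, especially in lineages with recent genome
duplication), chimeric reads, and allele-specific expression. Results on
real assemblies depend on upstream mapping quality in ways the simulator
cannot probe.

## Numerical and interface conventions

- Coordinates are 1-based closed intervals at every interface (SAM/BLAST
  convention); any half-open arithmetic is internal.
- Soft-masked FASTA is the native mask representation; `N` is also
  treated as masked so hard-masked input degrades gracefully.
- SAM `SEQ` case is not preserved by standard parsers, so per-read masks
  travel in an `XM:Z:` 0/1 tag on write and are honoured on read;
  lowercase sequences still work for records built in memory.
- BLAST tabular records with a nucleotide span that is not a whole number
  of codons are dropped with a warning count (they cannot be in-frame
  HSPs); the frame sign comes from the explicit 13th column when present,
  else from the coordinate order.
- Reported means are kept at full precision and rounded half-even to one
  decimal only for display. The denominator of the bp-per-SNP density is
  supplied by the caller (total assembled bases vs bases of SNP-bearing
  contigs is a reporting choice, not a property of the call set).
- Empty inputs yield empty-but-valid outputs everywhere (header-only
  tables, zero summaries with the density reported as absent).

## Problem sizes in the test suite

Oracle-equivalence tests run 1,000 random pileup instances and 1,000
random ORFs; recovery tests simulate 100 contigs (~55 kb, ~500 planted
sites) at 25×, chosen so the whole suite completes in well under a minute
per test while the binomial checks retain power. `scripts/acceptance.py`
re-runs the 100-contig experiment twice (error-free and default error
model) in a few seconds.
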