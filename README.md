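# snpmine

Pileup-based SNP mining for 454-era transcriptome assemblies.

Sequencing a pooled, normalized cDNA library from several outbred families
and assembling it into contigs leaves thousands of single-nucleotide
polymorphisms hiding in the read alignments. `snpmine` re-implements the
classic discovery workflow for that setting: it stacks reads aligned to
assembly contigs into per-position allele counts, applies an accuracy
filter cascade tuned for 454 pyrosequencing error modes, classifies each
surviving site as a transition or transversion, and assigns exon status
and codon position from translated-search (BLASTx-style) alignment
coordinates. It is aimed at researchers mining markers from non-model
transcriptomes, and at anyone who needs a transparent, fully tested
reference for this class of pipeline.

## The method

A site on a contig of length $L$ with allele counts
$n_1 \ge n_2 \ge n_3 \ge n_4$ (over A/C/G/T; N never counts) at position
$p$ becomes an accepted SNP iff all of:

1. **evidence** — total depth $\sum_i n_i \ge 5$ and minor allele
   $n_2 \ge 2$, with no third allele reaching $n_3 \ge 2$ (biallelic only);
2. **spacing** — no other evidence-passing candidate on the same contig
   within 50 bp (both members of a close pair are dropped). Clusters of
   nearby "variants" are the signature of misaligned homopolymer
   insertions/deletions, the dominant 454 error mode;
3. **flanks** — $p - 1 \ge 25$ and $L - p \ge 25$, so the site has usable
   flanking sequence for assay design.

Upstream of the cascade, a read participates in the pileup only if it
carries $\ge 100$ consecutive unmasked (non-repeat) bases, and contigs of
$\le 100$ bp are ignored entirely. Transitions are A$\leftrightarrow$G and
C$\leftrightarrow$T; everything else is a transversion.

For codon assignment, a translated HSP with nucleotide query coordinates
$(q_s, q_e)$ begins in-frame, so for a plus-frame alignment the codon
position of site $p$ is $((p - q_s) \bmod 3) + 1$, and for a minus-frame
alignment (where $q_s > q_e$) it is $((q_s - p) \bmod 3) + 1$. A site is
exonic when at least one HSP of its query covers it; it gets a definite
codon position only when *all* covering HSPs agree, and is otherwise
reported as exonic/uncertain.

The package also ships a ground-truthed simulator of the whole experiment
(log-normal contig lengths, repeat masking, planted biallelic sites with a
2:1 transition:transversion prior, 454-like reads with homopolymer indels
and optional gap-unaware misalignment, consistent and frame-conflicting
protein alignments), so every stage is testable end to end with exact
expectations.

## Worked example

Simulate a small dataset, call SNPs, and summarize:

```bash
cat > simcfg.yaml <<EOF
n_contigs: 40
coverage: 25.0
seed: 7
snp_density: 0.006667   # one planted site per 150 bp
EOF
snpmine simulate --config simcfg.yaml --outdir demo
snpmine call --contigs demo/contigs.fasta --aln demo/reads.sam \
             --blast demo/blast.tsv --isogroups demo/isogroups.tsv \
             --out demo/snps.tsv
snpmine summarize --snps demo/snps.tsv --isogroups demo/isogroups.tsv \
                  --total-bases 20830
```

The `call` step logs its per-filter audit to stderr:

```
reads: 2383 total, 1518 eligible (>= 100 bp unmasked run)
candidate sites: 4747
  removed by depth: 2
  removed by minor_allele: 3985
  removed by multiallelic: 0
  removed by spacing: 686
  removed by flank: 6
accepted SNPs: 68
```

Most raw candidate columns are singleton sequencing errors (killed by the
minor-allele rule), and the 50 bp spacing rule then strips the clustered
artifacts left by misaligned homopolymer indels. `summarize` prints:

```
putative SNPs            68
  transitions            36
  transversions          32
contigs with >=1 SNP     30
  mean SNPs per contig   2.3
  max SNPs in a contig   6
  contigs with one SNP   9
isogroups with >=1 SNP   22
  mean SNPs per isogroup 3.1
  max SNPs in isogroup   16
  isogroups with >=2     16
one SNP every            306 bp
```

`demo/snps.tsv` holds one row per accepted SNP with alleles, counts,
transition/transversion class, exon status, codon position and isogroup.
The same functionality is available as a library (`snpmine.call_snps`,
`snpmine.summarize`, `snpmine.SimulationConfig`, ...).

## Formats

Soft-masked FASTA contigs (lowercase = repeat-masked; `N` also treated as
masked), SAM alignments (CIGAR ops M/=/X/I/D/S; per-read masks in an
`XM:Z:` 0/1 tag), BLAST tabular outfmt-6 with an optional 13th frame
column (frame inferred from coordinate order when absent), TSV SNP tables
and isogroup maps, and `.xlsx` SNP discovery workbooks carrying the same
columns.
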