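# plastann

A self-contained toolkit for annotating circular plastid (chloroplast)
genomes against user-provided GenBank references, with integrated repeat
discovery and exploratory diversity analysis. Everything runs offline —
similarity search, repeat finding and variant calling are internal
implementations, so no external aligner or repeat tool is required.

## What it does

* **Gene annotation** — reference-guided identification of protein-coding
  and rRNA genes via a built-in seeded local aligner (k-mer seeds, x-drop
  extension, Karlin–Altschul-style E-values), HSP chaining into multi-exon
  models, and ORF-aware refinement of start/stop and exon boundaries
  against the reference exon structure.
* **Micro-exons** — the 6–9 bp first exons of *petB*, *petD* and *rpl16*
  are far too short for similarity search; they are located through their
  conserved 50-bp 5′ UTR anchor sequences extracted from the references
  (anchored query scan at E ≤ 1e-20, exon cut out of the hit by the
  reference exon length, start-codon admissibility).
* **Trans-spliced rps12** — exons 1 and 2 located independently, the
  26-bp last exon recovered with the 3′-UTR-anchored scan, and the pieces
  joined per IR copy: a two-IR genome yields two transcripts sharing
  exon 1.
* **tRNA reconciliation** — predictions from two external scanners
  (tRNAscan-SE-like and ARAGORN-like, consumed as files) merged by the
  intron rule: intron-less models are trusted from scanner A,
  intron-bearing ones from scanner B; name mismatches against the
  reference tRNAs go to a warnings file.
* **Repeats** — SSRs (unit 1–6 bp, MISA-tradition thresholds), longer
  tandem repeats (unit > 6 bp, consensus + per-copy identity), and
  dispersed forward/palindromic maximal pairs with a bounded substitution
  count. The inverted-repeat duplication itself is reported once as the
  quadripartite layout, not as a flood of trivial pairs.
* **Diversity** — CIGAR-aware pileup from SAM, transparent threshold SNP
  / heteroplasmy calling, C→U RNA-editing site detection inside CDS exons
  with codon/amino-acid effect annotation, and a similarity-based FASTQ
  prefilter for read enrichment.
* **Outputs** — GFF3 (Apollo-compatible, trans-splicing encoded as one
  gene with multiple mRNAs sharing an exon), GenBank flat file
  (`exception="trans-splicing"`), NCBI 5-column feature table + FASTA for
  submission, and a deterministic SVG circular map with four rings
  (dispersed arcs, tandem bars, SSR ticks, genes by functional category).
* **Synthetic fixtures** — a deterministic quadripartite plastome
  generator with full ground truth (genes, repeats, planted heteroplasmy
  and editing sites) plus a gapless read simulator emitting SAM/FASTQ, so
  the entire pipeline is testable without any external data.

## CLI

```bash
# full annotation run (7 output files in --out)
plastann annotate query.fasta --ref reference.gb --out outdir \
    --trna-a trnascan.out --trna-b aragorn.txt

# repeat discovery (three TSV reports)
plastann repeats query.fasta --out outdir

# SNP and RNA-editing calling from aligned reads
plastann diversity query.fasta --sam reads.sam --gff outdir/plastome.gff3 \
    --mode both --out divdir

# generate the synthetic test plastome
plastann make-fixture --seed 7 --out fixturedir
```

Exit codes: 0 success, 1 hard error, 2 empty annotation.
`--deterministic-log` freezes log timestamps for byte-identical reruns.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracle equivalence checks for all three
repeat finders, self-annotation identity on the synthetic fixture,
round-trip checks for every writer, and recovery tests for the planted
variants/editing sites over many simulator seeds.
`tests/test_acceptance.py` holds one test per acceptance criterion.

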