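"""Exploratory diversity analyses on aligned or raw reads.

Pileup construction is CIGAR-aware (SAM via pysam); SNP and C-to-U
RNA-editing calls are transparent threshold callers over the pileup —
re-running on the same alignments is bit-identical. Only the C-to-U class
(and its antisense mirror, G-to-A on the mapped strand) is detected for
editing; sites are annotated with the codon and amino-acid change through
the gene model's frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from plastann.annotate_core import AnnotationSet, GeneModel, similarity_search
from plastann.genome_model import Plastome, translate_cds

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    position: int  # 1-based
    ref_base: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # base -> (fwd, rev)

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    def base_count(self, base: str) -> int:
        f, r = self.counts.get(base, (0, 0))
        return f + r

    def strand_counts(self, base: str) -> tuple[int, int]:
        return self.counts.get(base, (0, 0))


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref_base: str
    alt_base: str
    alt_fraction: float
    depth: int
    filter: str  # PASS | low_depth | strand_bias


@dataclass(frozen=True)
class EditingSite:
    position: int
    gene: str
    strand: str
    genomic_base: str
    rna_base: str
    editing_level: float
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    depth: int


def build_pileup(
    sam_path: str,
    genome: Plastome,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> list[PileupColumn]:
    """CIGAR-aware per-column base counts from a SAM file.

    Unmapped / secondary / duplicate reads are skipped silently; reads
    below ``min_mapq`` and bases below ``min_baseq`` are excluded.
    Deletions leave coverage gaps (no base counted).
    """
    counts: dict[int, dict[str, list[int]]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if fh.get_reference_name(read.reference_id) != genome.id:
                raise ValueError(
                    f"SAM reference {fh.get_reference_name(read.reference_id)!r} "
                    f"does not match genome {genome.id!r}"
                )
            seq = read.query_sequence
            quals = read.query_qualities
            strand_idx = 1 if read.is_reverse else 0
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos].upper()
                if base not in BASES:
                    continue
                col = counts.setdefault(rpos, {})
                pair = col.setdefault(base, [0, 0])
                pair[strand_idx] += 1
    columns = []
    for rpos in sorted(counts):
        columns.append(
            PileupColumn(
                position=rpos + 1,
                ref_base=genome.sequence[rpos],
                counts={b: (f, r) for b, (f, r) in counts[rpos].items()},
            )
        )
    return columns


def call_snps(
    pileup: list[PileupColumn],
    min_depth: int = 10,
    min_alt_fraction: float = 0.05,
    min_alt_count: int = 3,
) -> list[VariantCall]:
    """Threshold-based SNP / heteroplasmy caller.

    One call per qualifying alt base; ``low_depth`` marks otherwise
    qualifying calls on thin columns, ``strand_bias`` alt alleles seen on
    one strand only with >= 10 supporting reads.
    """
    calls: list[VariantCall] = []
    for col in pileup:
        depth = col.depth
        if depth == 0:
            continue
        for base in BASES:
            if base == col.ref_base:
                continue
            alt = col.base_count(base)
            if alt < min_alt_count or alt / depth < min_alt_fraction:
                continue
            fwd, rev = col.strand_counts(base)
            if depth < min_depth:
                flt = "low_depth"
            elif (fwd == 0 or rev == 0) and alt >= 10:
                flt = "strand_bias"
            else:
                flt = "PASS"
            calls.append(VariantCall(
                position=col.position,
                ref_base=col.ref_base,
                alt_base=base,
                alt_fraction=alt / depth,
                depth=depth,
                filter=flt,
            ))
    return calls


def _cds_walk(model: GeneModel, genome_length: int):
    """Yield (genome_position 1-based, cds_index 0-based) along the CDS."""
    idx = 0
    n = genome_length
    for exon in model.exons:
        iv = exon.interval
        span = iv.span(n)
        if iv.strand == "+":
            positions = [((iv.start - 1 + o) % n) + 1 for o in range(span)]
        else:
            positions = [((iv.end - 1 - o) % n) + 1 for o in range(span)]
        for pos in positions:
            yield pos, idx
            idx += 1


def call_editing_sites(
    pileup: list[PileupColumn],
    annotation: AnnotationSet,
    genome: Plastome,
    min_depth: int = 10,
    min_level: float = 0.1,
) -> list[EditingSite]:
    """C-to-U editing sites inside CDS exons, with codon-effect annotation.

    A site qualifies when the sense-strand genomic base is C and the
    sense-strand RNA mismatch is T (C>T on + genes, G>A on the mapped
    strand for - genes), with depth >= min_depth and editing level >=
    min_level. Sites in overlapping genes yield one record per gene.
    """
    by_pos = {col.position: col for col in pileup}
    sites: list[EditingSite] = []
    n = genome.length
    for model in annotation.models:
        if model.kind != "CDS":
            continue
        cds = model.spliced_seq(genome)
        walk = list(_cds_walk(model, n))
        seen: set[tuple[int, str]] = {(s.position, s.gene) for s in sites}
        for pos, idx in walk:
            if (pos, model.name) in seen:
                continue
            if cds[idx] != "C":  # sense-strand genomic base must be C
                continue
            col = by_pos.get(pos)
            if col is None or col.depth < min_depth:
                continue
            exon_strand = "-" if genome.sequence[pos - 1] != "C" else "+"
            if exon_strand == "+":
                edited = col.base_count("T")
            else:
                edited = col.base_count("A")
            level = edited / col.depth
            if level < min_level:
                continue
            codon_i = idx // 3
            codon_before = cds[codon_i * 3 : codon_i * 3 + 3]
            if len(codon_before) < 3:
                continue
            in_codon = idx % 3
            codon_after = (
                codon_before[:in_codon] + "T" + codon_before[in_codon + 1 :]
            )
            aa_before = translate_cds(codon_before + "TAA").protein[:1] or "*"
            aa_after = translate_cds(codon_after + "TAA").protein[:1] or "*"
            sites.append(EditingSite(
                position=pos,
                gene=model.name,
                strand=exon_strand,
                genomic_base="C",
                rna_base="T",
                editing_level=level,
                codon_before=codon_before,
                codon_after=codon_after,
                aa_before=aa_before,
                aa_after=aa_after,
                depth=col.depth,
            ))
    sites.sort(key=lambda s: (s.position, s.gene))
    return sites


# ---------------------------------------------------------------------------
# Read prefiltering (similarity-based enrichment before upload/analysis)
# ---------------------------------------------------------------------------


def _read_passes(
    seq: str, targets: Plastome, min_identity: float, min_cov: float
) -> bool:
    if len(seq) < 8 or set(seq) - set("ACGTN"):
        return False
    hits = similarity_search(seq, targets, "nucleotide", min_evalue=10.0)
    for h in hits[:5]:
        if h.identity >= min_identity and (h.q1 - h.q0) >= min_cov * len(seq):
            return True
    return False


def prefilter_reads(
    fastq_in: str,
    fastq_out: str,
    gene_seqs: list[str],
    mate_in: str | None = None,
    mate_out: str | None = None,
    min_identity: float = 0.9,
    min_cov: float = 0.5,
) -> dict[str, int]:
    """Keep reads whose best local alignment to any gene passes the
    identity/coverage thresholds (either strand); a pair passes when either
    mate does. Malformed records are skipped and counted.
    """
    if not gene_seqs:
        raise ValueError("gene set must be non-empty")
    target = Plastome(
        id="genes",
        sequence=("N" * 50).join(gene_seqs),
        circular=False,
    )

    def parse_fastq(path: str):
        with open(path) as fh:
            block: list[str] = []
            for line in fh:
                block.append(line.rstrip("\n"))
                if len(block) == 4:
                    yield block
                    block = []
            if block:
                yield block  # malformed trailing record

    stats = {"input": 0, "kept": 0, "malformed": 0}

    def record_ok(rec: list[str]) -> bool:
        return (
            len(rec) == 4
            and rec[0].startswith("@")
            and rec[2].startswith("+")
            and len(rec[1]) == len(rec[3])
        )

    if mate_in is None:
        with open(fastq_out, "w") as out:
            for rec in parse_fastq(fastq_in):
                stats["input"] += 1
                if not record_ok(rec):
                    stats["malformed"] += 1
                    continue
                if _read_passes(rec[1].upper(), target, min_identity, min_cov):
                    stats["kept"] += 1
                    out.write("\n".join(rec) + "\n")
        return stats

    with open(fastq_out, "w") as out1, open(mate_out or fastq_out + ".2", "w") as out2:
        for rec1, rec2 in zip(parse_fastq(fastq_in), parse_fastq(mate_in)):
            stats["input"] += 2
            if not (record_ok(rec1) and record_ok(rec2)):
                stats["malformed"] += 2
                continue
            if _read_passes(rec1[1].upper(), target, min_identity, min_cov) or \
               _read_passes(rec2[1].upper(), target, min_identity, min_cov):
                stats["kept"] += 2
                out1.write("\n".join(rec1) + "\n")
                out2.write("\n".join(rec2) + "\n")
    return stats


def write_variants_tsv(calls: list[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref\talt\talt_fraction\tdepth\tfilter\n")
        for c in calls:
            fh.write(
                f"{c.position}\t{c.ref_base}\t{c.alt_base}"
                f"\t{c.alt_fraction:.4f}\t{c.depth}\t{c.filter}\n"
            )


def write_editing_tsv(sites: list[EditingSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tgene\tstrand\tgenomic_base\trna_base\tediting_level"
            "\tdepth\tcodon_change\taa_change\n"
        )
        for s in sites:
            fh.write(
                f"{s.position}\t{s.gene}\t{s.strand}\t{s.genomic_base}\t{s.rna_base}"
                f"\t{s.editing_level:.4f}\t{s.depth}"
                f"\t{s.codon_before}>{s.codon_after}\t{s.aa_before}>{s.aa_after}\n"
            )
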