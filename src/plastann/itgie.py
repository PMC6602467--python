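"""Trans-spliced rps12 assembly from individually located exons.

Exon 1 (large single-copy region) and exon 2 (inverted repeats) are
located independently by similarity search against per-exon reference
sets; the micro last exon is recovered with the 3'-anchored small-exon
finder, constrained downstream of each exon-2 copy. Each (exon2, exon3)
pair within one IR copy joins the single exon 1 into a transcript, so a
two-IR genome yields two transcripts sharing exon 1.
"""

from __future__ import annotations

import logging

from plastann.genome_model import (
    Exon,
    Interval,
    Plastome,
    QuadripartiteLayout,
    STOP_CODONS,
    translate_cds,
)
from plastann.annotate_core import (
    GeneModel,
    _pad,
    _padded_to_interval,
    similarity_search,
)
from plastann.isecus import find_small_exon, _project_exon
from plastann.reference_db import ReferenceDB, build_anchor_table

logger = logging.getLogger(__name__)

GENE = "rps12"


def _locate_copies(
    seqs: list[str], genome: Plastome, evalue_cutoff: float
) -> list[tuple[int, int, str, float]]:
    """All genomic loci matching any of the reference exon sequences.

    Returns per-locus best (s0, e0, strand, score) full-query projections
    in padded 0-based coordinates, sorted by descending score.
    """
    padded_len = len(_pad(genome))
    raw: list[tuple[int, int, str, float]] = []
    for seq in seqs:
        if len(seq) < 8:
            continue
        for hsp in similarity_search(seq, genome, "nucleotide", evalue_cutoff,
                                     query_name=GENE):
            s0, e0 = _project_exon(hsp, 0, len(seq))
            if s0 < 0 or e0 > padded_len:
                continue
            raw.append((s0, e0, hsp.strand, hsp.score))
    raw.sort(key=lambda c: (-c[3], c[0]))
    loci: list[tuple[int, int, str, float]] = []
    for cand in raw:
        s0, e0, strand, score = cand
        if any(
            min(e0, l_e0) - max(s0, l_s0) > 0.5 * (e0 - s0)
            for l_s0, l_e0, _, _ in loci
        ):
            continue
        loci.append(cand)
    return loci


def _in_ir(iv: Interval, layout: QuadripartiteLayout | None, n: int) -> bool:
    if layout is None:
        return False
    mid = iv.start + iv.span(n) // 2
    if mid > n:
        mid -= n
    return layout.ira.contains(mid, n) or layout.irb.contains(mid, n)


def assemble_rps12(
    genome: Plastome,
    db: ReferenceDB,
    layout: QuadripartiteLayout | None,
    max_intron: int = 2000,
    evalue_cutoff: float = 1e-20,
    warnings: list | None = None,
) -> list[GeneModel]:
    """Assemble the trans-spliced rps12 transcripts.

    A genome with two IR-resident exon-2 copies yields two transcripts
    sharing exon 1; one copy (or no layout) yields one transcript.
    References with a two-exon rps12 assemble analogously without exon 3.
    """
    from plastann._warnings import Warning as Warn

    def warn(message: str, severity: str = "warn") -> None:
        if warnings is not None:
            warnings.append(Warn(category="itgie", subject=GENE,
                                 severity=severity, message=message))

    refs = [g for g in db.by_name(GENE) if g.kind == "CDS"]
    if not refs:
        return []
    n_ref_exons = max(len(g.exons) for g in refs)
    exon1_seqs = sorted({g.exons[0].seq for g in refs})
    exon2_seqs = sorted({g.exons[1].seq for g in refs if len(g.exons) >= 2})
    n = genome.length

    exon1_loci = _locate_copies(exon1_seqs, genome, evalue_cutoff)
    non_ir = [c for c in exon1_loci
              if not _in_ir(_padded_to_interval(c[0], c[1], n, c[2]), layout, n)]
    pool = non_ir or exon1_loci
    if not pool:
        warn("exon 1 not found; no transcript assembled")
        return []
    if len(non_ir) >= 2:
        warn(f"exon 1 found at {len(non_ir)} single-copy locations; keeping the best")
    e1_s0, e1_e0, e1_strand, e1_score = pool[0]
    exon1_iv = _padded_to_interval(e1_s0, e1_e0, n, e1_strand)

    exon2_loci = _locate_copies(exon2_seqs, genome, evalue_cutoff)
    if not exon2_loci:
        warn("exon 2 not found; no transcript assembled")
        return []
    exon2_loci.sort(key=lambda c: c[0])

    three_prime_anchors = [
        a for a in build_anchor_table(db)
        if a.gene == GENE and a.side == "three_prime" and a.valid
    ]

    models: list[GeneModel] = []
    for idx, (s0, e0, strand, score) in enumerate(exon2_loci, start=1):
        exon2_iv = _padded_to_interval(s0, e0, n, strand)
        exon_ivs = [exon1_iv, exon2_iv]
        partial_3p = False
        notes: list[str] = []
        total_score = e1_score + score
        if n_ref_exons >= 3:
            exon3 = find_small_exon(
                genome, three_prime_anchors, evalue_cutoff=evalue_cutoff,
                partner_exon=exon2_iv, max_intron=max_intron,
            )
            if exon3 is None:
                partial_3p = True
                notes.append("micro last exon not found for this IR copy")
                warn(f"exon 3 missing downstream of exon-2 copy {idx}; "
                     "transcript emitted as 2-exon, 3'-partial")
            else:
                exon_ivs.append(exon3.interval)

        exons = []
        cum = 0
        for ordinal, iv in enumerate(exon_ivs, start=1):
            exons.append(Exon(interval=iv, phase=(3 - cum % 3) % 3, ordinal=ordinal))
            cum += iv.span(n)

        strands = {iv.strand for iv in exon_ivs}
        model = GeneModel(
            name=GENE,
            kind="CDS",
            exons=exons,
            strand=strand if len(strands) == 1 else "mixed",
            trans_spliced=True,
            partial_3p=partial_3p,
            provenance="itgie",
            notes=notes,
            score=total_score,
            transcript_id=f"{GENE}.t{idx}",
            shared_exon_ref=1,
        )
        cds = model.spliced_seq(genome)
        if not partial_3p:
            ok = (
                len(cds) % 3 == 0
                and cds.startswith("ATG")
                and cds[-3:] in STOP_CODONS
                and not translate_cds(cds).internal_stop
            )
            if not ok:
                model.notes.append("joined CDS fails ORF sanity check")
        models.append(model)
    return models
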