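"""Anchored micro-exon finder.

Micro exons (6-9 bp) are far too short for similarity search on their own.
They are located instead through a conserved 50-bp UTR anchor taken from
the reference: the scan query is anchor+exon (5' side) or exon+anchor
(3' side), and the micro exon is cut out of the best admissible hit by the
reference exon length. Admissibility requires the expected start/stop
codon and, when a partner exon is known, the correct placement relative to
it in transcription orientation within the intron bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from plastann.genome_model import Exon, Interval, Plastome, STOP_CODONS, revcomp
from plastann.annotate_core import (
    GeneModel,
    _pad,
    _padded_to_interval,
    similarity_search,
)
from plastann.reference_db import AnchorRecord, normalize_gene_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class _Candidate:
    s0: int  # padded 0-based start of the exon footprint
    e0: int
    strand: str
    score: float
    gap: int  # distance to the partner exon (large when no partner given)


def _project_exon(hsp, ex_q0: int, ex_q1: int) -> tuple[int, int]:
    """Map the query exon region through the HSP diagonal to padded coords."""
    if hsp.strand == "+":
        base = hsp.t0 - hsp.q0
        return base + ex_q0, base + ex_q1
    return hsp.t1 - (ex_q1 - hsp.q0), hsp.t1 - (ex_q0 - hsp.q0)


def find_small_exon(
    genome: Plastome,
    anchors: list[AnchorRecord],
    evalue_cutoff: float = 1e-20,
    partner_exon: Interval | None = None,
    max_intron: int = 2000,
) -> Exon | None:
    """Locate a micro exon via its conserved UTR anchor.

    All anchors (same gene and side) are scanned; the globally best
    admissible hit wins. Ties prefer the hit nearest the partner exon in
    transcription orientation, then the smallest genomic start. Returns
    None when no anchor yields an admissible exon.
    """
    if not anchors:
        return None
    sides = {a.side for a in anchors}
    genes = {a.gene for a in anchors}
    if len(sides) != 1 or len(genes) != 1:
        raise ValueError("anchors must share one gene and one side")
    side = sides.pop()
    padded = _pad(genome)
    n = genome.length

    candidates: list[_Candidate] = []
    for anchor in anchors:
        query = anchor.query_seq
        if side == "five_prime":
            ex_q0, ex_q1 = len(anchor.anchor_seq), len(query)
        else:
            ex_q0, ex_q1 = 0, anchor.exon_len
        hits = similarity_search(
            query, genome, "nucleotide", evalue_cutoff,
            query_name=anchor.gene,
        )
        for hsp in hits:
            if min(hsp.q1, ex_q1) - max(hsp.q0, ex_q0) < 1:
                logger.warning(
                    "%s anchor hit at %d does not reach the exon region; skipped",
                    anchor.gene, hsp.t0 + 1,
                )
                continue
            s0, e0 = _project_exon(hsp, ex_q0, ex_q1)
            if s0 < 0 or e0 > len(padded):
                continue
            seq = padded[s0:e0]
            coding = revcomp(seq) if hsp.strand == "-" else seq
            if side == "five_prime" and not coding.startswith("ATG"):
                continue
            if side == "three_prime" and coding[-3:] not in STOP_CODONS:
                continue
            gap = 10 * len(padded)
            if partner_exon is not None:
                if partner_exon.strand != hsp.strand:
                    continue
                p0, p1 = partner_exon.start - 1, partner_exon.end
                upstream = side == "five_prime"
                if hsp.strand == "-":
                    upstream = not upstream
                if upstream:
                    gap = p0 - e0
                else:
                    gap = s0 - p1
                if gap < 0 or gap > max_intron:
                    continue
            candidates.append(_Candidate(s0, e0, hsp.strand, hsp.score, gap))

    if not candidates:
        logger.warning("no admissible micro-exon hit for %s", genes.pop() if genes else "?")
        return None
    best = min(candidates, key=lambda c: (-c.score, c.gap, c.s0))
    return Exon(
        interval=_padded_to_interval(best.s0, best.e0, n, best.strand),
        phase=0,
        ordinal=1,
    )


def attach_micro_exon(
    model: GeneModel,
    genome: Plastome,
    anchor_table: list[AnchorRecord],
    evalue_cutoff: float = 1e-20,
    max_intron: int = 2000,
    warnings: list | None = None,
) -> GeneModel:
    """Prepend the anchored first exon to a core model missing it.

    When no admissible micro exon is found the model is returned with
    ``partial_5p`` set and a warning appended.
    """
    from plastann._warnings import Warning as Warn

    name = normalize_gene_name(model.name)
    anchors = [
        a for a in anchor_table
        if a.gene == name and a.side == "five_prime" and a.valid
    ]
    partner = model.exons[0].interval
    exon1 = find_small_exon(
        genome, anchors, evalue_cutoff=evalue_cutoff,
        partner_exon=partner, max_intron=max_intron,
    ) if anchors else None
    if exon1 is None:
        model.partial_5p = True
        model.notes.append("anchored first exon not found")
        if warnings is not None:
            warnings.append(Warn(
                category="isecus", subject=name, severity="warn",
                message=f"micro first exon of {name} not found; model left 5'-partial",
            ))
        return model

    n = genome.length
    intervals = [exon1.interval] + [e.interval for e in model.exons]
    exons = []
    cum = 0
    for idx, iv in enumerate(intervals, start=1):
        exons.append(Exon(interval=iv, phase=(3 - cum % 3) % 3, ordinal=idx))
        cum += iv.span(n)
    model.exons = exons
    model.partial_5p = False
    model.provenance = "isecus"
    spliced = model.spliced_seq(genome)
    if not spliced.startswith("ATG") or len(spliced) % 3 != 0:
        model.notes.append("micro-exon model fails ORF sanity check")
    return model
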