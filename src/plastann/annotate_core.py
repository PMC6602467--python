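"""Similarity-based gene identification: seeded local search, HSP chaining
into exon models, and ORF-aware gene-model refinement.

The search engine is a self-contained seed-and-extend local aligner
(exact k-mer seeds merged per diagonal, x-drop ungapped extension).
Gaps between exons are handled at the chaining level rather than inside a
single alignment. E-values use a Karlin-Altschul-style scaling with
blastn-like constants (match +2 / mismatch -3, lambda 0.625, K 0.41);
protein mode scores with BLOSUM62 (lambda 0.267, K 0.041).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace

from Bio.Align import substitution_matrices

from plastann.genome_model import (
    Exon,
    Interval,
    Plastome,
    STOP_CODONS,
    revcomp,
    translate_cds,
)
from plastann.reference_db import ReferenceDB, ReferenceGene, normalize_gene_name

logger = logging.getLogger(__name__)

MATCH, MISMATCH = 2, -3
XDROP = 40
NT_LAMBDA, NT_K = 0.67, 0.41  # ungapped +2/-3 scaling, calibrated
AA_LAMBDA, AA_K = 0.267, 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _evalue(score: float, m: int, n: int, protein: bool) -> float:
    lam, k = (AA_LAMBDA, AA_K) if protein else (NT_LAMBDA, NT_K)
    bits = (lam * score - math.log(k)) / math.log(2)
    return m * n * 2.0 ** (-bits)


def _padded_to_interval(t0: int, t1: int, n: int, strand: str) -> Interval:
    """0-based half-open segment on the circularly padded genome -> Interval."""
    if t0 >= n:
        t0, t1 = t0 - n, t1 - n
    if t1 <= n:
        return Interval(start=t0 + 1, end=t1, strand=strand)
    return Interval(start=t0 + 1, end=t1 - n, strand=strand, wraps_origin=True)


@dataclass
class HSP:
    """Ungapped local alignment between a query and the genome.

    ``q0/q1`` and ``t0/t1`` are 0-based half-open; ``t0/t1`` live on the
    circularly padded target and may exceed the genome length (the derived
    ``t_interval`` wraps the origin then). For minus-strand hits, ascending
    query positions map to descending target positions.
    """

    query_gene: str
    q0: int
    q1: int
    t0: int
    t1: int
    strand: str
    score: float
    identity: float
    evalue: float
    frame: int = 0
    genome_length: int = 0

    @property
    def q_interval(self) -> Interval:
        return Interval(start=self.q0 + 1, end=self.q1)

    @property
    def t_interval(self) -> Interval:
        return _padded_to_interval(self.t0, self.t1, self.genome_length, self.strand)


def _kmer_index(seq: str, k: int, max_hits: int = 200) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        bucket = index.setdefault(word, [])
        if len(bucket) < max_hits:
            bucket.append(i)
    return index


def _extend_ungapped(
    q: str, t: str, qs: int, qe: int, diag: int, xdrop: int = XDROP
) -> tuple[int, int, float, int]:
    """X-drop extension of an exact seed run q[qs:qe] == t[qs+diag:qe+diag].

    Returns (q_start, q_end, score, matches) of the max-scoring segment.
    """
    cur = best = float(MATCH * (qe - qs))
    best_qe = qe
    i = qe
    while i < len(q) and i + diag < len(t):
        a, b = q[i], t[i + diag]
        cur += MATCH if (a == b and a != "N") else MISMATCH
        i += 1
        if cur > best:
            best, best_qe = cur, i
        elif best - cur > xdrop:
            break
    cur = best
    best_qs = qs
    i = qs - 1
    while i >= 0 and i + diag >= 0:
        a, b = q[i], t[i + diag]
        cur += MATCH if (a == b and a != "N") else MISMATCH
        if cur > best:
            best, best_qs = cur, i
        elif best - cur > xdrop:
            break
        i -= 1
    matches = sum(
        1 for j in range(best_qs, best_qe) if q[j] == t[j + diag] and q[j] != "N"
    )
    return best_qs, best_qe, best, matches


def _scan_one_strand(query: str, target: str, k: int) -> list[tuple[int, int, int, float, int]]:
    """(diag, q_start, q_end, score, matches) segments of query vs target."""
    index = _kmer_index(target, k)
    diag_seeds: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        word = query[i : i + k]
        if "N" in word:
            continue
        for t in index.get(word, ()):
            diag_seeds.setdefault(t - i, []).append(i)
    segments: dict[tuple[int, int, int], tuple[float, int]] = {}
    for diag, starts in diag_seeds.items():
        starts.sort()
        covered_until = -1
        for qs in starts:
            if qs < covered_until:
                continue
            qe = qs + k
            while (
                qe < len(query)
                and qe + diag < len(target)
                and query[qe] == target[qe + diag] != "N"
            ):
                qe += 1
            bqs, bqe, score, matches = _extend_ungapped(query, target, qs, qe, diag)
            covered_until = bqe
            segments[(diag, bqs, bqe)] = (score, matches)
    return [
        (diag, qs, qe, score, matches)
        for (diag, qs, qe), (score, matches) in segments.items()
    ]


def _pad(genome: Plastome, max_span: int = 6000) -> str:
    """Circular scanning substrate: sequence + leading bases appended."""
    if not genome.circular:
        return genome.sequence
    pad = min(genome.length, max_span)
    return genome.sequence + genome.sequence[:pad]


def similarity_search(
    query: str,
    target: Plastome,
    mode: str = "nucleotide",
    min_evalue: float = 1e-6,
    query_name: str = "query",
) -> list[HSP]:
    """Local similarity search of a query against both strands of a genome.

    Returns HSPs with E-value <= ``min_evalue``, sorted by descending
    score. ``mode`` is "nucleotide" (DNA query) or "translated" (protein
    query searched against all six reading frames of the genome).
    """
    if mode == "translated":
        return _translated_search(query, target, min_evalue, query_name)
    if set(query) - set("ACGTN"):
        raise ValueError("invalid nucleotide query alphabet")
    if len(query) < 8:
        raise ValueError("nucleotide query shorter than 8 bp")
    n = target.length
    padded = _pad(target)
    k = 11 if len(query) >= 100 else 9 if len(query) >= 20 else 7
    hsps: list[HSP] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for diag, qs, qe, score, matches in _scan_one_strand(q, padded, k):
            t0, t1 = qs + diag, qe + diag
            if t0 >= n:  # duplicate of a hit inside the unpadded copy
                continue
            ev = _evalue(score, len(query), n, protein=False)
            if ev > min_evalue:
                continue
            if strand == "+":
                q0, q1 = qs, qe
            else:
                q0, q1 = len(query) - qe, len(query) - qs
            hsps.append(
                HSP(
                    query_gene=query_name,
                    q0=q0, q1=q1, t0=t0, t1=t1,
                    strand=strand, score=score,
                    identity=matches / (qe - qs), evalue=ev,
                    genome_length=n,
                )
            )
    hsps.sort(key=lambda h: (-h.score, h.t0, h.strand))
    return hsps


def _extend_blosum(q: str, t: str, qs: int, qe: int, diag: int) -> tuple[int, int, float, int]:
    def sc(a: str, b: str) -> float:
        try:
            return float(_BLOSUM62[a, b])
        except (KeyError, IndexError):
            return -4.0

    cur = best = sum(sc(q[i], t[i + diag]) for i in range(qs, qe))
    best_qe = qe
    i = qe
    while i < len(q) and i + diag < len(t):
        cur += sc(q[i], t[i + diag])
        i += 1
        if cur > best:
            best, best_qe = cur, i
        elif best - cur > XDROP:
            break
    cur, best_qs = best, qs
    i = qs - 1
    while i >= 0 and i + diag >= 0:
        cur += sc(q[i], t[i + diag])
        if cur > best:
            best, best_qs = cur, i
        elif best - cur > XDROP:
            break
        i -= 1
    matches = sum(1 for j in range(best_qs, best_qe) if q[j] == t[j + diag])
    return best_qs, best_qe, float(best), matches


def _translated_search(
    protein: str, target: Plastome, min_evalue: float, query_name: str
) -> list[HSP]:
    if len(protein) < 5:
        raise ValueError("protein query shorter than 5 aa")
    n = target.length
    padded = _pad(target)
    k = 4
    hsps: list[HSP] = []
    for strand, nt in (("+", padded), ("-", revcomp(padded))):
        for frame in range(3):
            if len(nt) - frame < 3:
                continue
            aa = translate_cds(nt[frame:]).protein
            index: dict[str, list[int]] = {}
            for i in range(len(aa) - k + 1):
                index.setdefault(aa[i : i + k], []).append(i)
            diag_seeds: dict[int, list[int]] = {}
            for i in range(len(protein) - k + 1):
                for t in index.get(protein[i : i + k], ()):
                    diag_seeds.setdefault(t - i, []).append(i)
            for diag, starts in diag_seeds.items():
                starts.sort()
                covered = -1
                seen: set[tuple[int, int]] = set()
                for qs in starts:
                    if qs < covered:
                        continue
                    bqs, bqe, score, matches = _extend_blosum(protein, aa, qs, qs + k, diag)
                    covered = bqe
                    if (bqs, bqe) in seen:
                        continue
                    seen.add((bqs, bqe))
                    ev = _evalue(score, len(protein), n, protein=True)
                    if ev > min_evalue:
                        continue
                    p0 = frame + 3 * (bqs + diag)
                    p1 = frame + 3 * (bqe + diag)
                    if strand == "+":
                        t0, t1 = p0, p1
                    else:
                        t0, t1 = len(padded) - p1, len(padded) - p0
                    if t0 >= n:
                        continue
                    hsps.append(
                        HSP(
                            query_gene=query_name,
                            q0=bqs, q1=bqe, t0=t0, t1=t1,
                            strand=strand, score=score,
                            identity=matches / (bqe - bqs), evalue=ev,
                            frame=frame, genome_length=n,
                        )
                    )
    hsps.sort(key=lambda h: (-h.score, h.t0, h.strand))
    return hsps


# ---------------------------------------------------------------------------
# HSP chaining
# ---------------------------------------------------------------------------


@dataclass
class ExonChain:
    query_gene: str
    strand: str
    hsps: list[HSP]

    @property
    def score(self) -> float:
        return sum(h.score for h in self.hsps)

    def t_extent(self) -> tuple[int, int]:
        return min(h.t0 for h in self.hsps), max(h.t1 for h in self.hsps)


def _colinear(a: HSP, b: HSP, max_intron: int) -> bool:
    """Can b follow a in one chain (same strand, colinear, gap <= max_intron)?"""
    if a.strand != b.strand:
        return False
    if not (b.q0 > a.q0 and b.q1 > a.q1):
        return False
    if a.q1 - b.q0 > 0.5 * min(a.q1 - a.q0, b.q1 - b.q0):
        return False
    if a.strand == "+":
        if not (b.t0 > a.t0 and b.t1 > a.t1):
            return False
        t_overlap, gap = a.t1 - b.t0, b.t0 - a.t1
    else:
        if not (b.t0 < a.t0 and b.t1 < a.t1):
            return False
        t_overlap, gap = b.t1 - a.t0, a.t0 - b.t1
    if t_overlap > 0.5 * min(a.t1 - a.t0, b.t1 - b.t0):
        return False
    return gap <= max_intron


def _best_chain(hsps: list[HSP], max_intron: int) -> list[HSP]:
    """Maximum-total-score colinear chain (O(n^2) dynamic programme)."""
    if not hsps:
        return []
    order = sorted(range(len(hsps)), key=lambda i: (hsps[i].q0, hsps[i].q1))
    best = [hsps[i].score for i in order]
    back: list[int | None] = [None] * len(order)
    for bi, i in enumerate(order):
        for ai in range(bi):
            a = hsps[order[ai]]
            if _colinear(a, hsps[i], max_intron) and best[ai] + hsps[i].score > best[bi]:
                best[bi] = best[ai] + hsps[i].score
                back[bi] = ai
    end = max(range(len(order)), key=lambda bi: best[bi])
    chain = []
    cur: int | None = end
    while cur is not None:
        chain.append(hsps[order[cur]])
        cur = back[cur]
    chain.reverse()
    return chain


def chain_hsps(
    hsps: list[HSP], max_intron: int = 2000, min_chain_score: float = 0.0
) -> list[ExonChain]:
    """Partition HSPs into per-locus maximum-score colinear chains.

    The best chain is extracted repeatedly; leftover HSPs overlapping an
    extracted chain's genomic footprint by > 50% are consumed with it, so
    IR twin loci come out as separate chains.
    """
    if not hsps:
        return []
    remaining = list(hsps)
    chains: list[ExonChain] = []
    while remaining:
        chain = _best_chain(remaining, max_intron)
        if not chain or sum(h.score for h in chain) < min_chain_score:
            break
        chains.append(
            ExonChain(query_gene=chain[0].query_gene, strand=chain[0].strand, hsps=chain)
        )
        lo = min(h.t0 for h in chain)
        hi = max(h.t1 for h in chain)
        in_chain = {id(h) for h in chain}
        kept = [
            h for h in remaining
            if id(h) not in in_chain
            and min(hi, h.t1) - max(lo, h.t0) <= 0.5 * (h.t1 - h.t0)
        ]
        if len(kept) == len(remaining):
            break
        remaining = kept
    return chains


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    name: str
    kind: str  # CDS | rRNA | tRNA
    exons: list[Exon]
    strand: str  # +, - or mixed (trans-spliced only)
    trans_spliced: bool = False
    partial_5p: bool = False
    partial_3p: bool = False
    provenance: str = "core"
    notes: list[str] = field(default_factory=list)
    score: float = 0.0
    copy: int = 1  # IR twin copies get distinct numbers
    transcript_id: str = ""
    shared_exon_ref: int | None = None  # ordinal of the shared trans-spliced exon

    @property
    def uid(self) -> str:
        base = self.transcript_id or self.name
        return base if self.copy == 1 else f"{base}-{self.copy}"

    def spliced_seq(self, genome: Plastome) -> str:
        return "".join(genome.fetch(e.interval) for e in self.exons)

    def total_exon_len(self, genome_length: int) -> int:
        return sum(e.interval.span(genome_length) for e in self.exons)

    def t_extent(self) -> tuple[int, int]:
        return (
            min(e.interval.start for e in self.exons),
            max(e.interval.end for e in self.exons),
        )

    def key(self) -> tuple:
        """Structural identity used for round-trip / equality checks."""
        return (
            normalize_gene_name(self.name),
            self.kind,
            tuple(
                (e.interval.start, e.interval.end, e.interval.strand,
                 e.interval.wraps_origin)
                for e in self.exons
            ),
            self.trans_spliced,
            self.partial_5p,
            self.partial_3p,
        )


@dataclass
class AnnotationSet:
    genome_id: str
    models: list[GeneModel] = field(default_factory=list)
    layout: object | None = None
    warnings: list = field(default_factory=list)

    def by_name(self, name: str) -> list[GeneModel]:
        norm = normalize_gene_name(name)
        return [m for m in self.models if normalize_gene_name(m.name) == norm]

    def keys(self) -> set:
        return {m.key() for m in self.models}


def make_exons(segments: list[tuple[int, int]], n: int, strand: str, cds: bool) -> list[Exon]:
    """Transcription-ordered exons from padded 0-based half-open segments."""
    exons = []
    cum = 0
    for idx, (s0, e0) in enumerate(segments, start=1):
        iv = _padded_to_interval(s0, e0, n, strand)
        phase = (3 - cum % 3) % 3 if cds else 0
        exons.append(Exon(interval=iv, phase=phase, ordinal=idx))
        cum += e0 - s0
    return exons


def refine_gene_model(
    chain: ExonChain,
    genome: Plastome,
    ref: ReferenceGene,
    start_window: int = 90,
    boundary_window: int = 30,
    refine_start: bool = True,
    frame_offset: int = 0,
) -> GeneModel | None:
    """Turn a chained set of HSPs into a reference-phased gene model.

    Internal exon boundaries are snapped so exon lengths preserve the
    reference phase: each reference exon's query range is projected through
    the diagonal of the chain HSP that covers it best (adjustments beyond
    ``boundary_window`` bp from the raw footprint gain a note). The 5' end
    is moved to the nearest in-frame ATG within ``start_window`` bp and the
    3' end to the first in-frame stop; partial flags are set otherwise.
    A refined CDS containing internal stops is returned with a note.
    """
    if not chain.hsps:
        return None
    strand = chain.strand
    padded = _pad(genome)
    np_len = len(padded)
    notes: list[str] = []

    if strand == "-":
        work = revcomp(padded)
        hsps_w = [(h.q0, h.q1, np_len - h.t1, np_len - h.t0) for h in chain.hsps]
    else:
        work = padded
        hsps_w = [(h.q0, h.q1, h.t0, h.t1) for h in chain.hsps]

    # reference exon query ranges (0-based half-open on the spliced sequence)
    ranges = []
    cum = 0
    for ex in ref.exons:
        ranges.append((cum, cum + len(ex.seq)))
        cum += len(ex.seq)

    segments: list[tuple[int, int]] = []
    missing: list[int] = []
    for ordinal, (rs, re_) in enumerate(ranges, start=1):
        best_h, best_ov = None, 0
        for (q0, q1, t0, t1) in hsps_w:
            ov = min(q1, re_) - max(q0, rs)
            if ov > best_ov:
                best_ov, best_h = ov, (q0, q1, t0, t1)
        if best_h is None or best_ov < 0.6 * (re_ - rs):
            missing.append(ordinal)
            continue
        q0, q1, t0, t1 = best_h
        diag = t0 - q0
        s0, e0 = rs + diag, re_ + diag
        if s0 < 0 or e0 > len(work):
            # clamp projections that run off a (linear) sequence end
            s0, e0 = max(s0, 0), min(e0, len(work))
            if e0 - s0 < 1:
                missing.append(ordinal)
                continue
            notes.append(f"exon {ordinal} truncated at a sequence end")
        if rs < q0 - boundary_window or re_ > q1 + boundary_window:
            notes.append(f"exon {ordinal} boundary adjusted > {boundary_window} bp "
                         "beyond the alignment footprint")
        segments.append((s0, e0))
    if not segments:
        return None
    if missing:
        notes.append(f"reference exons not located: {missing}")

    partial_5p = partial_3p = False
    if ref.kind == "CDS":
        if refine_start and 1 not in missing:
            s0, e0 = segments[0]
            if work[s0 : s0 + 3] != "ATG":
                found = None
                for off in sorted(range(-start_window, start_window + 1, 3),
                                  key=lambda o: (abs(o), o)):
                    c0 = s0 + off
                    if 0 <= c0 and c0 + 3 <= min(e0, len(work)) + start_window \
                            and c0 < e0 and work[c0 : c0 + 3] == "ATG":
                        found = c0
                        break
                if found is not None:
                    segments[0] = (found, e0)
                else:
                    partial_5p = True
        if len(ref.exons) not in missing:
            last_s0, last_e0 = segments[-1]
            pre = frame_offset + sum(b - a for a, b in segments[:-1])
            cds_len = pre + (last_e0 - last_s0)
            if cds_len % 3 != 0 or work[last_e0 - 3 : last_e0] not in STOP_CODONS:
                # first in-frame codon start at or after the mapped end
                first = last_s0 + ((3 - pre % 3) % 3)
                q = first + 3 * max(0, (last_e0 - 3 - first) // 3)
                found = None
                while q + 3 <= len(work) and q <= last_e0 + start_window:
                    if q >= first and work[q : q + 3] in STOP_CODONS:
                        found = q + 3
                        break
                    q += 3
                if found is not None and found > last_s0:
                    segments[-1] = (last_s0, found)
                else:
                    partial_3p = True
        cds = "".join(work[a:b] for a, b in segments)
        if (frame_offset + len(cds)) % 3 != 0 and not (partial_5p or partial_3p or missing):
            notes.append("CDS length not divisible by 3")
        in_frame = cds[(3 - frame_offset) % 3 :]
        if len(in_frame) >= 3 and translate_cds(in_frame).internal_stop:
            notes.append("internal stop codon in refined CDS")

    n = genome.length
    if strand == "-":
        segments = [(np_len - e0, np_len - s0) for s0, e0 in segments]
    exons = make_exons(segments, n, strand, cds=ref.kind == "CDS")
    return GeneModel(
        name=normalize_gene_name(ref.name),
        kind=ref.kind,
        exons=exons,
        strand=strand,
        partial_5p=partial_5p,
        partial_3p=partial_3p,
        provenance="core",
        notes=notes,
        score=chain.score,
    )


# ---------------------------------------------------------------------------
# Whole-genome annotation
# ---------------------------------------------------------------------------

MICRO_EXON_GENES = ("petB", "petD", "rpl16")


def _suppress_duplicates(models: list[GeneModel]) -> list[GeneModel]:
    """Same-gene models overlapping >= 50% keep only the best (IR twins kept)."""
    kept: list[GeneModel] = []
    for m in sorted(models, key=lambda x: -x.score):
        lo, hi = m.t_extent()
        dup = False
        for other in kept:
            if normalize_gene_name(other.name) != normalize_gene_name(m.name):
                continue
            olo, ohi = other.t_extent()
            ov = min(hi, ohi) - max(lo, olo) + 1
            if ov >= 0.5 * min(hi - lo + 1, ohi - olo + 1):
                dup = True
                break
        if not dup:
            kept.append(m)
    return kept


def _assign_copies(models: list[GeneModel]) -> None:
    by_name: dict[str, list[GeneModel]] = {}
    for m in models:
        by_name.setdefault(m.transcript_id or m.name, []).append(m)
    for same in by_name.values():
        if len(same) > 1:
            for idx, m in enumerate(sorted(same, key=lambda x: x.t_extent()[0]), start=1):
                m.copy = idx


def annotate_genome(
    genome: Plastome,
    db: ReferenceDB,
    min_evalue: float = 1e-6,
    max_intron: int = 2000,
    isecus_evalue: float = 1e-20,
) -> AnnotationSet:
    """Full similarity-based annotation of a plastome against a reference DB.

    CDS and rRNA genes are located by nucleotide search of the reference
    spliced gene sequence, chained into exon models and refined against the
    reference exon structure. The micro-exon genes then go through the
    anchored small-exon finder, and rps12 through the trans-splicing
    assembler; their results override the core models for those genes.
    """
    from plastann import isecus as isecus_mod
    from plastann import itgie as itgie_mod
    from plastann._warnings import Warning as Warn
    from plastann.genome_model import detect_inverted_repeats
    from plastann.reference_db import build_anchor_table

    layout = detect_inverted_repeats(genome)
    warnings: list = []
    models: list[GeneModel] = []
    anchor_table = build_anchor_table(db)

    for kind in ("CDS", "rRNA"):
        for name in db.gene_names(kind):
            norm = normalize_gene_name(name)
            if norm == "rps12" and kind == "CDS":
                continue  # handled by the trans-splicing assembler below
            micro = kind == "CDS" and norm in MICRO_EXON_GENES
            candidates: list[GeneModel] = []
            for ref in (g for g in db.by_name(name) if g.kind == kind):
                if micro and len(ref.exons) > 1:
                    # the micro first exon is deferred to the anchored finder
                    ref_for_core = dc_replace_ref(ref, ref.exons[1:])
                    query = ref_for_core.cds_seq
                else:
                    ref_for_core = ref
                    query = ref.cds_seq
                if len(query) < 8:
                    continue
                hsps = similarity_search(
                    query, genome, "nucleotide", min_evalue, query_name=norm
                )
                offset = (
                    len(ref.exons[0].seq) % 3
                    if micro and len(ref.exons) > 1 else 0
                )
                for chain in chain_hsps(hsps, max_intron):
                    model = refine_gene_model(
                        chain, genome, ref_for_core,
                        refine_start=not micro,
                        frame_offset=offset,
                    )
                    if model is not None:
                        candidates.append(model)
            gene_models = _suppress_duplicates(candidates)
            if micro:
                gene_models = [
                    isecus_mod.attach_micro_exon(
                        m, genome, anchor_table,
                        evalue_cutoff=isecus_evalue, max_intron=max_intron,
                        warnings=warnings,
                    )
                    for m in gene_models
                ]
            models.extend(m for m in gene_models if m is not None)
            if not gene_models:
                warnings.append(Warn(
                    category="annotation", subject=name, severity="info",
                    message=f"gene {name} not found in genome",
                ))

    if db.by_name("rps12"):
        models.extend(
            itgie_mod.assemble_rps12(
                genome, db, layout, max_intron=max_intron,
                evalue_cutoff=isecus_evalue, warnings=warnings,
            )
        )

    _assign_copies(models)
    ann = AnnotationSet(genome_id=genome.id, models=models, layout=layout,
                        warnings=warnings)
    if not models:
        warnings.append(Warn(
            category="annotation", subject=genome.id, severity="warn",
            message="no genes found at all",
        ))
    return ann


def dc_replace_ref(ref: ReferenceGene, exons) -> ReferenceGene:
    """Reference entry restricted to a subset of its exons (renumbered)."""
    new_exons = [dc_replace(e, ordinal=i) for i, e in enumerate(exons, start=1)]
    return ReferenceGene(
        name=ref.name, kind=ref.kind, exons=new_exons,
        source_accession=ref.source_accession, product=ref.product,
        trans_spliced=ref.trans_spliced,
    )
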