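"""Output writers: GFF3, GenBank flat file, NCBI 5-column feature table
(+FASTA) and an SVG circular map — plus the matching parsers used for
lossless round-trip checks.

Coordinate conversion happens here and only here: models are 1-based
inclusive internally, GFF3 and the feature table stay 1-based, Biopython
locations are 0-based half-open. Origin-wrapping features are split into
two location segments sharing one ID.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    CompoundLocation,
    ExactPosition,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from plastann.annotate_core import AnnotationSet, GeneModel
from plastann.genome_model import Exon, Interval, Plastome, translate_cds
from plastann.repeats import SSR, DispersedRepeat, TandemRepeat

logger = logging.getLogger(__name__)

_FEATURE_TYPE = {"CDS": "mRNA", "tRNA": "tRNA", "rRNA": "rRNA"}


def _exon_segments(iv: Interval, n: int) -> list[tuple[int, int, str]]:
    """(start, end, strand) 1-based inclusive segments in genomic 5'->3'
    order along the plus strand; wrapping intervals split in two."""
    if not iv.wraps_origin:
        return [(iv.start, iv.end, iv.strand)]
    return [(iv.start, n, iv.strand), (1, iv.end, iv.strand)]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(annotation: AnnotationSet, genome: Plastome) -> str:
    """GFF3 document with a gene/(mRNA|tRNA|rRNA)/exon/CDS hierarchy.

    Trans-spliced genes come out as one gene with several mRNA children
    sharing the common exon feature through multiple Parent values.
    """
    n = genome.length
    lines = [
        "##gff-version 3",
        f"##sequence-region {genome.id} 1 {n}",
    ]

    # group trans-spliced transcripts of one gene under one gene feature
    groups: dict[str, list[GeneModel]] = {}
    order: list[str] = []
    for m in annotation.models:
        gid = f"{m.name}-{m.copy}" if not m.trans_spliced else m.name
        if gid not in groups:
            order.append(gid)
        groups.setdefault(gid, []).append(m)

    def attrs(**kv) -> str:
        return ";".join(f"{k}={v}" for k, v in kv.items() if v not in (None, ""))

    for gid in order:
        models = groups[gid]
        first = models[0]
        gene_id = f"gene-{gid}"
        span_lo = min(m.t_extent()[0] for m in models)
        span_hi = max(m.t_extent()[1] for m in models)
        strands = {e.interval.strand for m in models for e in m.exons}
        gstrand = strands.pop() if len(strands) == 1 else "."
        extra = {}
        if first.trans_spliced:
            extra["trans_splicing"] = "true"
        lines.append("\t".join([
            genome.id, "plastann", "gene", str(span_lo), str(span_hi), ".",
            gstrand, ".",
            attrs(ID=gene_id, Name=first.name, **extra),
        ]))

        # mRNA (or tRNA/rRNA) rows first, then exon/CDS rows; an exon used
        # by several transcripts of a trans-spliced gene is written once
        # with every transcript in its Parent list.
        exon_entries: dict[tuple, dict] = {}
        exon_order: list[tuple] = []
        for m in models:
            mid = f"{_FEATURE_TYPE[m.kind]}-{m.uid}"
            lo, hi = m.t_extent()
            partial = ",".join(
                p for p, f in (("5p", m.partial_5p), ("3p", m.partial_3p)) if f
            )
            mstrands = {e.interval.strand for e in m.exons}
            mstrand = mstrands.pop() if len(mstrands) == 1 else "."
            lines.append("\t".join([
                genome.id, "plastann", _FEATURE_TYPE[m.kind],
                str(lo), str(hi), ".", mstrand, ".",
                attrs(ID=mid, Parent=gene_id, Name=m.name,
                      partial=partial or None,
                      provenance=m.provenance or None),
            ]))
            for exon in m.exons:
                iv = exon.interval
                ekey = (iv.start, iv.end, iv.strand, iv.wraps_origin)
                if not first.trans_spliced:
                    ekey = ekey + (mid,)
                entry = exon_entries.get(ekey)
                if entry is None:
                    entry = {
                        "iv": iv,
                        "id": f"exon-{m.uid}.{exon.ordinal}",
                        "parents": [],
                        "rank": exon.ordinal,
                        "phase": exon.phase,
                        "cds": m.kind == "CDS",
                    }
                    exon_entries[ekey] = entry
                    exon_order.append(ekey)
                entry["parents"].append(mid)
        for ekey in exon_order:
            entry = exon_entries[ekey]
            iv = entry["iv"]
            parent = ",".join(entry["parents"])
            for (s, e, strand) in _exon_segments(iv, n):
                lines.append("\t".join([
                    genome.id, "plastann", "exon", str(s), str(e), ".",
                    strand, ".",
                    attrs(ID=entry["id"], Parent=parent, rank=str(entry["rank"])),
                ]))
            if entry["cds"]:
                phase = entry["phase"]
                segs = _exon_segments(iv, n)
                if iv.strand == "-":
                    segs = list(reversed(segs))  # transcription order for phase
                for (s, e, strand) in segs:
                    lines.append("\t".join([
                        genome.id, "plastann", "CDS", str(s), str(e), ".",
                        strand, str(phase),
                        attrs(ID=f"cds-{entry['id']}", Parent=parent,
                              rank=str(entry["rank"])),
                    ]))
                    phase = (3 - ((e - s + 1) - phase) % 3) % 3
    return "\n".join(lines) + "\n"


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(text: str, genome_length: int | None = None) -> AnnotationSet:
    """Parse a GFF3 document produced by :func:`write_gff3`."""
    genome_id = ""
    mrnas: dict[str, dict] = {}
    gene_flags: dict[str, dict] = {}
    order: list[str] = []
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            genome_id = parts[1]
            genome_length = int(parts[3])
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            continue
        seqid, _src, ftype, start, end, _score, strand, phase, attr_s = cols
        attrs = _parse_attrs(attr_s)
        if ftype == "gene":
            gene_flags[attrs["ID"]] = {
                "trans": attrs.get("trans_splicing") == "true",
                "name": attrs.get("Name", ""),
            }
        elif ftype in ("mRNA", "tRNA", "rRNA"):
            mid = attrs["ID"]
            order.append(mid)
            kind = {"mRNA": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}[ftype]
            partial = attrs.get("partial", "")
            mrnas[mid] = {
                "name": attrs.get("Name", mid),
                "kind": kind,
                "gene": attrs.get("Parent", ""),
                "partial_5p": "5p" in partial,
                "partial_3p": "3p" in partial,
                "provenance": attrs.get("provenance", "core"),
                "exons": {},  # exon_id -> {rank, segments}
            }
        elif ftype == "exon":
            for parent in attrs["Parent"].split(","):
                if parent in mrnas:
                    ex = mrnas[parent]["exons"].setdefault(
                        attrs["ID"], {"rank": int(attrs.get("rank", 1)), "segs": []}
                    )
                    ex["segs"].append((int(start), int(end), strand))

    models = []
    for mid in order:
        info = mrnas[mid]
        exons = []
        for eid, ex in sorted(info["exons"].items(), key=lambda kv: kv[1]["rank"]):
            segs = ex["segs"]
            if len(segs) == 1:
                s, e, strand = segs[0]
                iv = Interval(start=s, end=e, strand=strand)
            else:
                segs_sorted = sorted(segs)
                (s1, e1, strand), (s2, e2, _) = segs_sorted
                # wrapped feature split at the origin: [s2..n] + [1..e1]
                iv = Interval(start=s2, end=e1, strand=strand, wraps_origin=True)
            exons.append(Exon(interval=iv, phase=0, ordinal=ex["rank"]))
        cum = 0
        rebuilt = []
        for exon in exons:
            phase = (3 - cum % 3) % 3 if info["kind"] == "CDS" else 0
            rebuilt.append(Exon(interval=exon.interval, phase=phase,
                                ordinal=exon.ordinal))
            cum += (exon.interval.span(genome_length)
                    if genome_length else exon.interval.end - exon.interval.start + 1)
        strands = {e.interval.strand for e in rebuilt}
        gene = gene_flags.get(info["gene"], {})
        models.append(GeneModel(
            name=info["name"],
            kind=info["kind"],
            exons=rebuilt,
            strand=strands.pop() if len(strands) == 1 else "mixed",
            trans_spliced=bool(gene.get("trans")),
            partial_5p=info["partial_5p"],
            partial_3p=info["partial_3p"],
            provenance=info["provenance"],
            transcript_id=mid.split("-", 1)[1] if "-" in mid else "",
        ))
    return AnnotationSet(genome_id=genome_id, models=models)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def _model_location(m: GeneModel, n: int):
    # parts listed in transcription order (minus-strand parts high-to-low)
    parts = []
    for exon in m.exons:
        segs = _exon_segments(exon.interval, n)
        if exon.interval.strand == "-":
            segs = list(reversed(segs))
        strand = 1 if exon.interval.strand == "+" else -1
        for s, e, _ in segs:
            parts.append(SimpleLocation(ExactPosition(s - 1), ExactPosition(e), strand))
    # partial ends
    if m.partial_5p:
        first = parts[0]
        if first.strand == 1:
            parts[0] = SimpleLocation(BeforePosition(int(first.start)), first.end, 1)
        else:
            parts[0] = SimpleLocation(first.start, AfterPosition(int(first.end)), -1)
    if m.partial_3p:
        last = parts[-1]
        if last.strand == 1:
            parts[-1] = SimpleLocation(last.start, AfterPosition(int(last.end)), 1)
        else:
            parts[-1] = SimpleLocation(BeforePosition(int(last.start)), last.end, -1)
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def to_seqrecord(annotation: AnnotationSet, genome: Plastome) -> SeqRecord:
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="plastome annotation",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "data_file_division": "PLN",
        },
    )
    n = genome.length
    for m in annotation.models:
        loc = _model_location(m, n)
        quals = {"gene": [m.name]}
        gene_feat = SeqFeature(loc, type="gene", qualifiers=dict(quals))
        if m.trans_spliced:
            gene_feat.qualifiers["exception"] = ["trans-splicing"]
        rec.features.append(gene_feat)
        quals2 = dict(quals)
        if m.kind == "CDS":
            quals2["codon_start"] = ["1"]
            quals2["transl_table"] = ["11"]
            if m.trans_spliced:
                quals2["exception"] = ["trans-splicing"]
            cds = m.spliced_seq(genome)
            if (not m.partial_5p and not m.partial_3p and len(cds) % 3 == 0
                    and len(cds) >= 6):
                tr = translate_cds(cds)
                if not tr.internal_stop:
                    quals2["translation"] = [tr.protein]
        feat = SeqFeature(loc, type=m.kind, qualifiers=quals2)
        rec.features.append(feat)
    return rec


def write_genbank(annotation: AnnotationSet, genome: Plastome, path: str) -> None:
    """GenBank flat file with join()/complement() locations and
    exception="trans-splicing" on trans-spliced models."""
    rec = to_seqrecord(annotation, genome)
    SeqIO.write([rec], path, "genbank")


def read_genbank_annotation(path: str) -> tuple[AnnotationSet, Plastome]:
    """Parse a GenBank flat file back into an annotation set (round-trip)."""
    rec = next(SeqIO.parse(path, "genbank"))
    genome = Plastome(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        circular=(rec.annotations or {}).get("topology") == "circular",
    )
    n = genome.length
    models = []
    for feature in rec.features:
        if feature.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = feature.qualifiers.get("gene", ["?"])[0]
        parts = list(feature.location.parts)
        raw: list[tuple[int, int, str, bool, bool]] = []
        for part in parts:
            strand = "-" if part.strand == -1 else "+"
            fuzzy_start = isinstance(part.start, BeforePosition)
            fuzzy_end = isinstance(part.end, AfterPosition)
            raw.append((int(part.start) + 1, int(part.end), strand,
                        fuzzy_start, fuzzy_end))
        # merge origin-split segments: [x..n] followed by [1..y] on + strand
        merged: list[tuple[Interval, bool, bool]] = []
        i = 0
        while i < len(raw):
            s, e, strand, f5, f3 = raw[i]
            if (i + 1 < len(raw) and strand == raw[i + 1][2]):
                s2, e2, _, g5, g3 = raw[i + 1]
                if strand == "+" and e == n and s2 == 1:
                    merged.append((Interval(start=s, end=e2, strand=strand,
                                            wraps_origin=True), f5 or g5, f3 or g3))
                    i += 2
                    continue
                if strand == "-" and s == 1 and e2 == n:
                    merged.append((Interval(start=s2, end=e, strand=strand,
                                            wraps_origin=True), f5 or g5, f3 or g3))
                    i += 2
                    continue
            merged.append((Interval(start=s, end=e, strand=strand), f5, f3))
            i += 1
        exons = []
        cum = 0
        for ordinal, (iv, _, _) in enumerate(merged, start=1):
            phase = (3 - cum % 3) % 3 if feature.type == "CDS" else 0
            exons.append(Exon(interval=iv, phase=phase, ordinal=ordinal))
            cum += iv.span(n)
        strands = {iv.strand for iv, _, _ in merged}
        trans = "trans-splicing" in feature.qualifiers.get("exception", [])
        strand = strands.pop() if len(strands) == 1 else "mixed"
        # fuzziness on the first/last transcription-order part, read relative
        # to that part's own strand
        first_iv, first_f5, first_f3 = merged[0]
        last_iv, last_f5, last_f3 = merged[-1]
        partial_5p = first_f5 if first_iv.strand == "+" else first_f3
        partial_3p = last_f3 if last_iv.strand == "+" else last_f5
        models.append(GeneModel(
            name=name,
            kind=feature.type,
            exons=exons,
            strand=strand,
            trans_spliced=trans,
            partial_5p=partial_5p,
            partial_3p=partial_3p,
        ))
    return AnnotationSet(genome_id=genome.id, models=models), genome


# ---------------------------------------------------------------------------
# NCBI 5-column feature table (+ FASTA) for submission
# ---------------------------------------------------------------------------


def write_feature_table(
    annotation: AnnotationSet, genome: Plastome
) -> tuple[str, str]:
    """(.tbl, .fsa) contents in the NCBI 5-column feature-table dialect."""
    n = genome.length
    lines = [f">Feature {genome.id}"]
    for m in annotation.models:
        segs: list[tuple[int, int]] = []
        for exon in m.exons:
            parts = _exon_segments(exon.interval, n)
            if exon.interval.strand == "-":
                parts = list(reversed(parts))
            for s, e, strand in parts:
                segs.append((s, e) if strand == "+" else (e, s))
        g_first, g_last = segs[0], segs[-1]
        lines.append(f"{g_first[0]}\t{g_last[1]}\tgene")
        lines.append(f"\t\t\tgene\t{m.name}")
        if m.trans_spliced:
            lines.append("\t\t\texception\ttrans-splicing")
        ftype = m.kind
        for idx, (a, b) in enumerate(segs):
            a_s, b_s = str(a), str(b)
            if idx == 0 and m.partial_5p:
                a_s = f"<{a_s}"
            if idx == len(segs) - 1 and m.partial_3p:
                b_s = f">{b_s}"
            if idx == 0:
                lines.append(f"{a_s}\t{b_s}\t{ftype}")
            else:
                lines.append(f"{a_s}\t{b_s}")
        lines.append(f"\t\t\tgene\t{m.name}")
        if m.kind == "CDS":
            lines.append("\t\t\ttransl_table\t11")
        if m.trans_spliced:
            lines.append("\t\t\texception\ttrans-splicing")
    tbl = "\n".join(lines) + "\n"
    fsa_lines = [f">{genome.id}"]
    for i in range(0, n, 70):
        fsa_lines.append(genome.sequence[i : i + 70])
    return tbl, "\n".join(fsa_lines) + "\n"


# ---------------------------------------------------------------------------
# SVG circular map
# ---------------------------------------------------------------------------

GENE_CATEGORY_COLORS = [
    ("psa", "photosystem I", "#2e5e1f"),
    ("psb", "photosystem II", "#4c8c2b"),
    ("pet", "cytochrome b/f complex", "#7a5230"),
    ("atp", "ATP synthase", "#9b3d20"),
    ("ndh", "NADH dehydrogenase", "#d4a017"),
    ("rbc", "RubisCO", "#317873"),
    ("rpo", "RNA polymerase", "#8e3e63"),
    ("rps", "ribosomal protein (small)", "#c46210"),
    ("rpl", "ribosomal protein (large)", "#e2851f"),
    ("rrn", "ribosomal RNA", "#b22222"),
    ("trn", "transfer RNA", "#1f6fb2"),
    ("ycf", "hypothetical ORF", "#777777"),
]
DEFAULT_GENE_COLOR = "#444444"

_CX = _CY = 400.0
_RINGS = {"dispersed": 120.0, "tandem": 180.0, "ssr": 220.0, "genes": 280.0}


def _gene_color(name: str) -> str:
    low = name.lower()
    for prefix, _label, color in GENE_CATEGORY_COLORS:
        if low.startswith(prefix):
            return color
    return DEFAULT_GENE_COLOR


def _xy(radius: float, pos: float, n: int) -> tuple[float, float]:
    angle = 2 * math.pi * (pos / n) - math.pi / 2
    return (_CX + radius * math.cos(angle), _CY + radius * math.sin(angle))


def _arc_path(radius: float, p1: float, p2: float, n: int, width: float) -> str:
    x1, y1 = _xy(radius, p1, n)
    x2, y2 = _xy(radius, p2, n)
    frac = ((p2 - p1) % n) / n
    large = 1 if frac > 0.5 else 0
    return (f"M {x1:.2f} {y1:.2f} A {radius:.1f} {radius:.1f} 0 {large} 1 "
            f"{x2:.2f} {y2:.2f}")


def render_map(
    annotation: AnnotationSet,
    ssrs: list[SSR],
    tandems: list[TandemRepeat],
    dispersed: list[DispersedRepeat],
    genome: Plastome,
) -> str:
    """Deterministic SVG circular map with four rings: dispersed-repeat
    arcs (forward red, palindromic green), tandem-repeat bars, SSR ticks
    and gene boxes colored by functional category."""
    n = genome.length
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<svg xmlns="http://www.w3.org/2000/svg" width="800" height="800" '
        'viewBox="0 0 800 800">',
        f'<title>{genome.id}</title>',
        '<rect width="800" height="800" fill="white"/>',
    ]
    for ring_name, radius in sorted(_RINGS.items()):
        parts.append(
            f'<circle cx="{_CX}" cy="{_CY}" r="{radius}" fill="none" '
            f'stroke="#dddddd" stroke-width="1" class="ring-{ring_name}"/>'
        )
    for rep in dispersed:
        color = "#cc2222" if rep.orientation == "forward" else "#22aa44"
        mid_a = (rep.interval_a.start + rep.interval_a.end) / 2
        mid_b = (rep.interval_b.start + rep.interval_b.end) / 2
        x1, y1 = _xy(_RINGS["dispersed"], mid_a, n)
        x2, y2 = _xy(_RINGS["dispersed"], mid_b, n)
        parts.append(
            f'<path class="dispersed {rep.orientation}" d="M {x1:.2f} {y1:.2f} '
            f'Q {_CX} {_CY} {x2:.2f} {y2:.2f}" fill="none" stroke="{color}" '
            'stroke-width="1.5"/>'
        )
    for rep in tandems:
        d = _arc_path(_RINGS["tandem"], rep.interval.start, rep.interval.end, n, 8)
        parts.append(
            f'<path class="tandem" d="{d}" fill="none" stroke="#884499" '
            'stroke-width="8"/>'
        )
    for ssr in ssrs:
        mid = (ssr.interval.start + ssr.interval.end) / 2
        x1, y1 = _xy(_RINGS["ssr"] - 6, mid, n)
        x2, y2 = _xy(_RINGS["ssr"] + 6, mid, n)
        parts.append(
            f'<line class="ssr" x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" '
            f'y2="{y2:.2f}" stroke="#333333" stroke-width="1.5"/>'
        )
    for m in sorted(annotation.models, key=lambda m: (m.t_extent(), m.uid)):
        color = _gene_color(m.name)
        for exon in m.exons:
            iv = exon.interval
            r = _RINGS["genes"] + (8 if iv.strand == "+" else -8)
            d = _arc_path(r, iv.start, iv.end if not iv.wraps_origin else iv.end + n, n, 10)
            parts.append(
                f'<path class="gene" data-gene="{m.name}" d="{d}" fill="none" '
                f'stroke="{color}" stroke-width="10"/>'
            )
    # legend
    y = 20.0
    for prefix, label, color in GENE_CATEGORY_COLORS:
        parts.append(
            f'<rect x="10" y="{y:.0f}" width="12" height="12" fill="{color}"/>'
        )
        parts.append(
            f'<text x="28" y="{y + 11:.0f}" font-size="11" '
            f'font-family="sans-serif">{label}</text>'
        )
        y += 16
    parts.append(
        f'<text x="{_CX}" y="{_CY}" text-anchor="middle" font-size="14" '
        f'font-family="sans-serif">{genome.id} ({n} bp)</text>'
    )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
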