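"""Reference GenBank parsing into a searchable gene / anchor database.

The user supplies one or more annotated plastomes in GenBank flat-file
format; every CDS / rRNA / tRNA feature becomes a :class:`ReferenceGene`
with resolved, transcription-ordered exons. Micro-exon anchor records
(50-bp UTR flanks) are derived from the reference genome sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from plastann.genome_model import Interval, revcomp, translate_cds, STOP_CODONS

logger = logging.getLogger(__name__)

#: genes whose first exon is a micro-exon found via a conserved 5' UTR anchor
FIVE_PRIME_ANCHOR_GENES = ("petB", "petD", "rpl16")
#: gene whose last exon is a micro-exon found via a conserved 3' UTR anchor
THREE_PRIME_ANCHOR_GENES = ("rps12",)

_SYNONYMS = {
    "rpl-16": "rpl16",
    "rps-12": "rps12",
    "pet-b": "petB",
    "pet-d": "petD",
}

_CANONICAL_CASE = {
    g.lower(): g
    for g in (
        "petB petD rpl16 rps12 matK rbcL psbA psbB psbD ndhA ndhB atpA atpB "
        "ycf1 ycf2 rpoB rpoC1 rpoC2 clpP rrn16 rrn23 rrn4.5 rrn5"
    ).split()
}


def normalize_gene_name(name: str) -> str:
    """Case-insensitive gene-symbol normalization with a small synonym map.

    tRNA names are canonicalized to ``trnX-NNN`` with an uppercase
    anticodon written in the RNA alphabet (U, not T).
    """
    key = name.strip()
    low = key.lower()
    low = _SYNONYMS.get(low, low)
    if low.startswith("trn"):
        core = key.strip().replace("_", "-")
        parts = core.split("-", 1)
        aa = parts[0][3:].strip() or "X"
        anticodon = parts[1].upper().replace("T", "U") if len(parts) > 1 else ""
        return f"trn{aa.upper()}-{anticodon}" if anticodon else f"trn{aa.upper()}"
    return _CANONICAL_CASE.get(low, key)


@dataclass(frozen=True)
class RefExon:
    """One reference exon: sequence in coding orientation + source interval."""

    ordinal: int
    seq: str
    interval: Interval
    strand: str


@dataclass
class ReferenceGene:
    name: str
    kind: str  # CDS | rRNA | tRNA
    exons: list[RefExon]
    source_accession: str
    product: str = ""
    trans_spliced: bool = False
    internal_stop: bool = False

    @property
    def cds_seq(self) -> str:
        """Concatenated exon sequence in transcription order."""
        return "".join(e.seq for e in self.exons)

    @property
    def protein(self) -> str:
        if self.kind != "CDS" or len(self.cds_seq) < 3:
            return ""
        return translate_cds(self.cds_seq).protein


@dataclass(frozen=True)
class AnchorRecord:
    gene: str
    side: str  # five_prime | three_prime
    anchor_seq: str
    exon_seq: str
    source_accession: str
    valid: bool = True

    @property
    def exon_len(self) -> int:
        return len(self.exon_seq)

    @property
    def query_seq(self) -> str:
        """Scan query: anchor+exon (5') or exon+anchor (3')."""
        if self.side == "five_prime":
            return self.anchor_seq + self.exon_seq
        return self.exon_seq + self.anchor_seq


@dataclass
class ReferenceDB:
    genes: list[ReferenceGene] = field(default_factory=list)
    genomes: dict[str, str] = field(default_factory=dict)  # accession -> sequence
    circular: dict[str, bool] = field(default_factory=dict)

    def by_name(self, name: str) -> list[ReferenceGene]:
        norm = normalize_gene_name(name)
        return [g for g in self.genes if normalize_gene_name(g.name) == norm]

    def of_kind(self, kind: str) -> list[ReferenceGene]:
        return [g for g in self.genes if g.kind == kind]

    def gene_names(self, kind: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            if kind is None or g.kind == kind:
                seen.setdefault(normalize_gene_name(g.name), None)
        return list(seen)


def _feature_name(feature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return None


def _location_to_exons(feature, seq: str) -> tuple[list[RefExon], bool]:
    """Resolve a (possibly compound) location into transcription-ordered exons."""
    parts = feature.location.parts
    exons: list[RefExon] = []
    strands = set()
    for idx, part in enumerate(parts, start=1):
        start0, end0 = int(part.start), int(part.end)
        if end0 <= start0:
            continue
        strand = "-" if part.strand == -1 else "+"
        strands.add(strand)
        piece = seq[start0:end0]
        if strand == "-":
            piece = revcomp(piece)
        exons.append(
            RefExon(
                ordinal=idx,
                seq=piece,
                interval=Interval(start=start0 + 1, end=end0, strand=strand),
                strand=strand,
            )
        )
    mixed = len(strands) > 1
    return exons, mixed


def load_reference(paths: list[str]) -> ReferenceDB:
    """Parse reference GenBank files into a :class:`ReferenceDB`.

    Every CDS/rRNA/tRNA feature becomes one gene entry; join()/complement()
    locations are resolved to ordered exons; zero-length locations are
    skipped with a warning; an unparseable file is a hard error naming it.
    """
    db = ReferenceDB()
    for path in paths:
        try:
            records = list(SeqIO.parse(path, "genbank"))
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise ValueError(f"cannot parse reference GenBank file {path}: {exc}") from exc
        if not records:
            raise ValueError(f"no GenBank records in {path}")
        for rec in records:
            seq = str(rec.seq).upper()
            acc = rec.id or rec.name
            db.genomes[acc] = seq
            topology = (rec.annotations or {}).get("topology", "linear")
            db.circular[acc] = topology == "circular"
            n_features = 0
            for feature in rec.features:
                if feature.type not in ("CDS", "rRNA", "tRNA"):
                    continue
                name = _feature_name(feature)
                if name is None:
                    logger.warning("unnamed %s feature in %s skipped", feature.type, acc)
                    continue
                exons, mixed = _location_to_exons(feature, seq)
                if not exons:
                    logger.warning("zero-length location for %s in %s skipped", name, acc)
                    continue
                trans = mixed or "trans-splicing" in feature.qualifiers.get("exception", [])
                gene = ReferenceGene(
                    name=name,
                    kind=feature.type,
                    exons=exons,
                    source_accession=acc,
                    product=feature.qualifiers.get("product", [""])[0],
                    trans_spliced=trans,
                )
                if gene.kind == "CDS" and len(gene.cds_seq) >= 3:
                    tr = translate_cds(gene.cds_seq)
                    if tr.internal_stop:
                        gene.internal_stop = True
                        logger.warning(
                            "reference CDS %s (%s) has internal stop codons", name, acc
                        )
                db.genes.append(gene)
                n_features += 1
            if n_features == 0:
                raise ValueError(f"reference record {acc} in {path} has no usable features")
    return db


def _flank(seq: str, circular: bool, start0: int, end0: int) -> str | None:
    """seq[start0:end0) with circular wrap; None when out of range on a linear ref."""
    n = len(seq)
    if 0 <= start0 and end0 <= n:
        return seq[start0:end0]
    if not circular:
        return None
    return "".join(seq[i % n] for i in range(start0, end0))


def build_anchor_table(db: ReferenceDB, anchor_len: int = 50) -> list[AnchorRecord]:
    """Extract UTR anchor records for the micro-exon genes.

    5' side (petB/petD/rpl16): anchor = ``anchor_len`` bp immediately
    upstream of the exon-1 start codon on the coding strand; exon_seq is
    exon 1. 3' side (rps12): anchor = ``anchor_len`` bp immediately
    downstream of the stop codon; exon_seq is the last exon. Records are
    deduplicated on (gene, side, anchor_seq, exon_seq).
    """
    records: list[AnchorRecord] = []
    seen: set[tuple] = set()

    def emit(gene: str, side: str, anchor: str | None, exon_seq: str, acc: str, valid: bool):
        if anchor is None or len(anchor) != anchor_len:
            logger.warning("anchor for %s (%s) unavailable; dropped", gene, acc)
            return
        key = (gene, side, anchor, exon_seq)
        if key in seen:
            return
        seen.add(key)
        if not valid:
            logger.warning("anchored exon for %s (%s) lacks expected codon", gene, acc)
        records.append(
            AnchorRecord(
                gene=gene, side=side, anchor_seq=anchor, exon_seq=exon_seq,
                source_accession=acc, valid=valid,
            )
        )

    for gene_name in FIVE_PRIME_ANCHOR_GENES:
        for g in db.by_name(gene_name):
            if g.kind != "CDS":
                continue
            seq = db.genomes[g.source_accession]
            circ = db.circular.get(g.source_accession, True)
            ex = g.exons[0]
            if ex.strand == "+":
                anchor = _flank(seq, circ, ex.interval.start - 1 - anchor_len, ex.interval.start - 1)
            else:
                raw = _flank(seq, circ, ex.interval.end, ex.interval.end + anchor_len)
                anchor = revcomp(raw) if raw is not None else None
            emit(
                normalize_gene_name(g.name), "five_prime", anchor, ex.seq,
                g.source_accession, ex.seq.startswith("ATG"),
            )

    for gene_name in THREE_PRIME_ANCHOR_GENES:
        for g in db.by_name(gene_name):
            if g.kind != "CDS":
                continue
            seq = db.genomes[g.source_accession]
            circ = db.circular.get(g.source_accession, True)
            ex = g.exons[-1]
            if ex.strand == "+":
                anchor = _flank(seq, circ, ex.interval.end, ex.interval.end + anchor_len)
            else:
                raw = _flank(seq, circ, ex.interval.start - 1 - anchor_len, ex.interval.start - 1)
                anchor = revcomp(raw) if raw is not None else None
            emit(
                normalize_gene_name(g.name), "three_prime", anchor, ex.seq,
                g.source_accession, ex.seq[-3:] in STOP_CODONS,
            )

    return records
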