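"""Reconciliation of tRNA predictions from two external scanners.

The predictors themselves are consumed as files (their covariance /
heuristic models are not reimplemented): scanner A plays the
tRNAscan-SE-like role, scanner B the ARAGORN-like role. Intron-less
predictions are trusted from A, intron-bearing ones from B; predicted
names are validated against the reference tRNAs, mismatches going to a
warning file for expert curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from plastann._warnings import Warning  # noqa: F401 - re-exported contract type
from plastann.annotate_core import GeneModel, similarity_search
from plastann.genome_model import Exon, Interval, Plastome, revcomp, translate_cds
from plastann.reference_db import ReferenceDB, normalize_gene_name

logger = logging.getLogger(__name__)


@dataclass
class TrnaPrediction:
    source: str  # scanner_a | scanner_b
    name: str
    anticodon: str
    interval: Interval
    intron_intervals: list[Interval] = field(default_factory=list)
    score: float = 0.0

    def __post_init__(self) -> None:
        if set(self.anticodon.upper()) - set("ACGUT"):
            raise ValueError(f"bad anticodon {self.anticodon!r}")
        for intron in self.intron_intervals:
            if not (self.interval.start <= intron.start <= intron.end <= self.interval.end):
                raise ValueError("intron not nested within the tRNA interval")

    @property
    def has_intron(self) -> bool:
        return bool(self.intron_intervals)


def anticodon_to_aa(anticodon: str) -> str:
    """One-letter amino acid decoded by a tRNA with the given anticodon."""
    ac = anticodon.upper().replace("U", "T")
    codon = revcomp(ac)
    if len(codon) != 3 or set(codon) - set("ACGT"):
        return "X"
    aa = translate_cds(codon + "TAA").protein[:1]
    return aa or "X"


def canonical_trna_name(anticodon: str, aa_hint: str | None = None) -> str:
    ac = anticodon.upper().replace("T", "U")
    aa = aa_hint or anticodon_to_aa(anticodon)
    return f"trn{aa}-{ac}"


def _to_model(pred: TrnaPrediction) -> GeneModel:
    """Kept prediction -> tRNA gene model (exons = interval minus introns)."""
    cuts = sorted(
        (iv for iv in pred.intron_intervals), key=lambda iv: iv.start
    )
    pieces: list[tuple[int, int]] = []
    pos = pred.interval.start
    for intron in cuts:
        if intron.start > pos:
            pieces.append((pos, intron.start - 1))
        pos = intron.end + 1
    if pos <= pred.interval.end:
        pieces.append((pos, pred.interval.end))
    if pred.interval.strand == "-":
        pieces.reverse()  # transcription order
    exons = [
        Exon(
            interval=Interval(start=s, end=e, strand=pred.interval.strand),
            phase=0,
            ordinal=i,
        )
        for i, (s, e) in enumerate(pieces, start=1)
    ]
    return GeneModel(
        name=normalize_gene_name(pred.name),
        kind="tRNA",
        exons=exons,
        strand=pred.interval.strand,
        provenance="trna",
        score=pred.score,
        notes=[f"source={pred.source}", f"anticodon={pred.anticodon.upper().replace('T', 'U')}"],
    )


def _reciprocal_overlap(a: Interval, b: Interval) -> bool:
    ov = a.overlap_len(b)
    return ov >= 0.5 * a.span() and ov >= 0.5 * b.span()


def reconcile_trna(
    preds_a: list[TrnaPrediction],
    preds_b: list[TrnaPrediction],
    warnings: list | None = None,
) -> list[GeneModel]:
    """Merge two scanners' predictions by the intron rule.

    Scanner-A predictions without introns and scanner-B predictions with
    introns are kept; at loci where both survive (>= 50% reciprocal
    overlap) the one whose intron status matches its scanner wins.
    Scanner-A intron-bearing predictions with no scanner-B counterpart are
    dropped with a warning.
    """
    kept_a = [p for p in preds_a if not p.has_intron]
    kept_b = [p for p in preds_b if p.has_intron]

    dropped_a_introns = [p for p in preds_a if p.has_intron]
    for p in dropped_a_introns:
        covered = any(
            _reciprocal_overlap(p.interval, q.interval) for q in kept_b
        )
        if warnings is not None:
            msg = (
                f"intron-bearing prediction {p.name} from scanner_a "
                + ("superseded by scanner_b" if covered else
                   "has no scanner_b counterpart and was dropped")
            )
            warnings.append(Warning(category="trna", subject=p.name,
                                    severity="warn" if not covered else "info",
                                    message=msg))

    final: list[TrnaPrediction] = list(kept_b)
    for p in kept_a:
        clash = next(
            (q for q in kept_b if _reciprocal_overlap(p.interval, q.interval)),
            None,
        )
        if clash is not None:
            continue  # intron-bearing locus: scanner B's model wins
        final.append(p)
    final.sort(key=lambda p: (p.interval.start, p.name))
    return [_to_model(p) for p in final]


def validate_trna_names(
    models: list[GeneModel], db: ReferenceDB, genome: Plastome | None = None
) -> list[Warning]:
    """Compare each predicted tRNA with its best reference hit by name."""
    ref_trnas = db.of_kind("tRNA")
    if not ref_trnas:
        return [Warning(category="trna", subject="*", severity="info",
                        message="name validation skipped: no reference tRNAs")]
    out: list[Warning] = []
    for model in models:
        if model.kind != "tRNA":
            continue
        if genome is not None:
            seq = model.spliced_seq(genome)
        else:
            continue
        best_name, best_score = None, 0.0
        for ref in ref_trnas:
            ref_seq = ref.cds_seq
            if len(ref_seq) < 8 or len(seq) < 8:
                continue
            hits = similarity_search(
                seq,
                Plastome(id="ref", sequence=ref_seq, circular=False),
                "nucleotide",
                min_evalue=1e3,
            )
            if hits and hits[0].score > best_score:
                best_score = hits[0].score
                best_name = normalize_gene_name(ref.name)
        if best_name is not None and best_name != normalize_gene_name(model.name):
            out.append(Warning(
                category="trna", subject=model.name, severity="warn",
                message=(f"predicted name {normalize_gene_name(model.name)} differs "
                         f"from best reference hit {best_name}"),
            ))
    return out


# ---------------------------------------------------------------------------
# Prediction file readers
# ---------------------------------------------------------------------------


def read_neutral_tsv(path: str, source: str) -> list[TrnaPrediction]:
    """Neutral TSV: name start end strand anticodon intron_start intron_end score.

    ``intron_start``/``intron_end`` of 0 mean no intron. Lines starting
    with '#' are ignored.
    """
    preds: list[TrnaPrediction] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, start, end, strand, anticodon = fields[:5]
            istart = int(fields[5]) if len(fields) > 5 else 0
            iend = int(fields[6]) if len(fields) > 6 else 0
            score = float(fields[7]) if len(fields) > 7 else 0.0
            iv = Interval(start=int(start), end=int(end), strand=strand)
            introns = (
                [Interval(start=istart, end=iend, strand=strand)]
                if istart and iend else []
            )
            preds.append(TrnaPrediction(
                source=source, name=name, anticodon=anticodon,
                interval=iv, intron_intervals=introns, score=score,
            ))
    return preds


def read_trnascan(path: str) -> list[TrnaPrediction]:
    """tRNAscan-SE v2 tabular output (.out with the 3 header lines)."""
    preds: list[TrnaPrediction] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("Sequence", "Name", "----")) or not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 9:
                f = line.split()
            begin, end = int(f[2]), int(f[3])
            aa, anticodon = f[4], f[5]
            ib, ie = int(f[6]), int(f[7])
            score = float(f[8])
            strand = "+" if begin <= end else "-"
            lo, hi = min(begin, end), max(begin, end)
            introns = []
            if ib and ie:
                introns = [Interval(start=min(ib, ie), end=max(ib, ie), strand=strand)]
            preds.append(TrnaPrediction(
                source="scanner_a",
                name=canonical_trna_name(anticodon, aa_hint=aa if len(aa) <= 3 else None),
                anticodon=anticodon,
                interval=Interval(start=lo, end=hi, strand=strand),
                intron_intervals=introns,
                score=score,
            ))
    return preds


def read_aragorn(path: str) -> list[TrnaPrediction]:
    """ARAGORN batch (-w) text output.

    Recognized data lines look like::

        2   tRNA-Ala               [10348,10432]   33      (ugc)
        3   tRNA-Ile              c[5120,5210]     34      (gau)    i(38,12)

    ``c[...]`` marks the complementary strand; ``i(offset,len)`` an intron
    given as 1-based offset into the gene and length.
    """
    preds: list[TrnaPrediction] = []
    import re

    pat = re.compile(
        r"^\s*\d+\s+tRNA-(\w+)\s+(c?)\[(-?\d+),(\d+)\]\s+\d+\s+\((\w+)\)"
        r"(?:\s+i\((\d+),(\d+)\))?"
    )
    with open(path) as fh:
        for line in fh:
            m = pat.match(line)
            if not m:
                continue
            aa3, comp, start, end, anticodon, ioff, ilen = m.groups()
            strand = "-" if comp else "+"
            lo, hi = int(start), int(end)
            introns = []
            if ioff and ilen:
                off, length = int(ioff), int(ilen)
                if strand == "+":
                    istart = lo + off - 1
                else:
                    istart = hi - off - length + 2
                introns = [Interval(start=istart, end=istart + length - 1, strand=strand)]
            aa1 = _THREE_TO_ONE.get(aa3.capitalize(), None)
            preds.append(TrnaPrediction(
                source="scanner_b",
                name=canonical_trna_name(anticodon, aa_hint=aa1),
                anticodon=anticodon,
                interval=Interval(start=lo, end=hi, strand=strand),
                intron_intervals=introns,
            ))
    return preds


_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def write_warnings_tsv(warnings: list[Warning], path: str) -> None:
    """Warning file: tab-separated category, subject, severity, message."""
    with open(path, "w") as fh:
        fh.write("category\tsubject\tseverity\tmessage\n")
        for w in warnings:
            fh.write(f"{w.category}\t{w.subject}\t{w.severity}\t{w.message}\n")
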