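"""Core sequence/coordinate types and circular-genome arithmetic.

Coordinates are 1-based inclusive everywhere in the public API; the only
0-based arithmetic happens inside helper functions and is converted at the
boundaries. Intervals on a circular genome may wrap the origin, in which
case ``wraps_origin`` is set and ``start > end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Plastome:
    """A (typically circular) plastid genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("plastome id must be non-empty")
        if not self.sequence:
            raise ValueError("plastome sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, interval: "Interval") -> str:
        """Strand-aware, wrap-aware sequence extraction (1-based inclusive)."""
        n = self.length
        if interval.wraps_origin:
            s = self.sequence[interval.start - 1 :] + self.sequence[: interval.end]
        else:
            s = self.sequence[interval.start - 1 : interval.end]
        return revcomp(s) if interval.strand == "-" else s

    def rotated(self, k: int) -> "Plastome":
        """Genome rotated so the old position k+1 becomes position 1."""
        k %= self.length
        return replace(self, sequence=self.sequence[k:] + self.sequence[:k])


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval, optionally wrapping the origin."""

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError("start > end on a non-wrapping interval")

    def span(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for wrapping interval")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def overlap_len(self, other: "Interval") -> int:
        """Overlap in bp between two non-wrapping intervals."""
        if self.wraps_origin or other.wraps_origin:
            raise ValueError("overlap_len only defined for non-wrapping intervals")
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def shifted(self, delta: int, genome_length: int) -> "Interval":
        """Interval translated by delta on a circular genome of given length."""
        s0 = (self.start - 1 + delta) % genome_length
        length = self.span(genome_length)
        e0 = (s0 + length - 1) % genome_length
        return Interval(
            start=s0 + 1,
            end=e0 + 1,
            strand=self.strand,
            wraps_origin=s0 + length > genome_length,
        )


@dataclass(frozen=True)
class Exon:
    interval: Interval
    phase: int = 0
    ordinal: int = 1

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError("exon ordinal must be >= 1")
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")


@dataclass(frozen=True)
class QuadripartiteLayout:
    """The LSC / IRa / SSC / IRb partition of a quadripartite plastome."""

    lsc: Interval
    ira: Interval
    ssc: Interval
    irb: Interval

    def ir_copies(self) -> tuple[Interval, Interval]:
        return self.ira, self.irb

    def region_of(self, position: int, genome_length: int) -> str:
        for name in ("lsc", "ira", "ssc", "irb"):
            if getattr(self, name).contains(position, genome_length):
                return name
        raise ValueError(f"position {position} outside genome")


@dataclass
class TranslationResult:
    protein: str
    internal_stop: bool = False
    partial_codon: bool = False

    def __str__(self) -> str:  # convenient for direct comparisons
        return self.protein


def translate_cds(cds: str, genetic_code_table: int = 11) -> TranslationResult:
    """Translate a CDS; trailing stop excluded, internal stops flagged.

    A length not divisible by 3 translates floor(len/3) codons and sets
    ``partial_codon``. Codons containing N translate to 'X'.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    partial = len(cds) % 3 != 0
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate(table=genetic_code_table))
    if prot.endswith("*"):
        prot = prot[:-1]
    internal = "*" in prot
    return TranslationResult(protein=prot, internal_stop=internal, partial_codon=partial)


def read_fasta(path: str) -> Plastome:
    """Read a plastome from FASTA; first record used (with warning) if several."""
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    cleaned = "".join(c if c in VALID_BASES else "N" for c in seq)
    if cleaned != seq:
        logger.warning("non-ACGTN characters in %s replaced with N", path)
    return Plastome(id=rec.id, sequence=cleaned)


# ---------------------------------------------------------------------------
# Inverted-repeat (quadripartite) structure detection
# ---------------------------------------------------------------------------

_HASH_MOD = (1 << 61) - 1
_HASH_BASE = 1_000_003


def _hashes(s: str, w: int, count: int) -> list[int]:
    """Rolling hashes of s[i:i+w] for i = 0..count-1."""
    h = 0
    for c in s[:w]:
        h = (h * _HASH_BASE + ord(c)) % _HASH_MOD
    top = pow(_HASH_BASE, w - 1, _HASH_MOD)
    out = [0] * count
    out[0] = h
    for i in range(1, count):
        h = ((h - ord(s[i - 1]) * top) % _HASH_MOD) * _HASH_BASE % _HASH_MOD
        h = (h + ord(s[i + w - 1])) % _HASH_MOD
        out[i] = h
    return out


def _circ_disjoint(i: int, j: int, length: int, n: int) -> bool:
    return (j - i) % n >= length and (i - j) % n >= length


def _ir_pairs_at(s2: str, r2: str, n: int, length: int, limit: int | None = None):
    """Yield 0-based (i, j) with circ(i,L) == revcomp(circ(j,L)), disjoint."""
    # revcomp(circular_segment(j, L)) == r2[2n-j-L : 2n-j]
    a_hashes = _hashes(s2, length, n)
    by_hash: dict[int, list[int]] = {}
    for i, h in enumerate(a_hashes):
        by_hash.setdefault(h, []).append(i)
    b_all = _hashes(r2, length, 2 * n - length + 1)
    out = []
    for j in range(n):
        pos = 2 * n - j - length
        for i in by_hash.get(b_all[pos], ()):
            if not _circ_disjoint(i, j, length, n):
                continue
            seg_a = s2[i : i + length]
            seg_b = r2[pos : pos + length]
            if seg_a != seg_b or "N" in seg_a:
                continue
            out.append((i, j))
            if limit is not None and len(out) >= limit:
                return out
    return out


def detect_inverted_repeats(
    genome: Plastome, min_ir_len: int = 1000
) -> QuadripartiteLayout | None:
    """Locate the maximal pair of exact reverse-complementary repeats.

    Returns the quadripartite layout, labelling the longer single-copy
    region LSC and the repeat copy immediately downstream of it IRa.
    Returns None (with a logged warning) when no such pair >= min_ir_len
    exists, e.g. for IR-lacking plastomes.
    """
    n = genome.length
    if n < 2 * min_ir_len:
        logger.warning(
            "genome %s (%d bp) shorter than 2 x min_ir_len=%d; no IR search",
            genome.id, n, min_ir_len,
        )
        return None
    s2 = genome.sequence * 2
    r2 = revcomp(s2)

    # Binary search the maximal length with any valid (disjoint) pair.
    lo, hi = min_ir_len, n // 2
    best_len = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _ir_pairs_at(s2, r2, n, mid, limit=1):
            best_len = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best_len == 0:
        logger.warning("no inverted repeat >= %d bp found in %s", min_ir_len, genome.id)
        return None

    pairs = _ir_pairs_at(s2, r2, n, best_len)
    i, j = min(pairs)  # canonical pair; (i,j) and (j,i) are both present

    g_after_1 = (j - (i + best_len)) % n  # gap between IR@i end and IR@j start
    g_after_2 = (i - (j + best_len)) % n
    if g_after_1 >= g_after_2:
        lsc0, lsc_len = (i + best_len) % n, g_after_1
        ira0, irb0 = j, i
        ssc0, ssc_len = (j + best_len) % n, g_after_2
    else:
        lsc0, lsc_len = (j + best_len) % n, g_after_2
        ira0, irb0 = i, j
        ssc0, ssc_len = (i + best_len) % n, g_after_1

    def iv(start0: int, length: int) -> Interval:
        e0 = (start0 + length - 1) % n
        return Interval(
            start=start0 + 1,
            end=e0 + 1,
            strand="+",
            wraps_origin=start0 + length > n,
        )

    return QuadripartiteLayout(
        lsc=iv(lsc0, lsc_len),
        ira=iv(ira0, best_len),
        ssc=iv(ssc0, ssc_len),
        irb=iv(irb0, best_len),
    )
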