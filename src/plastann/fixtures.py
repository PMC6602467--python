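"""Deterministic synthetic plastome + read simulator with full ground truth.

The default genome is quadripartite (LSC 18 kb, IR 6 kb, SSC 4 kb): IRb is
the exact reverse complement of IRa, so every feature planted inside IRa
exists twice. The gene roster covers single- and multi-exon CDS genes, a
pair of overlapping genes on opposite strands, the anchored micro-exon
genes, a trans-spliced rps12 (exon 1 in the LSC, exons 2+3 in both IRs),
four rRNA loci in the IR and six tRNA loci (two with introns).
SSR / tandem / dispersed repeats are planted behind "mismatch walls" so
the finders report exactly the planted coordinates; filler and gene
blocks are rejection-sampled against accidental repeats, and the
assembled genome is validated against the planted roster (deterministic
retries on the rare residual collision).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from plastann.annotate_core import AnnotationSet, GeneModel
from plastann.genome_model import (
    Exon,
    Interval,
    Plastome,
    QuadripartiteLayout,
    STOP_CODONS,
    revcomp,
)
from plastann.repeats import (
    SSR,
    DispersedRepeat,
    TandemRepeat,
    canonical_rotation,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    is_primitive,
    _min_period,
)

logger = logging.getLogger(__name__)

PETB_EXON1 = "ATGAGT"
PETD_EXON1 = "ATGGGAGT"
RPL16_EXON1 = "ATGCTTAGT"
RPS12_EXON3 = "AATATGGGGTCAAAAAGCCAAAATAA"

_BASES = "ACGT"
_STOPS = sorted(STOP_CODONS)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WALL = 4  # mismatch-wall width around planted repeats (max_mismatch + 1)


@dataclass
class FixtureConfig:
    lsc_len: int = 18000
    ir_len: int = 6000
    ssc_len: int = 4000
    divergence: float = 0.0  # query-vs-reference mutation rate (single-copy only)
    anchor_mutation_rate: float = 0.0  # extra mutations inside 5' UTR anchors

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass(frozen=True)
class PlantedVariant:
    position: int  # 1-based
    ref: str
    alt: str
    fraction: float


@dataclass(frozen=True)
class PlantedEditing:
    position: int  # 1-based
    gene: str
    level: float
    read_base: str  # base observed on the plus strand of edited reads


@dataclass
class FixtureTruth:
    genome: Plastome
    ref_genome: Plastome
    layout: QuadripartiteLayout
    annotation: AnnotationSet
    ssrs: list[SSR]
    tandems: list[TandemRepeat]
    dispersed: list[DispersedRepeat]
    planted_variants: list[PlantedVariant]
    planted_editing: list[PlantedEditing]
    seed: int
    config: FixtureConfig = field(default_factory=FixtureConfig)

    def write(self, outdir: str) -> dict[str, str]:
        """Emit query FASTA + reference GenBank; returns the paths."""
        import os

        from plastann.writers import write_genbank

        os.makedirs(outdir, exist_ok=True)
        fasta = os.path.join(outdir, "query.fasta")
        with open(fasta, "w") as fh:
            fh.write(f">{self.genome.id}\n")
            for i in range(0, self.genome.length, 70):
                fh.write(self.genome.sequence[i : i + 70] + "\n")
        gb = os.path.join(outdir, "reference.gb")
        ref_ann = AnnotationSet(
            genome_id=self.ref_genome.id, models=self.annotation.models
        )
        write_genbank(ref_ann, self.ref_genome, gb)
        return {"fasta": fasta, "reference": gb}

    def write_trna_predictions(self, outdir: str) -> tuple[str, str]:
        """Neutral-TSV prediction files for both scanners from the truth."""
        import os

        os.makedirs(outdir, exist_ok=True)
        path_a = os.path.join(outdir, "trna_a.tsv")
        path_b = os.path.join(outdir, "trna_b.tsv")
        with open(path_a, "w") as fa, open(path_b, "w") as fb:
            header = ("# name\tstart\tend\tstrand\tanticodon"
                      "\tintron_start\tintron_end\tscore\n")
            fa.write(header)
            fb.write(header)
            for m in self.annotation.models:
                if m.kind != "tRNA":
                    continue
                lo, hi = m.t_extent()
                anticodon = m.name.split("-")[-1]
                if len(m.exons) == 1:
                    fa.write(f"{m.name}\t{lo}\t{hi}\t{m.strand}\t{anticodon}"
                             f"\t0\t0\t80.0\n")
                else:
                    ivs = sorted((e.interval for e in m.exons),
                                 key=lambda iv: iv.start)
                    istart, iend = ivs[0].end + 1, ivs[1].start - 1
                    fb.write(f"{m.name}\t{lo}\t{hi}\t{m.strand}\t{anticodon}"
                             f"\t{istart}\t{iend}\t75.0\n")
        return path_a, path_b


# ---------------------------------------------------------------------------
# sequence building helpers
# ---------------------------------------------------------------------------


def _nonstop_fill(rng: random.Random, prefix: str, length: int) -> str:
    """Sequence of the given length starting with prefix and containing no
    complete in-frame stop codon (frame anchored at position 0)."""
    seq = list(prefix)
    while len(seq) < length:
        seq.append(rng.choice(_BASES))
        if len(seq) % 3 == 0 and "".join(seq[-3:]) in STOP_CODONS:
            seq.pop()
    return "".join(seq)


def _random_cds(rng: random.Random, length: int, prefix: str = "ATG") -> str:
    """Valid CDS: starts with prefix (default ATG), single stop at the end."""
    if length % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    return _nonstop_fill(rng, prefix, length - 3) + rng.choice(_STOPS)


def _rand_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _wall_base(rng: random.Random, avoid: str) -> str:
    return rng.choice([b for b in _BASES if b != avoid])


def _has_ssr(chunk: str) -> bool:
    if len(chunk) < 8:
        return False
    return bool(find_ssrs(
        Plastome(id="f", sequence=chunk, circular=False),
        min_copies={1: 6, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3},
    ))


def _has_tandem_seed(chunk: str) -> bool:
    """Any lag-p (p >= 7) self-match run long enough to risk a spurious
    tandem call (a period-p array needs roughly p matched bases)."""
    n = len(chunk)
    if n < 14:
        return False
    arr = np.frombuffer(chunk.encode(), dtype=np.uint8)
    for p in range(7, n // 2 + 1):
        w = max(7, int(0.7 * p))
        eq = (arr[: n - p] == arr[p:]).astype(np.int32)
        if eq.size < w:
            break
        c = np.cumsum(np.concatenate(([0], eq)))
        if np.any(c[w:] - c[:-w] == w):
            return True
    return False


@dataclass
class _LocalFeature:
    name: str
    kind: str
    strand: str
    exons: list[tuple[int, int]]  # block-local 0-based half-open, transcription order
    trans_part: str | None = None  # 'exon1' | 'exon23' for the rps12 pieces


@dataclass
class _Block:
    seq: str
    features: list[_LocalFeature] = field(default_factory=list)
    tag: str = ""


def _gene_block(
    rng: random.Random,
    name: str,
    kind: str,
    strand: str,
    exon_lens: list[int],
    intron_lens: list[int],
    anchor5: str | None = None,
    cds_seq: str | None = None,
    trans_part: str | None = None,
    anchor3: str | None = None,
) -> _Block:
    """One gene's genomic block (built on the sense strand, revcomped if -).

    Regenerated (bounded retries) when the random content happens to carry
    an SSR-grade or tandem-grade repeat.
    """
    total = sum(exon_lens)
    fixed_cds = cds_seq
    for attempt in range(30):
        if fixed_cds is not None:
            cds = fixed_cds
        elif kind == "CDS":
            cds = _random_cds(rng, total)
        else:
            cds = _rand_seq(rng, total)
        sense_parts: list[str] = []
        exon_coords: list[tuple[int, int]] = []
        pos = 0
        if anchor5:
            sense_parts.append(anchor5)
            pos += len(anchor5)
        cds_pos = 0
        for i, elen in enumerate(exon_lens):
            exon_coords.append((pos, pos + elen))
            sense_parts.append(cds[cds_pos : cds_pos + elen])
            cds_pos += elen
            pos += elen
            if i < len(intron_lens):
                sense_parts.append(_rand_seq(rng, intron_lens[i]))
                pos += intron_lens[i]
        if anchor3:
            sense_parts.append(anchor3)
        sense = "".join(sense_parts)
        if attempt < 29 and (_has_tandem_seed(sense) or _has_ssr(sense)):
            continue
        break

    if strand == "-":
        L = len(sense)
        block_seq = revcomp(sense)
        exon_coords = [(L - e, L - s) for (s, e) in exon_coords]
    else:
        block_seq = sense
    return _Block(
        seq=block_seq,
        features=[_LocalFeature(name=name, kind=kind, strand=strand,
                                exons=exon_coords, trans_part=trans_part)],
        tag=name,
    )


def _overlap_block(
    rng: random.Random, name_a: str, name_b: str, len_a: int, len_b: int,
    ov: int = 18,
) -> _Block:
    """Two overlapping CDS genes on opposite strands sharing ``ov`` bases."""
    assert len_a % 3 == 0 and len_b % 3 == 0 and ov % 3 == 0
    for _ in range(30):
        rc_stop = revcomp(rng.choice(_STOPS))
        mid = []
        for _c in range(ov // 3 - 2):
            while True:
                c = _rand_seq(rng, 3)
                if c not in STOP_CODONS and revcomp(c) not in STOP_CODONS:
                    mid.append(c)
                    break
        overlap = rc_stop + "".join(mid) + rng.choice(_STOPS)
        a_seq = _nonstop_fill(rng, "ATG", len_a - ov) + overlap
        b_fill = _nonstop_fill(rng, "ATG", len_b - ov)
        block_seq = a_seq + revcomp(b_fill)
        if not (_has_tandem_seed(block_seq) or _has_ssr(block_seq)):
            break
    start_b = len_a - ov
    return _Block(
        seq=block_seq,
        features=[
            _LocalFeature(name=name_a, kind="CDS", strand="+", exons=[(0, len_a)]),
            _LocalFeature(name=name_b, kind="CDS", strand="-",
                          exons=[(start_b, start_b + len_b)]),
        ],
        tag=f"{name_a}/{name_b}",
    )


def _walled(rng: random.Random, core: str, p: int) -> str:
    """core framed by _WALL guard bases that mismatch at lag p on each side."""
    chars = list(core)
    for _ in range(_WALL):  # left guard, built inward-out against lag-p partner
        chars.insert(0, _wall_base(rng, chars[p - 1]))
    for _ in range(_WALL):
        chars.append(_wall_base(rng, chars[len(chars) - p]))
    return "".join(chars)


def _ssr_block(rng: random.Random, motif: str, copies: int) -> _Block:
    return _Block(seq=_walled(rng, motif * copies, len(motif)),
                  tag=f"ssr:{motif}")


def _tandem_unit(rng: random.Random, p: int) -> str:
    while True:
        unit = _rand_seq(rng, p)
        if is_primitive(unit) and _min_period(unit) > 6 \
                and not _has_ssr(unit * 2):
            return unit


def _tandem_block(rng: random.Random, unit: str, copies: int) -> _Block:
    return _Block(seq=_walled(rng, unit * copies, len(unit)),
                  tag=f"tandem:{len(unit)}:{unit}")


# ---------------------------------------------------------------------------
# region assembly
# ---------------------------------------------------------------------------


def _filler(rng: random.Random, length: int, kmer_guard: set[str],
            k: int = 15) -> str:
    """Random filler avoiding SSR/tandem-grade runs and 15-mer collisions."""
    for _ in range(200):
        chars: list[str] = []
        while len(chars) < length:
            b = rng.choice(_BASES)
            if len(chars) >= 3 and all(c == b for c in chars[-3:]):
                continue  # no homopolymer longer than 3
            chars.append(b)
        chunk = "".join(chars)
        if _has_ssr(chunk) or _has_tandem_seed(chunk):
            continue
        words = [chunk[i : i + k] for i in range(max(0, len(chunk) - k + 1))]
        wordset = set(words)
        if len(wordset) < len(words):  # internal duplicate k-mer
            continue
        if wordset & kmer_guard:
            continue
        kmer_guard |= wordset
        kmer_guard |= {revcomp(w) for w in wordset}
        return chunk
    raise _RosterMismatch("could not generate clean filler")


def _guard_add(kmer_guard: set[str], seq: str, k: int = 15) -> None:
    for i in range(max(0, len(seq) - k + 1)):
        w = seq[i : i + k]
        kmer_guard.add(w)
        kmer_guard.add(revcomp(w))


def _assemble_region(
    rng: random.Random,
    blocks: list[_Block],
    target_len: int,
    kmer_guard: set[str],
    region_name: str,
) -> tuple[str, list[tuple[_Block, int]]]:
    """Interleave blocks with filler to exactly target_len; returns the
    region sequence and each block's offset within it."""
    used = sum(len(b.seq) for b in blocks)
    n_gaps = len(blocks) + 1
    spare = target_len - used
    if spare < n_gaps * 110:
        raise ValueError(
            f"region {region_name}: blocks ({used} bp) leave too little room "
            f"in {target_len} bp"
        )
    base_gap = spare // n_gaps
    gaps = [base_gap] * n_gaps
    gaps[-1] += spare - base_gap * n_gaps
    parts: list[str] = []
    placed: list[tuple[_Block, int]] = []
    offset = 0
    for i, block in enumerate(blocks):
        fill = _filler(rng, gaps[i], kmer_guard)
        parts.append(fill)
        offset += len(fill)
        placed.append((block, offset))
        parts.append(block.seq)
        _guard_add(kmer_guard, block.seq)
        offset += len(block.seq)
    parts.append(_filler(rng, gaps[-1], kmer_guard))
    return "".join(parts), placed


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _phase_exons(intervals: list[Interval], n: int, cds: bool) -> list[Exon]:
    out = []
    cum = 0
    for i, iv in enumerate(intervals, start=1):
        out.append(Exon(interval=iv, phase=(3 - cum % 3) % 3 if cds else 0,
                        ordinal=i))
        cum += iv.span(n)
    return out


class _RosterMismatch(RuntimeError):
    pass


def generate_plastome(seed: int, config: FixtureConfig | None = None) -> FixtureTruth:
    """Build the synthetic quadripartite plastome with full ground truth.

    Byte-identical for identical (seed, config). The assembled genome is
    validated against the planted repeat roster; deterministic retries
    with derived seeds handle the rare random collision.
    """
    config = config or FixtureConfig()
    last_err: Exception | None = None
    for attempt in range(8):
        rng = random.Random(f"plastann-fixture:{seed}:{attempt}")
        try:
            return _generate(rng, seed, config)
        except _RosterMismatch as exc:
            logger.warning("fixture attempt %d failed validation: %s", attempt, exc)
            last_err = exc
    raise RuntimeError(f"fixture generation failed repeatedly: {last_err}")


def _generate(rng: random.Random, seed: int, config: FixtureConfig) -> FixtureTruth:
    kmer_guard: set[str] = set()
    anchors = {g: _rand_seq(rng, 50) for g in ("petB", "petD", "rpl16", "rps12")}

    # rps12 CDS: exon1 (114) + exon2 (232) + the printed 26-bp last exon
    exon12 = _nonstop_fill(rng, "ATG", 346)
    if exon12[345] == "T":  # junction codon x+"AA" must not become a stop
        exon12 = exon12[:345] + rng.choice("ACG")
    rps12_cds = exon12 + RPS12_EXON3

    lsc_blocks = [
        _gene_block(rng, "psbA", "CDS", "+", [600], []),
        _gene_block(rng, "trnH-GUG", "tRNA", "+", [74], []),
        _gene_block(rng, "rbcL", "CDS", "+", [900], []),
        _ssr_block(rng, "A", 12),
        _gene_block(rng, "matK", "CDS", "-", [750], []),
        _gene_block(rng, "trnK-UUU", "tRNA", "+", [37, 35], [300]),
        _ssr_block(rng, "AT", 6),
        _gene_block(rng, "atpA", "CDS", "-", [600], []),
        _overlap_block(rng, "psbD", "psbB", 450, 432),
        _ssr_block(rng, "AAG", 5),
        _gene_block(rng, "ndhB", "CDS", "+", [720, 756], [680]),
        _tandem_block(rng, _tandem_unit(rng, 30), 4),
        _gene_block(rng, "clpP", "CDS", "-", [210, 291, 69], [560, 430]),
        _ssr_block(rng, "AGAT", 5),
        _gene_block(rng, "petB", "CDS", "+", [6, 642], [700],
                    anchor5=anchors["petB"],
                    cds_seq=_random_cds(rng, 648, prefix=PETB_EXON1)),
        _gene_block(rng, "trnM-CAU", "tRNA", "-", [73], []),
        _gene_block(rng, "petD", "CDS", "+", [8, 475], [650],
                    anchor5=anchors["petD"],
                    cds_seq=_random_cds(rng, 483, prefix=PETD_EXON1)),
        _ssr_block(rng, "AACTG", 5),
        _gene_block(rng, "rpl16", "CDS", "-", [9, 399], [600],
                    anchor5=anchors["rpl16"],
                    cds_seq=_random_cds(rng, 408, prefix=RPL16_EXON1)),
        _gene_block(rng, "trnF-GAA", "tRNA", "+", [75], []),
        _gene_block(rng, "rps12", "CDS", "-", [114], [],
                    cds_seq=rps12_cds[:114], trans_part="exon1"),
        _ssr_block(rng, "AACGAT", 5),
        _gene_block(rng, "trnL-UAA", "tRNA", "-", [35, 50], [250]),
        _tandem_block(rng, _tandem_unit(rng, 17), 3),
        _gene_block(rng, "trnI-GAU", "tRNA", "+", [74], []),
    ]

    # dispersed repeat copies (forward + palindromic) with mismatch walls
    fwd_seg = _rand_seq(rng, 40)
    pal_seg = _rand_seq(rng, 35)
    fa_l, fa_r = _rand_seq(rng, _WALL), _rand_seq(rng, _WALL)
    pa_l, pa_r = _rand_seq(rng, _WALL), _rand_seq(rng, _WALL)
    fb_l = "".join(_wall_base(rng, fa_l[t]) for t in range(_WALL))
    fb_r = "".join(_wall_base(rng, fa_r[t]) for t in range(_WALL))
    pb_l = "".join(_wall_base(rng, _COMP[pa_r[_WALL - 1 - t]]) for t in range(_WALL))
    pb_r = "".join(_wall_base(rng, _COMP[pa_l[_WALL - 1 - t]]) for t in range(_WALL))
    blk_fwd_a = _Block(seq=fa_l + fwd_seg + fa_r, tag="disp:fwd:a")
    blk_fwd_b = _Block(seq=fb_l + fwd_seg + fb_r, tag="disp:fwd:b")
    blk_pal_a = _Block(seq=pa_l + pal_seg + pa_r, tag="disp:pal:a")
    blk_pal_b = _Block(seq=pb_l + revcomp(pal_seg) + pb_r, tag="disp:pal:b")
    lsc_blocks.insert(3, blk_fwd_a)
    lsc_blocks.insert(12, blk_fwd_b)
    lsc_blocks.insert(8, blk_pal_a)
    lsc_blocks.append(blk_pal_b)

    ira_blocks = [
        _gene_block(rng, "rrn16", "rRNA", "+", [900], []),
        _gene_block(rng, "rrn23", "rRNA", "+", [1500], []),
        _gene_block(rng, "rrn4.5", "rRNA", "+", [100], []),
        _gene_block(rng, "rrn5", "rRNA", "+", [120], []),
        _gene_block(rng, "rps12", "CDS", "+", [232, 26], [540],
                    cds_seq=rps12_cds[114:], trans_part="exon23",
                    anchor3=anchors["rps12"]),
    ]
    ssc_blocks = [
        _gene_block(rng, "ndhA", "CDS", "-", [540, 552], [550]),
        _gene_block(rng, "ccsA", "CDS", "+", [600], []),
    ]

    lsc_seq, lsc_placed = _assemble_region(rng, lsc_blocks, config.lsc_len,
                                           kmer_guard, "LSC")
    ira_seq, ira_placed = _assemble_region(rng, ira_blocks, config.ir_len,
                                           kmer_guard, "IRa")
    ssc_seq, ssc_placed = _assemble_region(rng, ssc_blocks, config.ssc_len,
                                           kmer_guard, "SSC")

    # IR boundary guards: 'A' at both single-copy-region ends keeps the
    # detected IR from extending past the planted boundaries
    lsc_seq = "A" + lsc_seq[1:-1] + "A"
    ssc_seq = "A" + ssc_seq[1:-1] + "A"

    irb_seq = revcomp(ira_seq)
    genome_seq = lsc_seq + ira_seq + ssc_seq + irb_seq
    n = len(genome_seq)
    assert n == config.total_len

    lsc_off = 0
    ira_off = config.lsc_len
    ssc_off = ira_off + config.ir_len
    irb_off = ssc_off + config.ssc_len

    # --- truth gene models -------------------------------------------------
    models: list[GeneModel] = []
    rps12_exon1: Interval | None = None
    rps12_cassettes: list[list[Interval]] = []

    def add_feature(feat: _LocalFeature, abs_off: int) -> None:
        nonlocal rps12_exon1
        intervals = [
            Interval(start=abs_off + s + 1, end=abs_off + e, strand=feat.strand)
            for (s, e) in feat.exons
        ]
        if feat.trans_part == "exon1":
            rps12_exon1 = intervals[0]
            return
        if feat.trans_part == "exon23":
            rps12_cassettes.append(intervals)
            return
        models.append(GeneModel(
            name=feat.name,
            kind=feat.kind,
            exons=_phase_exons(intervals, n, feat.kind == "CDS"),
            strand=feat.strand,
            provenance="core",
        ))

    for placed, region_off in ((lsc_placed, lsc_off), (ira_placed, ira_off),
                               (ssc_placed, ssc_off)):
        for block, off in placed:
            for feat in block.features:
                add_feature(feat, region_off + off)

    # IRb mirror copies of every IRa feature (same exon identity order)
    for block, off in ira_placed:
        for feat in block.features:
            mirror_exons = [
                (config.ir_len - (off + e), config.ir_len - (off + s))
                for (s, e) in feat.exons
            ]
            add_feature(
                _LocalFeature(
                    name=feat.name, kind=feat.kind,
                    strand="-" if feat.strand == "+" else "+",
                    exons=mirror_exons, trans_part=feat.trans_part,
                ),
                irb_off,
            )

    # trans-spliced rps12 transcripts (cassettes ordered by genomic start)
    assert rps12_exon1 is not None and rps12_cassettes
    rps12_cassettes.sort(key=lambda ivs: ivs[0].start)
    for idx, cassette in enumerate(rps12_cassettes, start=1):
        intervals = [rps12_exon1] + cassette
        strands = {iv.strand for iv in intervals}
        models.append(GeneModel(
            name="rps12",
            kind="CDS",
            exons=_phase_exons(intervals, n, cds=True),
            strand=intervals[1].strand if len(strands) == 1 else "mixed",
            trans_spliced=True,
            provenance="itgie",
            transcript_id=f"rps12.t{idx}",
            shared_exon_ref=1,
        ))

    by_name: dict[str, list[GeneModel]] = {}
    for m in models:
        by_name.setdefault(m.transcript_id or m.name, []).append(m)
    for same in by_name.values():
        if len(same) > 1:
            for i, m in enumerate(sorted(same, key=lambda x: x.t_extent()[0]), 1):
                m.copy = i

    # --- repeat rosters ----------------------------------------------------
    ssr_truth: list[SSR] = []
    tandem_truth: list[TandemRepeat] = []
    disp_truth: list[DispersedRepeat] = []
    disp_parts: dict[str, tuple[int, int]] = {}
    for block, off in lsc_placed:
        abs0 = lsc_off + off
        core0 = abs0 + _WALL
        core_len = len(block.seq) - 2 * _WALL
        if block.tag.startswith("ssr:"):
            motif = block.tag.split(":", 1)[1]
            copies = core_len // len(motif)
            ssr_truth.append(SSR(
                motif=canonical_rotation(motif),
                copies=copies,
                interval=Interval(start=core0 + 1,
                                  end=core0 + copies * len(motif)),
            ))
        elif block.tag.startswith("tandem:"):
            _, p_s, unit = block.tag.split(":", 2)
            p = int(p_s)
            tandem_truth.append(TandemRepeat(
                unit_len=p,
                copies=round(core_len / p, 2),
                consensus=unit,
                interval=Interval(start=core0 + 1, end=core0 + core_len),
                percent_identity=1.0,
            ))
            # a tandem array is also a set of forward self-pairs
            d = p
            while core_len - d >= 30:
                disp_truth.append(DispersedRepeat(
                    interval_a=Interval(start=core0 + 1, end=core0 + core_len - d),
                    interval_b=Interval(start=core0 + d + 1, end=core0 + core_len),
                    orientation="forward", length=core_len - d, mismatches=0,
                ))
                d += p
        elif block.tag.startswith("disp:"):
            disp_parts[block.tag] = (core0, core_len)
    ssr_truth.sort(key=lambda r: r.interval.start)
    for tag_a, tag_b, orientation in (
        ("disp:fwd:a", "disp:fwd:b", "forward"),
        ("disp:pal:a", "disp:pal:b", "palindromic"),
    ):
        a0, length = disp_parts[tag_a]
        b0, _ = disp_parts[tag_b]
        lo, hi = sorted((a0, b0))
        disp_truth.append(DispersedRepeat(
            interval_a=Interval(start=lo + 1, end=lo + length),
            interval_b=Interval(start=hi + 1, end=hi + length),
            orientation=orientation, length=length, mismatches=0,
        ))
    disp_truth.sort(key=lambda r: (r.orientation, r.interval_a.start,
                                   r.interval_b.start))

    layout = QuadripartiteLayout(
        lsc=Interval(start=1, end=config.lsc_len),
        ira=Interval(start=ira_off + 1, end=ira_off + config.ir_len),
        ssc=Interval(start=ssc_off + 1, end=ssc_off + config.ssc_len),
        irb=Interval(start=irb_off + 1, end=irb_off + config.ir_len),
    )
    ref_genome = Plastome(id=f"fixture{seed}", sequence=genome_seq)

    # --- query mutations (the reference stays pristine) --------------------
    query_seq = list(genome_seq)
    protected = _protected_positions(models, n)
    for anchor in anchors.values():
        a0 = genome_seq.find(anchor)
        if a0 >= 0:
            protected.update(range(a0, a0 + 50))
    if config.divergence > 0:
        single_copy = list(range(0, config.lsc_len)) + \
            list(range(ssc_off, irb_off))
        for pos0 in single_copy:
            if pos0 in protected:
                continue
            if rng.random() < config.divergence:
                query_seq[pos0] = _wall_base(rng, genome_seq[pos0])
    if config.anchor_mutation_rate > 0:
        for gene in ("petB", "petD", "rpl16"):
            a0 = genome_seq.find(anchors[gene])
            for t in range(50):
                if rng.random() < config.anchor_mutation_rate:
                    query_seq[a0 + t] = _wall_base(rng, genome_seq[a0 + t])
    genome = Plastome(id=f"fixture{seed}", sequence="".join(query_seq))

    annotation = AnnotationSet(genome_id=genome.id, models=models, layout=layout)
    variants = _plant_variants(rng, genome, n)
    editing = _plant_editing(genome, models, n)

    truth = FixtureTruth(
        genome=genome,
        ref_genome=ref_genome,
        layout=layout,
        annotation=annotation,
        ssrs=ssr_truth,
        tandems=tandem_truth,
        dispersed=disp_truth,
        planted_variants=variants,
        planted_editing=editing,
        seed=seed,
        config=config,
    )
    _validate_roster(truth)
    return truth


def _protected_positions(models: list[GeneModel], n: int) -> set[int]:
    """Positions that query-vs-reference divergence must not touch."""
    protected: set[int] = set()
    for m in models:
        for exon in m.exons:
            iv = exon.interval
            if iv.wraps_origin:
                continue
            if iv.span(n) <= 30:  # micro exons stay pristine
                protected.update(range(iv.start - 1, iv.end))
            else:  # protect exon boundaries (search seeds + terminal codons)
                protected.update(range(iv.start - 1, iv.start + 11))
                protected.update(range(iv.end - 12, iv.end))
    return protected


def _plant_variants(rng: random.Random, genome: Plastome, n: int) -> list[PlantedVariant]:
    out: list[PlantedVariant] = []
    used: list[int] = []
    tries = 0
    while len(out) < 15 and tries < 10000:
        tries += 1
        pos0 = rng.randrange(200, n - 200)
        if any(abs(pos0 - u) < 60 for u in used):
            continue
        ref = genome.sequence[pos0]
        if ref == "N":
            continue
        used.append(pos0)
        out.append(PlantedVariant(position=pos0 + 1, ref=ref,
                                  alt=_wall_base(rng, ref), fraction=0.3))
    out.sort(key=lambda v: v.position)
    return out


def _plant_editing(genome: Plastome, models: list[GeneModel], n: int) -> list[PlantedEditing]:
    """Twelve C-to-U sites inside the ndhB-like gene (sense-strand C's)."""
    from plastann.diversity import _cds_walk

    ndhb = next(m for m in models if m.name == "ndhB")
    cds = ndhb.spliced_seq(genome)
    margin = 110  # exonic read coverage ramps over one read length

    def interior(pos: int) -> bool:
        return any(
            e.interval.start + margin <= pos <= e.interval.end - margin
            for e in ndhb.exons
        )

    picks: list[int] = []
    for pos, idx in _cds_walk(ndhb, n):
        if cds[idx] == "C" and idx % 3 == 1 and interior(pos):
            if all(abs(pos - p) >= 40 for p in picks):
                picks.append(pos)
        if len(picks) == 12:
            break
    if len(picks) < 12:
        raise _RosterMismatch("not enough editable C positions in ndhB")
    read_base = "T" if ndhb.strand == "+" else "A"
    levels = [0.3, 0.4, 0.5, 0.6]
    return [
        PlantedEditing(position=pos, gene="ndhB",
                       level=levels[i % len(levels)], read_base=read_base)
        for i, pos in enumerate(sorted(picks))
    ]


def _disp_key(r: DispersedRepeat):
    return (r.orientation, r.interval_a.start, r.interval_b.start, r.length)


def _validate_roster(truth: FixtureTruth) -> None:
    """Finder outputs on the reference genome must equal the planted roster."""
    g = truth.ref_genome
    found_ssrs = find_ssrs(g)
    if found_ssrs != truth.ssrs:
        raise _RosterMismatch(
            f"SSR roster mismatch: planted {len(truth.ssrs)}, found {len(found_ssrs)}"
        )
    found_tandem = find_tandem_repeats(g)
    if found_tandem != truth.tandems:
        raise _RosterMismatch(
            f"tandem roster mismatch: planted {len(truth.tandems)}, "
            f"found {len(found_tandem)}"
        )
    found_disp = find_dispersed_repeats(g, layout=truth.layout)
    if sorted(found_disp, key=_disp_key) != sorted(truth.dispersed, key=_disp_key):
        raise _RosterMismatch(
            f"dispersed roster mismatch: planted {len(truth.dispersed)}, "
            f"found {len(found_disp)}"
        )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: FixtureTruth,
    mode: str,
    depth: int,
    read_len: int,
    seed: int,
    out_prefix: str,
) -> tuple[str, str]:
    """Uniform gapless reads with truth coordinates (no mapper needed).

    dna mode samples the whole genome and injects the planted variants at
    their fractions; rna mode samples exonic regions of CDS genes and
    injects the planted C-to-U edits at their levels. Returns the paths of
    the written SAM and FASTQ files.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(f"plastann-reads:{seed}:{mode}")
    genome = truth.genome
    n = genome.length
    sam_path = f"{out_prefix}.sam"
    fastq_path = f"{out_prefix}.fastq"

    variant_by_pos = {v.position: v for v in truth.planted_variants}
    editing_by_pos = {e.position: e for e in truth.planted_editing}

    starts: list[int] = []
    if mode == "dna":
        n_reads = depth * n // read_len
        starts = [rng.randrange(0, n - read_len + 1) for _ in range(n_reads)]
    elif mode == "rna":
        for m in truth.annotation.models:
            if m.kind != "CDS":
                continue
            for exon in m.exons:
                iv = exon.interval
                if iv.wraps_origin or iv.span(n) < read_len:
                    continue
                count = max(1, depth * iv.span(n) // read_len)
                starts.extend(
                    rng.randrange(iv.start - 1, iv.end - read_len + 1)
                    for _ in range(count)
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    qual = "I" * read_len
    with open(sam_path, "w") as sam, open(fastq_path, "w") as fq:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        sam.write(f"@SQ\tSN:{genome.id}\tLN:{n}\n")
        for i, start0 in enumerate(starts):
            seq = list(genome.sequence[start0 : start0 + read_len])
            if mode == "dna":
                for off in range(read_len):
                    v = variant_by_pos.get(start0 + off + 1)
                    if v is not None and rng.random() < v.fraction:
                        seq[off] = v.alt
            else:
                for off in range(read_len):
                    e = editing_by_pos.get(start0 + off + 1)
                    if e is not None and rng.random() < e.level:
                        seq[off] = e.read_base
            flag = 16 if rng.random() < 0.5 else 0
            read = "".join(seq)
            name = f"r{i:06d}"
            sam.write(
                f"{name}\t{flag}\t{genome.id}\t{start0 + 1}\t60\t{read_len}M"
                f"\t*\t0\t0\t{read}\t{qual}\n"
            )
            fq.write(f"@{name}\n{revcomp(read) if flag == 16 else read}\n+\n{qual}\n")
    return sam_path, fastq_path
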