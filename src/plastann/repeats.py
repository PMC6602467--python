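"""Integrated repeat discovery: SSRs (unit 1-6 bp), longer tandem repeats
(unit > 6 bp) and dispersed forward/palindromic repeat pairs.

All three finders are exact re-implementations of the pipeline roles of
the classic external tools, with documented, overridable thresholds. The
tandem detector uses period-wise self-comparison instead of a full
Bernoulli model; the dispersed finder enumerates maximal pairs with a
bounded substitution count via exact k-mer seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from plastann.genome_model import Interval, Plastome, QuadripartiteLayout, revcomp

logger = logging.getLogger(__name__)

#: MISA-tradition minimum copy numbers per unit size
DEFAULT_SSR_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
COMPOUND_GAP = 100


@dataclass(frozen=True)
class SSR:
    motif: str  # lexicographically minimal rotation, primitive
    copies: int
    interval: Interval
    compound_id: int | None = None


@dataclass(frozen=True)
class TandemRepeat:
    unit_len: int
    copies: float
    consensus: str
    interval: Interval
    percent_identity: float


@dataclass(frozen=True)
class DispersedRepeat:
    interval_a: Interval
    interval_b: Interval
    orientation: str  # forward | palindromic
    length: int
    mismatches: int


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(
    genome: Plastome,
    min_copies: dict[int, int] | None = None,
) -> list[SSR]:
    """All maximal perfect tandem runs of primitive 1-6 bp units.

    A run is reported when its full-copy count meets the unit-size
    threshold; runs within ``COMPOUND_GAP`` bp share a compound id.
    """
    thresholds = dict(DEFAULT_SSR_MIN_COPIES)
    if min_copies:
        thresholds.update(min_copies)
    s = genome.sequence
    n = len(s)
    raw: list[SSR] = []
    for p, need in sorted(thresholds.items()):
        i = 0
        while i + 2 * p <= n:
            if s[i] == "N":
                i += 1
                continue
            # maximality on the left
            if i > 0 and i + p <= n and s[i - 1] == s[i - 1 + p]:
                i += 1
                continue
            j = i + p
            while j < n and s[j] == s[j - p] != "N":
                j += 1
            run = j - i
            copies = run // p
            if copies >= need:
                motif = s[i : i + p]
                if is_primitive(motif):
                    raw.append(SSR(
                        motif=canonical_rotation(motif),
                        copies=copies,
                        interval=Interval(start=i + 1, end=i + copies * p),
                    ))
            i = max(i + 1, j - p + 1)
    raw.sort(key=lambda r: (r.interval.start, r.interval.end))
    # compound grouping
    out: list[SSR] = []
    group: int | None = None
    next_group = 1
    prev_end = None
    for idx, ssr in enumerate(raw):
        if prev_end is not None and ssr.interval.start - prev_end - 1 <= COMPOUND_GAP:
            if group is None:
                group = next_group
                next_group += 1
                out[-1] = SSR(out[-1].motif, out[-1].copies, out[-1].interval, group)
            out.append(SSR(ssr.motif, ssr.copies, ssr.interval, group))
        else:
            group = None
            out.append(ssr)
        prev_end = ssr.interval.end
    return out


def _true_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) half-open runs of True in a boolean array."""
    if mask.size == 0:
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def find_tandem_repeats(
    genome: Plastome,
    min_unit: int = 7,
    max_unit: int = 500,
    min_identity: float = 0.9,
    min_copies: float = 2.0,
) -> list[TandemRepeat]:
    """Approximate tandem arrays with unit length in (6, max_unit].

    Periodicity is detected from the per-period self-match profile
    (s[i] == s[i+p]); candidate regions are scored by aligning every copy
    against the column-majority consensus.
    """
    if min_unit <= 6:
        raise ValueError("min_unit must be > 6 (smaller units are SSRs)")
    s = genome.sequence
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    accepted: list[TandemRepeat] = []
    SEED_MIN = 8  # a real array has a clean self-match run at least this long

    for p in range(min_unit, min(max_unit, n // 2) + 1):
        eq = arr[: n - p] == arr[p:]
        if eq.size == 0:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        starts, ends = edges[0::2], edges[1::2]
        if starts.size == 0:
            continue
        lengths = ends - starts
        gap_tol = max(1, p // 10)
        regions: set[tuple[int, int]] = set()
        for ci in np.flatnonzero(lengths >= SEED_MIN):
            lo = hi = int(ci)
            while lo > 0 and starts[lo] - ends[lo - 1] <= gap_tol:
                lo -= 1
            while hi + 1 < starts.size and starts[hi + 1] - ends[hi] <= gap_tol:
                hi += 1
            regions.add((int(starts[lo]), int(ends[hi])))
        for seg_s, seg_e in sorted(regions):
            matched = seg_e - seg_s
            if matched + p < min_copies * p:
                continue
            region_s, region_e = seg_s, seg_e + p  # full array footprint
            span = region_e - region_s
            copies = span / p
            if copies < min_copies:
                continue
            rows = [s[region_s + c * p : region_s + (c + 1) * p]
                    for c in range(span // p)]
            consensus = "".join(
                max(set(col), key=lambda b: col.count(b))
                for col in zip(*rows)
            )
            if not is_primitive(consensus):
                continue
            if _min_period(consensus) <= 6:
                continue
            idents = [
                sum(a == b for a, b in zip(row, consensus)) / p for row in rows
            ]
            identity = sum(idents) / len(idents)
            if identity < min_identity or min(idents) < min_identity:
                continue
            iv = Interval(start=region_s + 1, end=region_e)
            if any(
                t.interval.overlap_len(iv) >= 0.5 * min(t.interval.span(), iv.span())
                for t in accepted
            ):
                continue  # harmonic of an already-accepted shorter unit
            accepted.append(TandemRepeat(
                unit_len=p,
                copies=round(copies, 2),
                consensus=consensus,
                interval=iv,
                percent_identity=round(identity, 4),
            ))
    accepted.sort(key=lambda t: (t.interval.start, t.unit_len))
    return accepted


def _min_period(seq: str) -> int:
    for d in range(1, len(seq) + 1):
        if all(seq[i] == seq[i % d] for i in range(len(seq))):
            return d
    return len(seq)


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------


def _maximal_windows(
    x: str, y: str, i0: int, j0: int, k: int, max_mm: int, min_len: int
) -> list[tuple[int, int, int]]:
    """Match-bounded <=max_mm-mismatch windows around the exact seed
    x[i0:i0+k] == y[j0:j0+k].

    A reported window starts and ends on matching bases and contains at
    most ``max_mm`` interior substitutions; raw windows (bounded by the
    budget-exceeding mismatch on each side) are trimmed to their outermost
    matches. Containment between windows is filtered by the caller.
    Returns (x_start, length, mismatches) tuples.
    """

    def is_mm(off: int) -> bool:
        a, b = x[i0 + off], y[j0 + off]
        return a != b or a == "N"

    # blocking positions outward of the seed: true mismatches, then (when the
    # budget is not exhausted first) a sentinel just past the sequence end
    left_mm: list[int] = []  # offsets < 0, closest first
    off = -1
    while i0 + off >= 0 and j0 + off >= 0 and len(left_mm) <= max_mm:
        if is_mm(off):
            left_mm.append(off)
        off -= 1
    lb = left_mm + ([off] if len(left_mm) <= max_mm else [])
    right_mm: list[int] = []
    off = k
    while i0 + off < len(x) and j0 + off < len(y) and len(right_mm) <= max_mm:
        if is_mm(off):
            right_mm.append(off)
        off += 1
    rb = right_mm + ([off] if len(right_mm) <= max_mm else [])

    out = []
    for nl in range(min(len(lb), max_mm + 1)):
        nr = min(max_mm - nl, len(rb) - 1)
        lo = lb[nl] + 1
        hi = rb[nr] - 1
        mm = nl + min(nr, len(right_mm))
        # trim to the outermost matches
        while lo <= hi and is_mm(lo):
            lo += 1
            mm -= 1
        while hi >= lo and is_mm(hi):
            hi -= 1
            mm -= 1
        length = hi - lo + 1
        if length >= min_len:
            out.append((i0 + lo, length, mm))
    return out


def find_dispersed_repeats(
    genome: Plastome,
    min_len: int = 30,
    max_mismatch: int = 3,
    exclude_ir: bool = True,
    layout: QuadripartiteLayout | None = None,
) -> list[DispersedRepeat]:
    """All maximal pairs of equal-length segments >= min_len matching in
    forward or palindromic orientation with <= max_mismatch substitutions.

    With ``exclude_ir``, pairs lying inside the two IR copies (the IR
    duplication itself) are suppressed: the quadripartite layout reports
    that structure once, rather than as a flood of trivial pairs.
    """
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    s = genome.sequence
    n = len(s)
    # pigeonhole: a min_len window with <= max_mismatch substitutions always
    # contains a clean run of ceil((min_len - max_mismatch)/(max_mismatch+1))
    k = max(4, -(-(min_len - max_mismatch) // (max_mismatch + 1)))
    k = min(k, min_len)
    results: set[tuple[str, int, int, int, int]] = set()

    def harvest(x: str, y: str, pairs, orientation: str) -> None:
        by_diag: dict[int, dict[int, tuple[int, int]]] = {}
        pairs.sort(key=lambda ij: (ij[1] - ij[0], ij[0]))
        run_diag, run_lo, run_hi = None, 0, -1
        for i0, j0 in pairs:
            diag = j0 - i0
            # seeds inside one clean (mismatch-free) run share identical
            # blocker context and would enumerate identical windows
            if diag == run_diag and run_lo <= i0 and i0 + k <= run_hi:
                continue
            windows = by_diag.setdefault(diag, {})
            for xs, length, mm in _maximal_windows(x, y, i0, j0, k, max_mismatch, min_len):
                prev = windows.get(xs)
                if prev is None or length > prev[0]:
                    windows[xs] = (length, mm)
            lo = i0
            while lo - 1 >= 0 and lo - 1 + diag >= 0 \
                    and x[lo - 1] == y[lo - 1 + diag] != "N":
                lo -= 1
            hi = i0 + k
            while hi < len(x) and hi + diag < len(y) \
                    and x[hi] == y[hi + diag] != "N":
                hi += 1
            run_diag, run_lo, run_hi = diag, lo, hi
        for diag, windows in by_diag.items():
            # drop windows contained in a longer window on the same diagonal
            items = sorted(windows.items())
            kept: list[tuple[int, int, int]] = []
            for xs, (length, mm) in items:
                if any(ks <= xs and xs + length <= ks + kl for ks, kl, _ in kept):
                    continue
                kept = [w for w in kept
                        if not (xs <= w[0] and w[0] + w[1] <= xs + length)]
                kept.append((xs, length, mm))
            for xs, length, mm in kept:
                ys = xs + diag
                if orientation == "forward":
                    a0, b0 = xs, ys
                else:
                    # y is revcomp(s): y[ys:ys+L] == revcomp(s[n-ys-L:n-ys])
                    a0, b0 = xs, n - ys - length
                if a0 == b0:
                    continue
                lo, hi = sorted((a0, b0))
                results.add((orientation, lo, hi, length, mm))

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        word = s[i : i + k]
        if "N" not in word:
            index.setdefault(word, []).append(i)

    fwd_pairs = []
    for positions in index.values():
        if len(positions) > 200:
            logger.warning("highly repetitive %d-mer skipped in dispersed scan", k)
            continue
        for a_i in range(len(positions)):
            for b_i in range(a_i + 1, len(positions)):
                fwd_pairs.append((positions[a_i], positions[b_i]))
    harvest(s, s, fwd_pairs, "forward")

    r = revcomp(s)
    pal_pairs = []
    for j in range(n - k + 1):
        word = r[j : j + k]
        for i in index.get(word, ()):
            pal_pairs.append((i, j))
    harvest(s, r, pal_pairs, "palindromic")

    if exclude_ir:
        if layout is None:
            from plastann.genome_model import detect_inverted_repeats

            layout = detect_inverted_repeats(genome)
        if layout is not None:
            def in_iv(p0: int, length: int, iv: Interval) -> bool:
                if iv.wraps_origin:
                    return False
                ov = min(p0 + length, iv.end) - max(p0, iv.start - 1)
                return ov >= 0.9 * length

            results = {
                rec for rec in results
                if not (
                    rec[0] == "palindromic"
                    and (
                        (in_iv(rec[1], rec[3], layout.ira) and in_iv(rec[2], rec[3], layout.irb))
                        or (in_iv(rec[1], rec[3], layout.irb) and in_iv(rec[2], rec[3], layout.ira))
                    )
                )
            }

    out = [
        DispersedRepeat(
            interval_a=Interval(start=a0 + 1, end=a0 + length),
            interval_b=Interval(start=b0 + 1, end=b0 + length),
            orientation=orientation,
            length=length,
            mismatches=mm,
        )
        for orientation, a0, b0, length, mm in sorted(results)
    ]
    return out


# ---------------------------------------------------------------------------
# TSV writers (1-based inclusive coordinates)
# ---------------------------------------------------------------------------


def write_ssr_tsv(ssrs: list[SSR], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tcopies\tstart\tend\tcompound_id\n")
        for r in ssrs:
            cid = r.compound_id if r.compound_id is not None else ""
            fh.write(f"{r.motif}\t{r.copies}\t{r.interval.start}\t{r.interval.end}\t{cid}\n")


def write_tandem_tsv(repeats: list[TandemRepeat], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("unit_len\tcopies\tstart\tend\tpercent_identity\tconsensus\n")
        for r in repeats:
            fh.write(
                f"{r.unit_len}\t{r.copies}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.percent_identity}\t{r.consensus}\n"
            )


def write_dispersed_tsv(repeats: list[DispersedRepeat], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("orientation\tstart_a\tend_a\tstart_b\tend_b\tlength\tmismatches\n")
        for r in repeats:
            fh.write(
                f"{r.orientation}\t{r.interval_a.start}\t{r.interval_a.end}"
                f"\t{r.interval_b.start}\t{r.interval_b.end}\t{r.length}\t{r.mismatches}\n"
            )
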