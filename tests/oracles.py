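"""Independent brute-force enumerators used as oracles for the repeat
finders. These re-derive the documented repeat definitions directly from
the sequence, sharing no code with the production finders."""

from __future__ import annotations

import numpy as np


def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """All maximal perfect runs of primitive 1-6 bp units meeting their
    thresholds, as (canonical_motif, copies, start_1based, end_1based)."""
    n = len(seq)
    out = set()
    for p, need in thresholds.items():
        for i in range(n - p + 1):
            motif = seq[i : i + p]
            if "N" in motif:
                continue
            # primitive: no proper divisor period
            if any(p % d == 0 and motif == motif[:d] * (p // d)
                   for d in range(1, p)):
                continue
            # maximal start: the run must not continue one base to the left
            if i >= 1 and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                continue
            copies = 1
            while seq[i + copies * p : i + (copies + 1) * p] == motif:
                copies += 1
            if copies >= need:
                canon = min(motif[r:] + motif[:r] for r in range(p))
                out.add((canon, copies, i + 1, i + copies * p))
    return out


def brute_tandems(
    seq: str,
    min_unit: int = 7,
    max_unit: int = 40,
    min_identity: float = 0.9,
    min_copies: float = 2.0,
) -> set[tuple]:
    """Approximate tandem arrays as (unit_len, copies, consensus,
    start_1based, end_1based, identity), derived by direct per-period
    scanning in pure Python."""
    n = len(seq)
    out = set()
    accepted_intervals: list[tuple[int, int]] = []
    for p in range(min_unit, max_unit + 1):
        if 2 * p > n:
            break
        eq = [seq[i] == seq[i + p] for i in range(n - p)]
        gap_tol = max(1, p // 10)
        # runs of True
        runs = []
        i = 0
        while i < len(eq):
            if eq[i]:
                j = i
                while j < len(eq) and eq[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        # candidate regions: merge around any run >= 8
        regions = set()
        for ri, (rs, re_) in enumerate(runs):
            if re_ - rs < 8:
                continue
            lo = hi = ri
            while lo > 0 and runs[lo][0] - runs[lo - 1][1] <= gap_tol:
                lo -= 1
            while hi + 1 < len(runs) and runs[hi + 1][0] - runs[hi][1] <= gap_tol:
                hi += 1
            regions.add((runs[lo][0], runs[hi][1]))
        for rs, re_ in sorted(regions):
            span = re_ - rs + p
            copies = span / p
            if copies < min_copies:
                continue
            rows = [seq[rs + c * p : rs + (c + 1) * p] for c in range(span // p)]
            consensus = "".join(
                max(set(col), key=lambda b: col.count(b)) for col in zip(*rows)
            )
            # consensus must be primitive with period > 6
            periods = [d for d in range(1, p + 1)
                       if all(consensus[k] == consensus[k % d]
                              for k in range(p))]
            if min(periods) != p or p <= 6:
                continue
            idents = [sum(a == b for a, b in zip(r, consensus)) / p
                      for r in rows]
            if min(idents) < min_identity or sum(idents) / len(idents) < min_identity:
                continue
            iv = (rs + 1, rs + span)
            if any(min(iv[1], b) - max(iv[0], a) + 1
                   >= 0.5 * min(iv[1] - iv[0] + 1, b - a + 1)
                   for a, b in accepted_intervals):
                continue
            accepted_intervals.append(iv)
            out.add((p, round(copies, 2), consensus, iv[0], iv[1],
                     round(sum(idents) / len(idents), 4)))
    return out


def _diag_windows(mm: np.ndarray, length: int, max_mm: int, min_len: int):
    """Match-bounded, containment-maximal <=max_mm windows on one diagonal.

    mm: sorted mismatch positions in [0, length). Yields (lo, hi, n_mm).
    """
    aug = np.concatenate(([-1], mm, [length]))
    mm_set = set(int(v) for v in mm)
    k = max_mm + 1
    # vectorized candidate selection (raw window length >= min_len); the
    # trimmed window is never longer than the raw one, so nothing is missed
    cand: list[tuple[int, int]] = []
    if len(aug) - 1 > k:
        spans = aug[k:] - aug[:-k] - 1
        for i in np.flatnonzero(spans >= min_len):
            cand.append((int(i), int(i) + k))
        tail_start = len(aug) - k
        tail = np.arange(max(0, tail_start), len(aug) - 1)
        ok = length - aug[tail] - 1 >= min_len
        for i in tail[ok]:
            cand.append((int(i), len(aug) - 1))
    else:
        for i in range(len(aug) - 1):
            if length - int(aug[i]) - 1 >= min_len:
                cand.append((i, len(aug) - 1))
    raw = []
    for i, j in cand:
        lo, hi = int(aug[i]) + 1, int(aug[j]) - 1
        while lo <= hi and lo in mm_set:
            lo += 1
        while hi >= lo and hi in mm_set:
            hi -= 1
        if hi - lo + 1 >= min_len:
            raw.append((lo, hi))
    kept = []
    for lo, hi in sorted(set(raw)):
        if any(a <= lo and hi <= b for a, b in kept):
            continue
        kept = [(a, b) for a, b in kept if not (lo <= a and b <= hi)]
        kept.append((lo, hi))
    for lo, hi in kept:
        yield lo, hi, sum(1 for v in mm_set if lo <= v <= hi)


def brute_dispersed(
    seq: str, min_len: int = 30, max_mm: int = 3
) -> set[tuple]:
    """All maximal dispersed pairs as (orientation, a0_1based, b0_1based,
    length, mismatches), by exhaustive per-diagonal comparison."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(
        seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1].encode(),
        dtype=np.uint8,
    )
    out = set()
    for d in range(1, n):
        a, b = arr[: n - d], arr[d:]
        if a.size < min_len:
            break
        mm = np.flatnonzero(a != b)
        for lo, hi, nmm in _diag_windows(mm, a.size, max_mm, min_len):
            out.add(("forward", lo + 1, lo + d + 1, hi - lo + 1, nmm))
    for d in range(-(n - min_len), n - min_len + 1):
        # align arr[i] with rc[i + d]
        i0 = max(0, -d)
        i1 = min(n, n - d)
        if i1 - i0 < min_len:
            continue
        a = arr[i0:i1]
        b = rc[i0 + d : i1 + d]
        mm = np.flatnonzero(a != b)
        for lo, hi, nmm in _diag_windows(mm, a.size, max_mm, min_len):
            length = hi - lo + 1
            x0 = i0 + lo  # position in seq
            y0 = i0 + lo + d  # position in rc
            b0 = n - y0 - length  # back to seq coordinates
            if x0 == b0:
                continue
            p, q = sorted((x0, b0))
            out.add(("palindromic", p + 1, q + 1, length, nmm))
    return out
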