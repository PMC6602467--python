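import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastann.genome_model import Plastome, revcomp
from plastann.repeats import (
    DEFAULT_SSR_MIN_COPIES,
    canonical_rotation,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    is_primitive,
)
from tests.oracles import brute_dispersed, brute_ssrs, brute_tandems


def _clean_seq(seed: int, length: int) -> str:
    """Random sequence without homopolymers > 3 (keeps SSR noise out)."""
    rng = random.Random(seed)
    chars: list[str] = []
    while len(chars) < length:
        b = rng.choice("ACGT")
        if len(chars) >= 3 and all(c == b for c in chars[-3:]):
            continue
        chars.append(b)
    return "".join(chars)


def _embed(host: str, pos: int, insert: str) -> Plastome:
    return Plastome(id="t", sequence=host[:pos] + insert + host[pos:],
                    circular=False)


class TestSSR:
    def test_mono_run_reported(self):
        g = _embed(_clean_seq(1, 2000), 500, "C" + "A" * 12 + "C")
        ssrs = [r for r in find_ssrs(g) if r.motif == "A"]
        assert len(ssrs) == 1
        assert ssrs[0].copies == 12
        assert ssrs[0].interval.span() == 12

    def test_dinucleotide_canonical_not_decomposed(self):
        g = _embed(_clean_seq(2, 2000), 700, "C" + "AT" * 6 + "C")
        ssrs = find_ssrs(g)
        at = [r for r in ssrs if len(r.motif) == 2]
        assert len(at) == 1
        assert at[0].motif == "AT"  # canonical rotation, not "TA"
        assert not [r for r in ssrs if r.motif in ("A", "T")]

    def test_below_threshold_not_reported(self):
        g = _embed(_clean_seq(3, 2000), 700, "C" + "AT" * 5 + "C")
        assert not [r for r in find_ssrs(g) if r.motif == "AT"]

    def test_copies_times_unit_equals_span(self, truth7):
        for r in find_ssrs(truth7.ref_genome):
            assert r.copies * len(r.motif) == r.interval.span()
            assert is_primitive(r.motif)
            assert r.motif == canonical_rotation(r.motif)

    def test_matches_planted_roster(self, truth7):
        assert find_ssrs(truth7.ref_genome) == truth7.ssrs

    def test_brute_force_equivalence(self, truth7):
        seq = truth7.ref_genome.sequence[:18000]  # LSC: all planted repeats
        got = {
            (r.motif, r.copies, r.interval.start, r.interval.end)
            for r in find_ssrs(Plastome(id="o", sequence=seq, circular=False))
        }
        assert got == brute_ssrs(seq, DEFAULT_SSR_MIN_COPIES)

    def test_compound_id_for_nearby_runs(self):
        host = _clean_seq(4, 1500)
        insert = "C" + "A" * 12 + "G" + _clean_seq(5, 40) + "C" + "AT" * 6 + "G"
        g = _embed(host, 600, insert)
        ssrs = [r for r in find_ssrs(g) if r.motif in ("A", "AT")]
        assert len(ssrs) == 2
        assert ssrs[0].compound_id is not None
        assert ssrs[0].compound_id == ssrs[1].compound_id


@given(st.text(alphabet="ACGT", min_size=1, max_size=6),
       st.integers(min_value=0, max_value=5))
def test_canonical_rotation_invariance(motif, shift):
    rotated = motif[shift % len(motif):] + motif[: shift % len(motif)]
    assert canonical_rotation(rotated) == canonical_rotation(motif)


class TestTandem:
    def test_exact_array(self):
        from plastann.fixtures import _walled

        rng = random.Random(10)
        unit = "ACGTTGCAGGATCCATTGACTTAGCCAGAT"
        host = _clean_seq(10, 3000)
        g = _embed(host, 1200, _walled(rng, unit * 4, 30))
        found = [t for t in find_tandem_repeats(g) if t.unit_len == 30]
        assert len(found) == 1
        t = found[0]
        assert t.copies == 4.0
        assert t.percent_identity == 1.0
        assert t.consensus == unit
        assert t.interval.span() == 120

    def test_mutated_copy_detected_with_lower_identity(self):
        from plastann.fixtures import _walled

        rng = random.Random(11)
        unit = _clean_seq(12, 30)
        arr = list(unit * 4)
        for pos in (40, 50):  # two point mutations in copy 2
            arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
        g = _embed(_clean_seq(13, 3000), 1500, _walled(rng, "".join(arr), 30))
        found = [t for t in find_tandem_repeats(g) if t.unit_len == 30]
        assert len(found) == 1
        assert found[0].percent_identity < 1.0
        # oracle: align each copy to the planted unit
        worst = min(
            sum(a == b for a, b in zip("".join(arr)[c * 30 : (c + 1) * 30], unit)) / 30
            for c in range(4)
        )
        assert worst == 28 / 30
        assert min(
            sum(a == b for a, b in zip("".join(arr)[c * 30 : (c + 1) * 30],
                                       found[0].consensus)) / 30
            for c in range(4)
        ) >= 0.9

    def test_ssr_region_not_reported_as_tandem(self):
        g = _embed(_clean_seq(14, 2000), 900, "C" + "AG" * 20 + "C")
        assert find_tandem_repeats(g) == []
        assert [r for r in find_ssrs(g) if r.motif == "AG"]

    def test_matches_planted_roster(self, truth7):
        assert find_tandem_repeats(truth7.ref_genome) == truth7.tandems

    def test_brute_force_equivalence(self, truth7):
        seq = truth7.ref_genome.sequence[:18000]
        finder = find_tandem_repeats(
            Plastome(id="o", sequence=seq, circular=False), max_unit=40
        )
        got = {
            (t.unit_len, t.copies, t.consensus, t.interval.start,
             t.interval.end, t.percent_identity)
            for t in finder
        }
        assert got == brute_tandems(seq, max_unit=40)

    def test_no_interval_shared_across_6bp_boundary(self, truth7):
        ssr_ivs = {(r.interval.start, r.interval.end)
                   for r in find_ssrs(truth7.ref_genome)}
        tandem_ivs = {(t.interval.start, t.interval.end)
                      for t in find_tandem_repeats(truth7.ref_genome)}
        assert not ssr_ivs & tandem_ivs


def _plant_pair(seed: int, seg_len: int, n_sub: int, palindromic: bool):
    """Host with two planted copies behind mismatch walls; returns
    (genome, a0, b0) with 0-based copy starts."""
    rng = random.Random(f"pair:{seed}")
    host = _clean_seq(seed + 100, 4000)
    seg = _clean_seq(seed + 200, seg_len)
    copy_b = list(seg)
    for pos in rng.sample(range(5, seg_len - 5), n_sub):
        copy_b[pos] = rng.choice([b for b in "ACGT" if b != copy_b[pos]])
    copy_b = "".join(copy_b)
    if palindromic:
        copy_b = revcomp(copy_b)
    wall = lambda ref: "".join(  # noqa: E731
        rng.choice([b for b in "ACGT" if b != c]) for c in ref
    )
    a_l, a_r = _clean_seq(seed + 300, 4), _clean_seq(seed + 400, 4)
    if palindromic:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        b_l = wall("".join(comp[c] for c in a_r[::-1]))
        b_r = wall("".join(comp[c] for c in a_l[::-1]))
    else:
        b_l, b_r = wall(a_l), wall(a_r)
    blk_a = a_l + seg + a_r
    blk_b = b_l + copy_b + b_r
    a0 = 500 + 4
    b0 = 500 + len(blk_a) + 2000 + 4
    seq = host[:500] + blk_a + host[500:2500] + blk_b + host[2500:]
    return Plastome(id="p", sequence=seq, circular=False), a0, b0


class TestDispersed:
    def test_exact_forward_pair(self):
        g, a0, b0 = _plant_pair(1, 40, 0, palindromic=False)
        pairs = find_dispersed_repeats(g, exclude_ir=False)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.orientation == "forward"
        assert (p.interval_a.start, p.interval_b.start) == (a0 + 1, b0 + 1)
        assert p.length == 40 and p.mismatches == 0

    def test_exact_palindromic_pair(self):
        g, a0, b0 = _plant_pair(2, 35, 0, palindromic=True)
        pairs = find_dispersed_repeats(g, exclude_ir=False)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.orientation == "palindromic"
        seq_a = g.sequence[p.interval_a.start - 1 : p.interval_a.end]
        seq_b = g.sequence[p.interval_b.start - 1 : p.interval_b.end]
        assert seq_a == revcomp(seq_b)

    def test_two_substitutions_reported(self):
        g, a0, b0 = _plant_pair(3, 40, 2, palindromic=False)
        pairs = find_dispersed_repeats(g, max_mismatch=3, exclude_ir=False)
        assert len(pairs) == 1
        assert pairs[0].mismatches == 2
        assert pairs[0].length == 40

    def test_matches_planted_roster(self, truth7):
        found = find_dispersed_repeats(truth7.ref_genome, layout=truth7.layout)
        key = lambda r: (r.orientation, r.interval_a.start,  # noqa: E731
                         r.interval_b.start, r.length)
        assert sorted(found, key=key) == sorted(truth7.dispersed, key=key)

    def test_brute_force_equivalence(self, truth7):
        # the full-LSC equivalence run lives in the acceptance suite; a
        # 6 kb slice keeps this unit test quick
        seq = truth7.ref_genome.sequence[:6000]
        finder = find_dispersed_repeats(
            Plastome(id="o", sequence=seq, circular=False), exclude_ir=False
        )
        got = {
            (r.orientation, r.interval_a.start, r.interval_b.start,
             r.length, r.mismatches)
            for r in finder
        }
        assert got == brute_dispersed(seq)

    def test_ir_pair_suppressed_by_default(self, truth7):
        with_ir = find_dispersed_repeats(truth7.ref_genome, exclude_ir=False)
        without = find_dispersed_repeats(truth7.ref_genome,
                                         layout=truth7.layout)
        big = [r for r in with_ir if r.length >= 5000]
        assert big and big[0].orientation == "palindromic"
        assert not [r for r in without if r.length >= 5000]

    def test_min_len_precondition(self, truth7):
        with pytest.raises(ValueError):
            find_dispersed_repeats(truth7.ref_genome, min_len=10)
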