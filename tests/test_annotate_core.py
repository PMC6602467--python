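import itertools
import random

import pytest
from Bio import Align

from plastann.annotate_core import (
    HSP,
    _best_chain,
    chain_hsps,
    refine_gene_model,
    similarity_search,
)
from plastann.genome_model import Interval, Plastome, revcomp
from plastann.reference_db import ReferenceGene, RefExon
from tests.conftest import random_genome


def _mk_ref(name: str, exon_seqs: list[str], kind: str = "CDS") -> ReferenceGene:
    exons = []
    pos = 1
    for i, seq in enumerate(exon_seqs, start=1):
        exons.append(RefExon(
            ordinal=i, seq=seq,
            interval=Interval(start=pos, end=pos + len(seq) - 1), strand="+",
        ))
        pos += len(seq)
    return ReferenceGene(name=name, kind=kind, exons=exons, source_accession="t")


class TestSimilaritySearch:
    def test_exact_substring_identity(self):
        g = random_genome(1, 6000)
        query = g.sequence[1000:1060]
        hits = similarity_search(query, g)
        top = hits[0]
        assert top.identity == 1.0
        assert (top.t_interval.start, top.t_interval.end) == (1001, 1060)
        assert top.strand == "+"

    def test_revcomp_query_minus_strand(self):
        g = random_genome(2, 6000)
        query = revcomp(g.sequence[2000:2080])
        top = similarity_search(query, g)[0]
        assert top.strand == "-"
        assert (top.t_interval.start, top.t_interval.end) == (2001, 2080)

    def test_one_mismatch_identity_vs_smith_waterman_oracle(self):
        g = random_genome(3, 6000)
        query = list(g.sequence[3000:3056])
        orig = query[25]
        query[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
        query = "".join(query)
        top = similarity_search(query, g, min_evalue=1e-10)[0]
        assert top.identity == pytest.approx(55 / 56)
        # independent oracle: ungapped Smith-Waterman via Bio.Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -10_000
        aligner.extend_gap_score = -10_000
        assert top.score == aligner.score(g.sequence, query)

    def test_invalid_alphabet_raises(self):
        g = random_genome(4, 1000)
        with pytest.raises(ValueError):
            similarity_search("ACGTU" * 4, g)

    def test_translated_mode_finds_protein(self):
        from plastann.genome_model import translate_cds

        g = random_genome(6, 4000)
        cds = g.sequence[500:1400]
        protein = translate_cds(cds).protein.replace("*", "W")
        hits = similarity_search(protein[:100], g, mode="translated",
                                 min_evalue=1e-5)
        assert hits
        top = hits[0]
        assert top.strand == "+"
        assert top.t_interval.start == 501

    def test_sorted_by_score(self):
        g = random_genome(7, 6000)
        q = g.sequence[100:400]
        hits = similarity_search(q, g)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)


def _hsp(q0, q1, t0, t1, score, strand="+"):
    return HSP(query_gene="g", q0=q0, q1=q1, t0=t0, t1=t1, strand=strand,
               score=score, identity=1.0, evalue=1e-30, genome_length=100000)


def _valid_chain(seq, max_intron):
    """Independent statement of the chaining rule for the brute oracle."""
    for a, b in zip(seq, seq[1:]):
        if a.strand != b.strand:
            return False
        if not (b.q0 > a.q0 and b.q1 > a.q1):
            return False
        if a.q1 - b.q0 > 0.5 * min(a.q1 - a.q0, b.q1 - b.q0):
            return False
        if a.strand == "+":
            if not (b.t0 > a.t0 and b.t1 > a.t1):
                return False
            if a.t1 - b.t0 > 0.5 * min(a.t1 - a.t0, b.t1 - b.t0):
                return False
            if b.t0 - a.t1 > max_intron:
                return False
        else:
            if not (b.t0 < a.t0 and b.t1 < a.t1):
                return False
            if b.t1 - a.t0 > 0.5 * min(a.t1 - a.t0, b.t1 - b.t0):
                return False
            if a.t0 - b.t1 > max_intron:
                return False
    return True


class TestChaining:
    def test_two_colinear_hsps_one_chain(self):
        hsps = [_hsp(0, 100, 1000, 1100, 200), _hsp(100, 200, 1900, 2000, 200)]
        chains = chain_hsps(hsps, max_intron=2000)
        assert len(chains) == 1
        assert len(chains[0].hsps) == 2

    def test_query_overlap_drops_weaker(self):
        hsps = [_hsp(0, 100, 1000, 1100, 200), _hsp(20, 110, 5000, 5090, 150)]
        chains = chain_hsps(hsps, max_intron=2000)
        assert [h.score for h in chains[0].hsps] == [200]

    def test_gap_beyond_max_intron_splits(self):
        hsps = [_hsp(0, 100, 1000, 1100, 200), _hsp(100, 200, 6100, 6200, 150)]
        chains = chain_hsps(hsps, max_intron=2000)
        assert len(chains) == 2
        assert all(len(c.hsps) == 1 for c in chains)

    @pytest.mark.parametrize("seed", range(6))
    def test_chain_optimality_vs_brute_force(self, seed):
        rng = random.Random(seed)
        hsps = []
        for _ in range(rng.randint(4, 9)):
            q0 = rng.randrange(0, 500)
            q1 = q0 + rng.randrange(30, 200)
            t0 = rng.randrange(0, 5000)
            hsps.append(_hsp(q0, q1, t0, t0 + (q1 - q0),
                             score=rng.randrange(10, 300)))
        max_intron = 2000
        best = 0.0
        order = sorted(hsps, key=lambda h: (h.q0, h.q1))
        for r in range(1, len(order) + 1):
            for combo in itertools.combinations(order, r):
                if _valid_chain(combo, max_intron):
                    best = max(best, sum(h.score for h in combo))
        chain = _best_chain(hsps, max_intron)
        assert sum(h.score for h in chain) == best


def _search_chain(query, genome, max_intron=2000):
    hsps = similarity_search(query, genome, min_evalue=1e-6)
    chains = chain_hsps(hsps, max_intron)
    assert chains
    return chains[0]


class TestRefine:
    def test_start_extended_to_planted_atg(self):
        rng = random.Random(10)
        filler = lambda k: "".join(rng.choice("ACGT") for _ in range(k))  # noqa: E731
        cds = "ATG" + "CAC" * 60 + "TAA"
        genome = Plastome(id="g", sequence=filler(800) + cds + filler(800),
                          circular=False)
        # reference missing the first 9 bases: mapped start sits 9 bp
        # downstream of the true ATG
        ref = _mk_ref("geneX", [cds[9:]])
        chain = _search_chain(cds[9:], genome)
        model = refine_gene_model(chain, genome, ref)
        assert model.exons[0].interval.start == 801
        assert not model.partial_5p
        assert model.spliced_seq(genome).startswith("ATG")

    def test_boundary_overshoot_snapped_to_reference_phase(self):
        # the alignment footprint runs 19 bp past the true exon end because
        # the intron begins with a copy of the next 19 query bases; the
        # reference phase pulls the boundary back
        rng = random.Random(11)
        filler = lambda k: "".join(rng.choice("ACGT") for _ in range(k))  # noqa: E731
        e1 = "ATG" + "".join(rng.choice("ACG") for _ in range(117))
        e2_body = filler(147)
        e2 = e2_body + "TAA"
        intron = e2[:19] + filler(300)
        genome = Plastome(
            id="g", sequence=filler(500) + e1 + intron + e2 + filler(500),
            circular=False,
        )
        ref = _mk_ref("geneY", [e1, e2])
        chain = _search_chain(e1 + e2, genome)
        model = refine_gene_model(chain, genome, ref)
        n = genome.length
        assert [e.interval.span(n) for e in model.exons] == [120, 150]
        assert model.exons[0].interval == Interval(start=501, end=620)
        assert model.spliced_seq(genome) == e1 + e2

    def test_missing_stop_sets_partial_3p(self):
        rng = random.Random(12)
        filler = lambda k: "".join(rng.choice("ACGT") for _ in range(k))  # noqa: E731
        cds = "ATG" + "CAC" * 50 + "TAA"
        truncated = cds[:-30]
        genome = Plastome(id="g", sequence=filler(600) + truncated,
                          circular=False)
        ref = _mk_ref("geneZ", [cds])
        chain = _search_chain(truncated, genome)
        model = refine_gene_model(chain, genome, ref)
        assert model.partial_3p


class TestAnnotateGenome:
    def test_self_annotation_identity(self, truth7, annotation7):
        truth_keys = {m.key() for m in truth7.annotation.models
                      if m.kind in ("CDS", "rRNA")}
        assert annotation7.keys() == truth_keys

    def test_ir_gene_reported_twice(self, annotation7):
        for rrna in ("rrn16", "rrn23", "rrn4.5", "rrn5"):
            copies = annotation7.by_name(rrna)
            assert len(copies) == 2
            assert {m.copy for m in copies} == {1, 2}
            strands = {m.strand for m in copies}
            assert strands == {"+", "-"}

    def test_overlapping_genes_both_reported(self, annotation7, truth7):
        a = annotation7.by_name("psbD")
        b = annotation7.by_name("psbB")
        assert len(a) == 1 and len(b) == 1
        ov = a[0].exons[0].interval.overlap_len(b[0].exons[0].interval)
        assert ov == 18
        assert a[0].strand != b[0].strand

    def test_complete_cds_models_translate(self, annotation7, truth7):
        from plastann.genome_model import translate_cds

        for m in annotation7.models:
            if m.kind != "CDS" or m.partial_5p or m.partial_3p:
                continue
            cds = m.spliced_seq(truth7.genome)
            tr = translate_cds(cds)
            assert not tr.internal_stop or any(
                "internal stop" in note for note in m.notes
            )

    def test_robustness_2pct_mutations(self, truth7, db7):
        from plastann.annotate_core import annotate_genome

        rng = random.Random(42)
        seq = list(truth7.ref_genome.sequence)
        for i in range(len(seq)):
            if rng.random() < 0.02:
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        mutated = Plastome(id="mut", sequence="".join(seq))
        ann = annotate_genome(mutated, db7)
        expected = {}
        for m in truth7.annotation.models:
            if m.kind in ("CDS", "rRNA"):
                expected[m.name] = len(m.exons)
        recovered = 0
        for name, n_exons in expected.items():
            models = ann.by_name(name)
            if any(len(m.exons) == n_exons for m in models):
                recovered += 1
        assert recovered / len(expected) >= 0.95
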