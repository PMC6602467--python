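import random

import pytest

from plastann.annotate_core import AnnotationSet, GeneModel
from plastann.diversity import (
    PileupColumn,
    build_pileup,
    call_editing_sites,
    call_snps,
    prefilter_reads,
)
from plastann.fixtures import simulate_reads
from plastann.genome_model import Exon, Interval, Plastome


def _sam(tmp_path, genome, rows):
    p = tmp_path / "reads.sam"
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{genome.id}\tLN:{genome.length}"]
    for i, (flag, pos, cigar, seq, mapq) in enumerate(rows):
        qual = "I" * len(seq)
        lines.append(f"r{i}\t{flag}\t{genome.id}\t{pos}\t{mapq}\t{cigar}"
                     f"\t*\t0\t0\t{seq}\t{qual}")
    p.write_text("\n".join(lines) + "\n")
    return str(p)


@pytest.fixture
def small_genome():
    rng = random.Random(77)
    return Plastome(id="g", sequence="".join(rng.choice("ACGT")
                                             for _ in range(400)),
                    circular=False)


class TestBuildPileup:
    def test_ten_identical_reads(self, tmp_path, small_genome):
        g = small_genome
        read = g.sequence[49:99]
        sam = _sam(tmp_path, g, [(0, 50, "50M", read, 60)] * 10)
        pile = build_pileup(sam, g)
        col = next(c for c in pile if c.position == 60)
        assert col.depth == 10
        assert col.base_count(col.ref_base) == 10

    def test_deletion_leaves_gap(self, tmp_path, small_genome):
        g = small_genome
        seq = g.sequence[49:69] + g.sequence[71:101]
        sam = _sam(tmp_path, g, [(0, 50, "20M2D30M", seq, 60)] * 5)
        pile = build_pileup(sam, g)
        by_pos = {c.position: c for c in pile}
        assert 70 not in by_pos and 71 not in by_pos
        assert by_pos[69].depth == 5 and by_pos[72].depth == 5

    def test_low_mapq_and_flags_skipped(self, tmp_path, small_genome):
        g = small_genome
        read = g.sequence[9:59]
        rows = [
            (0, 10, "50M", read, 5),     # low mapq
            (4, 10, "50M", read, 60),    # unmapped
            (256, 10, "50M", read, 60),  # secondary
            (1024, 10, "50M", read, 60),  # duplicate
            (0, 10, "50M", read, 60),
        ]
        pile = build_pileup(_sam(tmp_path, g, rows), g)
        assert {c.depth for c in pile} == {1}

    def test_strand_split_matches_simulation(self, truth7, tmp_path):
        sam, _ = simulate_reads(truth7, "dna", depth=20, read_len=100,
                                seed=3, out_prefix=str(tmp_path / "r"))
        pile = build_pileup(sam, truth7.genome)
        fwd = sum(f for c in pile for (f, r) in c.counts.values())
        rev = sum(r for c in pile for (f, r) in c.counts.values())
        total = fwd + rev
        assert abs(fwd / total - 0.5) < 0.05  # simulator plants ~50/50

    def test_reference_mismatch_raises(self, tmp_path, small_genome):
        other = Plastome(id="other", sequence=small_genome.sequence,
                         circular=False)
        sam = _sam(tmp_path, small_genome,
                   [(0, 10, "50M", small_genome.sequence[9:59], 60)])
        with pytest.raises(ValueError):
            build_pileup(sam, other)


def _col(position, ref, **base_counts):
    return PileupColumn(position=position, ref_base=ref,
                        counts={b: tuple(v) for b, v in base_counts.items()})


class TestCallSnps:
    def test_pass_call(self):
        col = _col(10, "A", A=[40, 40], G=[10, 10])
        calls = call_snps([col])
        assert len(calls) == 1
        c = calls[0]
        assert (c.alt_base, c.filter) == ("G", "PASS")
        assert c.alt_fraction == pytest.approx(0.20)

    def test_min_alt_count(self):
        col = _col(10, "A", A=[49, 49], G=[1, 1])
        assert call_snps([col]) == []

    def test_low_depth_filter(self):
        col = _col(10, "A", A=[3, 2], G=[2, 1])
        calls = call_snps([col])
        assert calls[0].filter == "low_depth"

    def test_strand_bias_filter(self):
        col = _col(10, "A", A=[50, 50], G=[12, 0])
        calls = call_snps([col])
        assert calls[0].filter == "strand_bias"

    def test_purity(self, truth7, tmp_path):
        sam, _ = simulate_reads(truth7, "dna", depth=40, read_len=100,
                                seed=11, out_prefix=str(tmp_path / "d"))
        pile = build_pileup(sam, truth7.genome)
        one = call_snps(pile)
        two = call_snps(pile)
        assert one == two

    def test_planted_heteroplasmy_recovered_exactly(self, truth7, tmp_path):
        sam, _ = simulate_reads(truth7, "dna", depth=50, read_len=100,
                                seed=11, out_prefix=str(tmp_path / "h"))
        pile = build_pileup(sam, truth7.genome)
        passed = {c.position for c in call_snps(pile) if c.filter == "PASS"}
        assert passed == {v.position for v in truth7.planted_variants}


class TestCallEditing:
    def _one_gene_annotation(self, genome, start, end, strand):
        model = GeneModel(
            name="geneE", kind="CDS",
            exons=[Exon(interval=Interval(start=start, end=end, strand=strand),
                        phase=0, ordinal=1)],
            strand=strand,
        )
        return AnnotationSet(genome_id=genome.id, models=[model])

    def test_plus_strand_codon_change(self):
        #      1-based:   123456789...
        seq = "ATGTCATTAGGATGA" + "A" * 30
        genome = Plastome(id="g", sequence=seq, circular=False)
        ann = self._one_gene_annotation(genome, 1, 15, "+")
        # position 5 is the C of codon TCA (S); 40% of 50 reads carry T
        col = _col(5, "C", C=[15, 15], T=[10, 10])
        sites = call_editing_sites([col], ann, genome)
        assert len(sites) == 1
        s = sites[0]
        assert (s.codon_before, s.codon_after) == ("TCA", "TTA")
        assert (s.aa_before, s.aa_after) == ("S", "L")
        assert s.editing_level == pytest.approx(0.4)
        assert s.strand == "+"

    def test_minus_strand_reported_on_sense(self):
        from plastann.genome_model import revcomp

        sense = "ATGTCATTAGGATGA"
        seq = "C" * 20 + revcomp(sense) + "C" * 20
        genome = Plastome(id="g", sequence=seq, circular=False)
        ann = self._one_gene_annotation(genome, 21, 35, "-")
        # sense C at CDS index 4 -> genome position 21 + (15-1) - 4 = 31 (G)
        col = _col(31, "G", G=[30, 30], A=[20, 20])
        sites = call_editing_sites([col], ann, genome)
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "-"
        assert (s.genomic_base, s.rna_base) == ("C", "T")
        assert (s.codon_before, s.codon_after) == ("TCA", "TTA")

    def test_never_reports_non_c_sense_base(self, truth7, tmp_path):
        sam, _ = simulate_reads(truth7, "rna", depth=40, read_len=100,
                                seed=5, out_prefix=str(tmp_path / "r"))
        pile = build_pileup(sam, truth7.genome)
        for site in call_editing_sites(pile, truth7.annotation, truth7.genome):
            assert site.genomic_base == "C"

    def test_planted_sites_recovered_no_false_positives(self, truth7, tmp_path):
        sam, _ = simulate_reads(truth7, "rna", depth=60, read_len=100,
                                seed=5, out_prefix=str(tmp_path / "e"))
        pile = build_pileup(sam, truth7.genome)
        sites = call_editing_sites(pile, truth7.annotation, truth7.genome)
        assert {s.position for s in sites} == \
            {e.position for e in truth7.planted_editing}


class TestPrefilter:
    def _gene(self):
        rng = random.Random(55)
        return "".join(rng.choice("ACGT") for _ in range(600))

    def _write_fastq(self, path, reads):
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    def test_matching_read_passes_random_read_filtered(self, tmp_path):
        gene = self._gene()
        rng = random.Random(56)
        noise = "".join(rng.choice("ACGT") for _ in range(100))
        fin = tmp_path / "in.fastq"
        fout = tmp_path / "out.fastq"
        self._write_fastq(fin, [gene[100:200], noise])
        stats = prefilter_reads(str(fin), str(fout), [gene])
        assert stats == {"input": 2, "kept": 1, "malformed": 0}
        assert "@r0" in fout.read_text()

    def test_pair_kept_when_either_mate_matches(self, tmp_path):
        gene = self._gene()
        rng = random.Random(57)
        noise = "".join(rng.choice("ACGT") for _ in range(100))
        f1, f2 = tmp_path / "1.fastq", tmp_path / "2.fastq"
        o1, o2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        self._write_fastq(f1, [noise])
        self._write_fastq(f2, [gene[50:150]])
        stats = prefilter_reads(str(f1), str(o1), [gene],
                                mate_in=str(f2), mate_out=str(o2))
        assert stats["kept"] == 2
        assert "@r0" in o1.read_text() and "@r0" in o2.read_text()

    def test_malformed_record_counted(self, tmp_path):
        gene = self._gene()
        fin = tmp_path / "in.fastq"
        fin.write_text(f"@r0\n{gene[:80]}\n+\nIIII\n")  # qual length mismatch
        fout = tmp_path / "out.fastq"
        stats = prefilter_reads(str(fin), str(fout), [gene])
        assert stats["malformed"] == 1 and stats["kept"] == 0

    def test_empty_gene_set_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            prefilter_reads("x", "y", [])


class TestRecoveryAcrossSeeds:
    def test_editing_recovery_20_seeds(self, truth7, tmp_path):
        """Planted sites at >= 2x thresholds recovered at 100% over 20
        simulator seeds, with zero false positives at unedited C's."""
        planted = {e.position for e in truth7.planted_editing}
        for seed in range(20):
            sam, _ = simulate_reads(truth7, "rna", depth=40, read_len=100,
                                    seed=seed,
                                    out_prefix=str(tmp_path / f"s{seed}"))
            pile = build_pileup(sam, truth7.genome)
            sites = call_editing_sites(pile, truth7.annotation, truth7.genome,
                                       min_depth=10, min_level=0.1)
            assert {s.position for s in sites} == planted, f"seed {seed}"
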