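import os

import pytest

from plastann.annotate_core import AnnotationSet, GeneModel
from plastann.genome_model import Exon, Interval, Plastome
from plastann.writers import (
    read_genbank_annotation,
    read_gff3,
    render_map,
    write_feature_table,
    write_genbank,
    write_gff3,
)

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def _single_gene_annotation(genome):
    model = GeneModel(
        name="psbA", kind="CDS",
        exons=[Exon(interval=Interval(start=101, end=400), phase=0, ordinal=1)],
        strand="+",
    )
    return AnnotationSet(genome_id=genome.id, models=[model])


@pytest.fixture
def tiny_genome():
    import random

    rng = random.Random(9)
    return Plastome(id="tiny",
                    sequence="".join(rng.choice("ACGT") for _ in range(600)))


class TestGFF3:
    def test_single_gene_four_lines(self, tiny_genome):
        ann = _single_gene_annotation(tiny_genome)
        body = [l for l in write_gff3(ann, tiny_genome).splitlines()
                if l and not l.startswith("#")]
        assert [l.split("\t")[2] for l in body] == ["gene", "mRNA", "exon", "CDS"]
        for line in body[1:]:
            assert "Parent=" in line

    def test_round_trip_fixture(self, truth7, annotation7):
        text = write_gff3(annotation7, truth7.genome)
        back = read_gff3(text, truth7.genome.length)
        assert back.keys() == annotation7.keys()
        assert back.genome_id == truth7.genome.id

    def test_trans_spliced_shared_exon_multi_parent(self, truth7):
        text = write_gff3(truth7.annotation, truth7.genome)
        shared = [
            l for l in text.splitlines()
            if "\texon\t" in l and "Parent=mRNA-rps12.t1,mRNA-rps12.t2" in l
        ]
        assert len(shared) == 1
        back = read_gff3(text, truth7.genome.length)
        t1 = next(m for m in back.models if m.transcript_id == "rps12.t1")
        t2 = next(m for m in back.models if m.transcript_id == "rps12.t2")
        assert t1.exons[0].interval == t2.exons[0].interval

    def test_wrapping_feature_split_and_merged(self):
        genome = Plastome(id="w", sequence="ATGAAA" * 100)
        model = GeneModel(
            name="wrap", kind="rRNA",
            exons=[Exon(interval=Interval(start=580, end=30, strand="+",
                                          wraps_origin=True),
                        phase=0, ordinal=1)],
            strand="+",
        )
        ann = AnnotationSet(genome_id="w", models=[model])
        text = write_gff3(ann, genome)
        exon_lines = [l for l in text.splitlines() if "\texon\t" in l]
        assert len(exon_lines) == 2
        ids = {l.split("ID=")[1].split(";")[0] for l in exon_lines}
        assert len(ids) == 1  # two location lines share one ID
        back = read_gff3(text, genome.length)
        assert back.models[0].exons[0].interval.wraps_origin

    def test_cds_phase_column(self, truth7):
        text = write_gff3(truth7.annotation, truth7.genome)
        for line in text.splitlines():
            cols = line.split("\t")
            if len(cols) == 9 and cols[2] == "CDS":
                assert cols[7] in ("0", "1", "2")


class TestGenBank:
    def test_round_trip_fixture(self, truth7, annotation7, tmp_path):
        path = str(tmp_path / "out.gb")
        write_genbank(annotation7, truth7.genome, path)
        back, genome = read_genbank_annotation(path)
        assert genome.sequence == truth7.genome.sequence
        assert back.keys() == annotation7.keys()

    def test_trans_splicing_exception_written(self, truth7, tmp_path):
        path = str(tmp_path / "out.gb")
        write_genbank(truth7.annotation, truth7.genome, path)
        text = open(path).read()
        assert text.count('/exception="trans-splicing"') >= 2
        assert "join(" in text and "complement(" in text

    def test_translation_qualifier_for_complete_cds(self, truth7, tmp_path):
        path = str(tmp_path / "out.gb")
        write_genbank(truth7.annotation, truth7.genome, path)
        from Bio import SeqIO

        rec = next(SeqIO.parse(path, "genbank"))
        cds = [f for f in rec.features if f.type == "CDS"]
        assert all("translation" in f.qualifiers for f in cds)
        psbA = next(f for f in cds if f.qualifiers["gene"][0] == "psbA")
        assert psbA.qualifiers["translation"][0].startswith("M")

    def test_partial_round_trip(self, tiny_genome, tmp_path):
        model = GeneModel(
            name="part", kind="CDS",
            exons=[Exon(interval=Interval(start=101, end=399), phase=0,
                        ordinal=1)],
            strand="+", partial_3p=True,
        )
        ann = AnnotationSet(genome_id=tiny_genome.id, models=[model])
        path = str(tmp_path / "p.gb")
        write_genbank(ann, tiny_genome, path)
        back, _ = read_genbank_annotation(path)
        assert back.models[0].partial_3p and not back.models[0].partial_5p


class TestFeatureTable:
    def test_single_gene_blocks(self, tiny_genome):
        ann = _single_gene_annotation(tiny_genome)
        tbl, fsa = write_feature_table(ann, tiny_genome)
        lines = tbl.splitlines()
        assert lines[0] == ">Feature tiny"
        assert lines[1] == "101\t400\tgene"
        assert "101\t400\tCDS" in lines
        assert fsa.startswith(">tiny\n")

    def test_partial_markers(self, tiny_genome):
        model = GeneModel(
            name="p5", kind="CDS",
            exons=[Exon(interval=Interval(start=101, end=400), phase=0,
                        ordinal=1)],
            strand="+", partial_5p=True,
        )
        ann = AnnotationSet(genome_id=tiny_genome.id, models=[model])
        tbl, _ = write_feature_table(ann, tiny_genome)
        assert "<101\t400\tCDS" in tbl

    def test_minus_strand_coordinates_reversed(self, tiny_genome):
        model = GeneModel(
            name="m", kind="CDS",
            exons=[Exon(interval=Interval(start=101, end=400, strand="-"),
                        phase=0, ordinal=1)],
            strand="-",
        )
        ann = AnnotationSet(genome_id=tiny_genome.id, models=[model])
        tbl, _ = write_feature_table(ann, tiny_genome)
        assert "400\t101\tCDS" in tbl

    def test_golden_file(self, truth7, annotation7):
        tbl, _ = write_feature_table(annotation7, truth7.genome)
        golden = os.path.join(DATA_DIR, "golden_plastome.tbl")
        expected = open(golden).read()
        assert tbl == expected


class TestRenderMap:
    def test_empty_annotation_valid_svg_four_rings(self, tiny_genome):
        svg = render_map(AnnotationSet(genome_id="tiny"), [], [], [],
                         tiny_genome)
        assert svg.startswith("<?xml")
        assert svg.rstrip().endswith("</svg>")
        for ring in ("dispersed", "tandem", "ssr", "genes"):
            assert f'class="ring-{ring}"' in svg

    def test_one_forward_pair_one_red_arc(self, tiny_genome, truth7):
        fwd = [d for d in truth7.dispersed
               if d.orientation == "forward" and d.length == 40]
        svg = render_map(AnnotationSet(genome_id="x"), [], [], fwd,
                         truth7.genome)
        assert svg.count('class="dispersed forward"') == 1
        assert '#cc2222' in svg

    def test_deterministic(self, truth7, annotation7):
        args = (annotation7, truth7.ssrs, truth7.tandems, truth7.dispersed,
                truth7.genome)
        assert render_map(*args) == render_map(*args)
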