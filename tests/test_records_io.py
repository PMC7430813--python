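"""Record invariants and file-format round trips."""

import pytest

from cgap import io
from cgap.records import (
    CodingSequenceRecord,
    CoverageTrack,
    ExonSpan,
    ProtocolConfig,
    cutoff_for,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestRecordInvariants:
    def test_cds_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodingSequenceRecord("r1", "Homo sapiens", "ATGC", (("c", 0, 4, "+"),))

    def test_exon_spans_must_sum_to_cds_length(self):
        with pytest.raises(ValueError, match="sum"):
            CodingSequenceRecord("r1", "Homo sapiens", "ATGTAA", (("c", 0, 3, "+"),))

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CodingSequenceRecord(
                "r1", "Homo sapiens", "ATGAAATAA",
                (("c", 0, 6, "+"), ("c", 3, 6, "+")),
            )

    def test_coverage_track_rejects_negative(self):
        with pytest.raises(ValueError):
            CoverageTrack("r1", (1, -2, 3))


class TestGFF3:
    def test_single_exon_plus_strand(self, tmp_path):
        fasta = _write(tmp_path / "c.fa", ">ctg\nAAATGTAAGGG\n")
        gff = _write(
            tmp_path / "m.gff3",
            "##gff-version 3\nctg\t.\tCDS\t3\t11\t.\t+\t.\tID=g1;Parent=g1;taxon=Homo_sapiens\n",
        )
        (rec,) = io.read_dataset(fasta, gff)
        assert rec.cds_sequence == "ATGTAAGGG"
        assert rec.n_exons == 1
        assert rec.taxon == "Homo sapiens"

    def test_two_exon_minus_strand_reverse_complement(self, tmp_path):
        # hand-constructed 12 bp gene: exons at [0,6) and [8,14) on '-'
        # genomic: AACCGG TT AATTCC -> CDS = revcomp(AATTCC) + revcomp(AACCGG)
        #        = GGAATT + CCGGTT
        fasta = _write(tmp_path / "c.fa", ">ctg\nAACCGGTTAATTCC\n")
        gff = _write(
            tmp_path / "m.gff3",
            "##gff-version 3\n"
            "ctg\t.\tCDS\t1\t6\t.\t-\t.\tParent=g1\n"
            "ctg\t.\tCDS\t9\t14\t.\t-\t.\tParent=g1\n",
        )
        (rec,) = io.read_dataset(fasta, gff)
        assert rec.cds_sequence == "GGAATTCCGGTT"
        # transcript order on minus strand: downstream exon first
        assert rec.exon_model[0].start == 8
        assert rec.exon_model[1].start == 0

    def test_invalid_length_record_rejected_not_raised(self, tmp_path, caplog):
        fasta = _write(tmp_path / "c.fa", ">ctg\nAAATGTAAGGG\n")
        gff = _write(
            tmp_path / "m.gff3",
            "ctg\t.\tCDS\t3\t10\t.\t+\t.\tParent=bad\n",
        )
        with caplog.at_level("WARNING", logger="cgap"):
            records = io.read_dataset(fasta, gff)
        assert records == []
        assert any("bad" in r.message for r in caplog.records)

    def test_missing_contig_is_hard_error(self, tmp_path):
        fasta = _write(tmp_path / "c.fa", ">ctg\nAAATGTAAGGG\n")
        gff = _write(tmp_path / "m.gff3", "other\t.\tCDS\t3\t11\t.\t+\t.\tParent=g1\n")
        with pytest.raises(KeyError):
            io.read_dataset(fasta, gff)

    def test_round_trip_on_simulated_records(self, tmp_path, small_family):
        records, contigs, _, _ = small_family
        io.write_contigs(contigs, tmp_path / "c.fa")
        io.write_gff3(records, tmp_path / "m.gff3")
        back = io.read_dataset(tmp_path / "c.fa", tmp_path / "m.gff3")
        assert len(back) == len(records)
        by_id = {r.id: r for r in back}
        for rec in records:
            assert by_id[rec.id].cds_sequence == rec.cds_sequence
            assert by_id[rec.id].exon_model == rec.exon_model
            assert by_id[rec.id].taxon == rec.taxon


class TestEMBL:
    def test_embl_join_feature_matches_gff3_reader(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
        from Bio import SeqIO

        genomic = "AAATGAAACCCTTTGGGTAATT"
        # exons [2,11) and [14,20): CDS = ATGAAACCC + TTGGGT... keep frame:
        loc = CompoundLocation([SimpleLocation(2, 11, 1), SimpleLocation(14, 20, 1)])
        cds = loc.extract(Seq(genomic))
        assert len(cds) % 3 == 0
        entry = SeqRecord(Seq(genomic), id="CTG1", name="CTG1",
                          description="synthetic test entry",
                          annotations={"molecule_type": "DNA"})
        entry.features.append(
            SeqFeature(SimpleLocation(0, len(genomic)), type="source",
                       qualifiers={"organism": ["Homo sapiens"]})
        )
        entry.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": ["G1"], "locus_tag": ["g1"]})
        )
        embl = tmp_path / "e.embl"
        SeqIO.write([entry], str(embl), "embl")

        fasta = _write(tmp_path / "c.fa", f">CTG1\n{genomic}\n")
        gff = _write(
            tmp_path / "m.gff3",
            "CTG1\t.\tCDS\t3\t11\t.\t+\t.\tParent=g1;taxon=Homo_sapiens\n"
            "CTG1\t.\tCDS\t15\t20\t.\t+\t.\tParent=g1;taxon=Homo_sapiens\n",
        )
        (from_embl,) = io.read_dataset_embl([embl])
        (from_gff,) = io.read_dataset(fasta, gff)
        assert from_embl.cds_sequence == from_gff.cds_sequence
        assert [
            (e.start, e.end, e.strand) for e in from_embl.exon_model
        ] == [(e.start, e.end, e.strand) for e in from_gff.exon_model]
        assert from_embl.taxon == from_gff.taxon


class TestWriters:
    def test_empty_table_has_header_only(self, tmp_path):
        import pandas as pd

        path = tmp_path / "t.tsv"
        io.write_table(pd.DataFrame(columns=["a", "b"]), path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["a\tb"]

    def test_three_leaf_tree_round_trip(self, tmp_path):
        path = tmp_path / "t.nwk"
        io.write_tree("(A:1,B:2,C:3)", path)
        tree = io.read_tree(path)
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]

    def test_coverage_round_trip(self, tmp_path):
        track = CoverageTrack("r1", (3, 3, 0, 0, 5, 1))
        io.write_coverage([track], tmp_path / "cov.bedgraph")
        back = io.read_coverage(tmp_path / "cov.bedgraph")
        assert back["r1"].coverage == track.coverage

    def test_alignment_round_trip_preserves_stop_symbol(self, tmp_path):
        from cgap.msa import align_records
        from cgap.records import CodingSequenceRecord

        recs = [
            CodingSequenceRecord("a", "t1", "ATGAAATGA", (("c1", 0, 9, "+"),)),
            CodingSequenceRecord("b", "t2", "ATGAAGTGA", (("c2", 0, 9, "+"),)),
        ]
        aln = align_records(recs)
        prot = aln.protein_rows()
        assert prot["a"].endswith("&")
        io.write_alignment(prot, tmp_path / "p.fasta")
        back = io.read_alignment(tmp_path / "p.fasta")
        assert back == prot


class TestCutoffTiers:
    @pytest.mark.parametrize(
        "taxon,expected",
        [
            ("Pan troglodytes", (0.95, 100)),
            ("Gorilla gorilla", (0.95, 100)),
            ("Pongo abelii", (0.90, 100)),
            ("Macaca mulatta", (0.85, 100)),
            ("Callithrix jacchus", (0.80, 100)),
            ("Microcebus murinus", (0.75, 100)),
            ("Mus musculus", (0.65, 100)),  # Rodentia tier
            ("Rattus norvegicus", (0.65, 100)),
            ("Bos taurus", (0.70, 100)),  # fallback tier
            ("Loxodonta africana", (0.70, 100)),
        ],
    )
    def test_tier_lookup(self, taxon, expected):
        assert cutoff_for(taxon) == expected

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(rscu_threshold=1.5)
        with pytest.raises(ValueError):
            ProtocolConfig(contiguity_cutoffs={"default": (1.5, 100)})
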