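"""RSCU statistics, site classification, alignment landmarks."""

import numpy as np
import pytest

from cgap.msa import CodonAlignment, align_records, thread_codons, translate
from cgap.protein_evolution import (
    FAMILIES,
    classify_sites,
    codon_usage,
    extract_landmarks,
    splice_boundary_positions,
)
from cgap.records import CodingSequenceRecord


class TestRSCU:
    def test_uniform_usage_gives_r_one_everywhere(self):
        cds = "".join(c for fam in FAMILIES.values() for c in fam)
        table = codon_usage([cds])
        for fam in FAMILIES.values():
            for c in fam:
                assert table.R[c] == pytest.approx(1.0)
        assert table.not_preferable == frozenset()

    def test_two_codon_family_example(self):
        table = codon_usage(["TTTTTTTTTTTC"])  # TTT x3, TTC x1
        assert table.R["TTT"] == pytest.approx(1.5)
        assert table.R["TTC"] == pytest.approx(0.5)
        assert "TTC" in table.not_preferable
        assert "TTT" not in table.not_preferable

    def test_family_mean_normalisation_on_simulated_data(self, small_family):
        records, *_ = small_family
        table = codon_usage(records)
        for fam in FAMILIES.values():
            total = sum(table.counts[c] for c in fam)
            if total > 0:
                assert np.mean([table.R[c] for c in fam]) == pytest.approx(1.0)

    def test_single_codon_families_never_not_preferable(self, small_family):
        records, *_ = small_family
        table = codon_usage(records)
        assert "ATG" not in table.not_preferable
        assert "TGG" not in table.not_preferable
        assert table.R["ATG"] == pytest.approx(1.0)

    def test_stops_tabulated_but_never_classified(self, small_family):
        records, *_ = small_family
        table = codon_usage(records)
        assert sum(table.counts[c] for c in ("TAA", "TAG", "TGA")) == len(records)
        assert not table.not_preferable & {"TAA", "TAG", "TGA"}

    def test_threshold_monotonicity(self, small_family):
        records, *_ = small_family
        low = codon_usage(records, threshold=0.5).not_preferable
        high = codon_usage(records, threshold=0.9).not_preferable
        assert low <= high


def _toy_alignment(rows_cds):
    msa = {rid: translate(cds) for rid, cds in rows_cds.items()}
    return thread_codons(msa, rows_cds)


class TestSiteClassification:
    def test_invariant_forward_compensatory_definitions(self):
        # column 2 varies (I/L) and row c uses TTA there; column 3 varies
        # (K/E) with no rare codon
        cds = {
            "ref": "ATGATTAAATAA",
            "b":   "ATGCTGGAATAA",
            "c":   "ATGTTAAAATAA",
        }
        aln = _toy_alignment(cds)
        pool = codon_usage(list(cds.values()))
        # force a known not-preferable set for the definition check
        pool.not_preferable = frozenset({"TTA"})
        sc = classify_sites(aln, "ref", pool)
        assert sc.label_of(1) == "invariant"     # M in every row
        assert sc.label_of(2) == "compensatory"  # L column contains TTA
        assert sc.label_of(3) == "forward"       # K/E variant, no rare codon
        assert sc.label_of(4) == "invariant"     # stop column: single symbol
        # without TTA in the pool the same variant column is forward
        pool.not_preferable = frozenset()
        sc2 = classify_sites(aln, "ref", pool)
        assert sc2.label_of(2) == "forward"

    def test_all_rows_identical_column_invariant(self):
        cds = {"ref": "ATGAAATAA", "b": "ATGAAATAA"}
        aln = _toy_alignment(cds)
        sc = classify_sites(aln, "ref", codon_usage(list(cds.values())))
        assert {s.label for s in sc.sites} == {"invariant"}

    def test_missing_reference_is_hard_error(self, small_alignment):
        table = codon_usage(small_alignment)
        with pytest.raises(KeyError):
            classify_sites(small_alignment, "no-such-record", table)

    def test_every_reference_site_gets_exactly_one_label(self, small_alignment, small_family):
        records, *_ = small_family
        table = codon_usage(small_alignment)
        ref = records[0].id
        sc = classify_sites(small_alignment, ref, table)
        assert len(sc.sites) == records[0].n_codons
        positions = [s.reference_position for s in sc.sites]
        assert positions == sorted(set(positions))

    def test_designed_invariant_sites_recovered(self):
        # codon rows are stacked on the generator's gapless homology (the
        # simulator introduces no indels), isolating the classifier from
        # aligner error at saturating divergence
        from cgap.simulate import FamilyDesign, simulate_family

        for seed in range(5):
            design = FamilyDesign(
                n_superclusters=2,
                clusters_per_supercluster=2,
                taxa=("Homo sapiens", "Macaca mulatta", "Mus musculus", "Bos taurus"),
                hole_probability=0.0,
            )
            records, _, _, truth = simulate_family(design, seed=seed)
            cds_map = {r.id: r.cds_sequence for r in records}
            aln = thread_codons({rid: translate(c) for rid, c in cds_map.items()}, cds_map)
            table = codon_usage(aln)
            sc = classify_sites(aln, records[0].id, table)
            recovered = set(sc.positions("invariant"))
            assert truth.invariant_site_positions <= recovered

    def test_raising_threshold_never_turns_compensatory_into_forward(self, small_alignment):
        ref = small_alignment.record_ids[0]
        low = classify_sites(small_alignment, ref, codon_usage(small_alignment, 0.5))
        high = classify_sites(small_alignment, ref, codon_usage(small_alignment, 0.9))
        for s_low, s_high in zip(low.sites, high.sites):
            if s_low.label == "compensatory":
                assert s_high.label == "compensatory"


class TestLandmarks:
    def _records(self, cds_map, n_exons=1):
        out = []
        for rid, cds in cds_map.items():
            L = len(cds)
            bounds = np.linspace(0, L, n_exons + 1).astype(int)
            spans = tuple(
                (f"{rid}_c", int(a), int(b), "+") for a, b in zip(bounds, bounds[1:])
            )
            out.append(CodingSequenceRecord(rid, "t", cds, spans))
        return out

    def test_common_sequon_in_identical_proteins(self):
        cds = {"a": "ATGAATGGATCTTAA", "b": "ATGAATGGATCTTAA"}  # M N G S &
        recs = self._records(cds)
        aln = _toy_alignment(cds)
        lm = extract_landmarks(aln, recs)
        assert lm.common_nglyc == (1,)  # the NGS sequon column

    def test_cysteine_lost_in_one_member_not_common(self):
        cds_c = {"a": "ATGTGTAAATAA", "b": "ATGTGTAAATAA"}  # M C K &
        recs = self._records(cds_c)
        lm = extract_landmarks(_toy_alignment(cds_c), recs)
        assert lm.common_cysteines == (1,)
        cds_s = {"a": "ATGTGTAAATAA", "b": "ATGAGTAAATAA"}  # C -> S in b
        recs2 = self._records(cds_s)
        lm2 = extract_landmarks(_toy_alignment(cds_s), recs2)
        assert lm2.common_cysteines == ()

    def test_five_exon_gene_has_four_splice_boundaries(self, small_family):
        records, _, _, truth = small_family
        five_exon = [r for r in records if r.n_exons == 5]
        assert five_exon
        for rec in five_exon:
            assert len(splice_boundary_positions(rec)) == 4

    def test_common_splice_sites_match_exon_count(self, small_family):
        records, _, _, truth = small_family
        cluster = [r for r in records if truth.cluster_membership[r.id][1] == "1A"]
        aln = align_records(cluster)
        lm = extract_landmarks(aln, cluster, "1A")
        assert len(lm.common_splice_sites) == cluster[0].n_exons - 1

    def test_split_codon_attributed_to_upstream_exon(self):
        # 9-codon CDS, exon boundary mid-codon at base 10 -> codon index 3
        rec = CodingSequenceRecord(
            "r", "t", "ATGAAACCCGGGTTTAAACCCGGGTAA",
            (("c", 0, 10, "+"), ("c", 20, 37, "+")),
        )
        assert splice_boundary_positions(rec) == [3]
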