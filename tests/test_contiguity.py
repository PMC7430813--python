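"""Anchor-chain genomic alignment and conserved-region detection."""

import numpy as np
import pytest

from cgap.contiguity import (
    AlignmentBlock,
    detect_conserved_regions,
    pairwise_genomic_align,
)
from cgap.contiguity import test_contiguity as contiguity_verdict
from cgap.records import GenomicContig
from cgap.simulate import FamilyDesign, inject_misassembly, revcomp, simulate_family


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _block(a, b, orientation="forward"):
    """Alignment block straight from two pre-aligned strings."""
    bc = np.full(len(a), -1, dtype=np.int64)
    tc = np.full(len(a), -1, dtype=np.int64)
    i = j = 0
    for k in range(len(a)):
        if a[k] != "-":
            bc[k] = i
            i += 1
        if b[k] != "-":
            tc[k] = j
            j += 1
    return AlignmentBlock(a, b, bc, tc, orientation)


class TestPairwiseAlign:
    def test_identical_contigs_single_full_chain(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 1000)
        base = GenomicContig("b", "Homo sapiens", seq)
        target = GenomicContig("t", "Pan troglodytes", seq, role="target")
        blocks = pairwise_genomic_align(base, target)
        assert len(blocks) == 1
        assert blocks[0].base_span == (0, 1000)
        segs = detect_conserved_regions(blocks, (0.95, 100))
        assert len(segs) == 1 and segs[0].mean_identity == 1.0

    def test_symmetry_for_identical_sequences(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 600)
        a = GenomicContig("a", "x", seq)
        b = GenomicContig("b", "y", seq, role="target")
        segs_ab = detect_conserved_regions(pairwise_genomic_align(a, b), (0.9, 100))
        segs_ba = detect_conserved_regions(pairwise_genomic_align(b, a), (0.9, 100))
        assert [(s.base_start, s.base_end) for s in segs_ab] == [
            (s.target_start, s.target_end) for s in segs_ba
        ]

    def test_inverted_region_yields_reverse_block_at_span(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 900)
        lo, hi = 400, 560
        mutated = seq[:lo] + revcomp(seq[lo:hi]) + seq[hi:]
        base = GenomicContig("b", "x", seq)
        target = GenomicContig("t", "y", mutated, role="target")
        blocks = pairwise_genomic_align(base, target)
        reverse = [blk for blk in blocks if blk.orientation == "reverse"]
        assert len(reverse) == 1
        span = reverse[0].base_span
        assert abs(span[0] - lo) <= 12 and abs(span[1] - hi) <= 12
        assert reverse[0].target_span == span  # in-place inversion

    @pytest.mark.parametrize("seed", range(5))
    def test_unrelated_sequences_have_no_conserved_segment(self, seed):
        rng = np.random.default_rng(seed)
        a = GenomicContig("a", "x", _random_seq(rng, 1000))
        b = GenomicContig("b", "y", _random_seq(rng, 1000), role="target")
        blocks = pairwise_genomic_align(a, b)
        for cutoff in [(0.95, 100), (0.65, 100)]:
            assert detect_conserved_regions(blocks, cutoff) == []


class TestConservedRegions:
    def brute_force(self, block, frac, window):
        """Exhaustive all-windows scan (oracle for short alignments)."""
        m = [
            1 if a == b and a != "-" and b != "-" else 0
            for a, b in zip(block.aligned_base, block.aligned_target)
        ]
        L = len(m)
        passing = [
            i for i in range(L - window + 1) if sum(m[i : i + window]) >= frac * window - 1e-9
        ]
        covered = set()
        for i in passing:
            covered.update(range(i, i + window))
        # split into maximal runs of consecutive passing windows
        runs = []
        for i in passing:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        return [(r[0], r[-1] + window) for r in runs]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        base = _random_seq(rng, 1500)
        # target: mutate at varying densities to create passing/failing zones
        target = list(base)
        for i in range(0, 500):
            if rng.random() < 0.02:
                target[i] = "ACGT"[(("ACGT".index(target[i]) + 1) % 4)]
        for i in range(500, 900):
            if rng.random() < 0.3:
                target[i] = "ACGT"[(("ACGT".index(target[i]) + 1) % 4)]
        block = _block(base, "".join(target))
        for cutoff in [(0.95, 100), (0.8, 50), (0.65, 100)]:
            got = [
                (s.base_start, s.base_end)
                for s in detect_conserved_regions(block, cutoff)
            ]
            assert got == self.brute_force(block, *cutoff)

    def test_threshold_straddling_block(self):
        rng = np.random.default_rng(3)
        base = _random_seq(rng, 200)
        target = list(base)
        # exactly 8 mismatches over 200 bp -> 96% identity
        for i in range(0, 200, 25):
            target[i] = "ACGT"[("ACGT".index(target[i]) + 1) % 4]
        block = _block(base, "".join(target))
        assert detect_conserved_regions(block, (0.95, 100))
        assert detect_conserved_regions(block, (0.97, 100)) == []

    def test_short_perfect_match_below_window_not_reported(self):
        block = _block("ACGT" * 20, "ACGT" * 20)  # 80 bp, identity 1.0
        assert detect_conserved_regions(block, (0.95, 100)) == []


@pytest.fixture(scope="module")
def family():
    design = FamilyDesign(
        n_superclusters=1, clusters_per_supercluster=1, hole_probability=0.0
    )
    return simulate_family(design, seed=9)


class TestVerdicts:
    def _base_and_targets(self, family):
        records, contigs, _, _ = family
        by_id = {c.id: c for c in contigs}
        base_rec = next(r for r in records if r.taxon == "Homo sapiens")
        base = by_id[base_rec.id + "_g"]
        targets = {
            r.taxon: (r, by_id[r.id + "_g"])
            for r in records
            if r.taxon != "Homo sapiens"
        }
        return base_rec, base, targets

    def test_clean_orthologue_set_is_consistent(self, family):
        base_rec, base, targets = self._base_and_targets(family)
        blocks = {
            taxon: pairwise_genomic_align(base, contig)
            for taxon, (_, contig) in targets.items()
        }
        verdict = contiguity_verdict(base_rec, blocks)
        assert verdict.verdict == "consistent"
        assert verdict.conserved_exons == verdict.expected_exons
        assert verdict.defect_hint is None

    @pytest.mark.parametrize("defect", ["inversion", "exon_loss", "reorder"])
    def test_injected_defect_flagged(self, family, defect):
        base_rec, base, targets = self._base_and_targets(family)
        taxon = "Pan troglodytes"
        target_rec, contig = targets[taxon]
        mutated = inject_misassembly(contig, target_rec.exon_model, defect, seed=4)
        verdict = contiguity_verdict(
            base_rec, {taxon: pairwise_genomic_align(base, mutated)}
        )
        assert verdict.verdict == "misassembly"
        expected_hint = {
            "inversion": "inversion",
            "exon_loss": "missing_exon",
            "reorder": "reorder",
        }[defect]
        assert verdict.defect_hint == expected_hint

    def test_exon_loss_reduces_conserved_count_by_one(self, family):
        base_rec, base, targets = self._base_and_targets(family)
        taxon = "Macaca mulatta"
        target_rec, contig = targets[taxon]
        mutated = inject_misassembly(contig, target_rec.exon_model, "exon_loss", seed=2)
        verdict = contiguity_verdict(
            base_rec, {taxon: pairwise_genomic_align(base, mutated)}
        )
        assert verdict.conserved_exons == verdict.expected_exons - 1
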