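"""Synthetic gene-family generator with a machine-readable truth record.

Emulates the statistical structure the analysis pipeline assumes: a
hierarchy of superclusters > major gene clusters > per-species orthologues,
coding sequences with 3 or 5 coding exons embedded in genomic contigs,
codon usage biased against a designated rare-codon set, invariant
amino-acid sites, per-base trace coverage with optional zero-coverage
holes, and injectable coding-exon misassemblies.  Every stochastic choice
flows through one ``numpy`` generator, so a fixed (design, seed) pair gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .msa import _CODON_TO_AA, STOP_SYMBOL
from .records import CodingSequenceRecord, CoverageTrack, ExonSpan, GenomicContig

_STOPS = tuple(c for c, aa in _CODON_TO_AA.items() if aa == STOP_SYMBOL)
_SENSE = tuple(c for c, aa in _CODON_TO_AA.items() if aa != STOP_SYMBOL)
_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    if _aa != STOP_SYMBOL:
        _FAMILIES.setdefault(_aa, ())
        _FAMILIES[_aa] = _FAMILIES[_aa] + (_codon,)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# Species tree

#: Default eutherian-like panel spanning the contiguity cutoff tiers,
#: with ultrametric relative branch lengths (tree depth 0.07 subs/site).
_DEFAULT_TAXA = (
    "Homo sapiens",
    "Pan troglodytes",
    "Pongo abelii",
    "Macaca mulatta",
    "Callithrix jacchus",
    "Microcebus murinus",
    "Mus musculus",
    "Rattus norvegicus",
    "Canis lupus familiaris",
    "Bos taurus",
)

# A node is (subtree, branch-length-to-parent); a subtree is either a leaf
# name or a tuple of child nodes.  The default panel tree is ultrametric
# with depth 0.07 expected substitutions per site.
_HOMINOID = (
    ((("Homo sapiens", 0.003), ("Pan troglodytes", 0.003)), 0.009),
    ("Pongo abelii", 0.012),
)
_CATARRHINI = ((_HOMINOID, 0.009), ("Macaca mulatta", 0.021))
_SIMIIFORMES = ((_CATARRHINI, 0.009), ("Callithrix jacchus", 0.03))
_PRIMATES = ((_SIMIIFORMES, 0.012), ("Microcebus murinus", 0.042))
_RODENTS = ((("Mus musculus", 0.045), ("Rattus norvegicus", 0.045)), 0.015)
_EUARCHONTOGLIRES = (((_PRIMATES, 0.018), _RODENTS), 0.01)
_LAURASIATHERIA = (
    (("Canis lupus familiaris", 0.035), ("Bos taurus", 0.035)),
    0.035,
)
_DEFAULT_TREE = ((_EUARCHONTOGLIRES, _LAURASIATHERIA), 0.0)
_DEFAULT_DEPTH = 0.07


def _ladder_tree(taxa: Sequence[str], depth: float):
    """Ultrametric caterpillar over an arbitrary taxon list."""
    n = len(taxa)
    if n == 1:
        return (((taxa[0], depth),), 0.0)
    step = depth / (n - 1)

    def build(k):  # node over taxa[:k], sitting at height (k-1)*step
        if k == 2:
            return (((taxa[0], step), (taxa[1], step)), step)
        return ((build(k - 1), (taxa[k - 1], (k - 1) * step)), step)

    return (build(n)[0], 0.0)


def _tree_newick(node) -> str:
    sub, bl = node
    if isinstance(sub, str):
        return f"{sub.replace(' ', '_')}:{bl:g}"
    return "(" + ",".join(_tree_newick(c) for c in sub) + f"):{bl:g}"


# ---------------------------------------------------------------------------
# Design and truth


@dataclass
class FamilyDesign:
    """Shape and rates of a simulated gene family.

    Defaults mirror a comprehensive eutherian gene-family study: 8
    superclusters holding (4,2,1,3,4,3,2,3) = 22 major gene clusters, a
    10-taxon panel, proteins of 190-250 codons, five coding exons in the
    first supercluster's clusters plus one more, three elsewhere, and
    divergence scales ordered within-cluster <= between-cluster <=
    between-supercluster (expected substitutions per site).
    """

    n_superclusters: int = 8
    clusters_per_supercluster: tuple[int, ...] | int = (4, 2, 1, 3, 4, 3, 2, 3)
    taxa: tuple[str, ...] = _DEFAULT_TAXA
    exons_per_cluster: Optional[tuple[int, ...]] = None
    protein_length_range: tuple[int, int] = (190, 250)
    divergence_within: float = 0.07
    divergence_between_clusters: float = 0.6
    divergence_between_superclusters: float = 1.6
    invariant_fraction: float = 0.08
    rare_codon_bias: float = 0.15
    n_rare_codons: int = 20
    kappa: float = 2.0
    mean_depth: float = 8.0
    hole_probability: float = 0.5
    intron_length_range: tuple[int, int] = (80, 300)
    flank_length_range: tuple[int, int] = (120, 200)
    min_exon_bp: int = 110
    base_taxon: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if isinstance(self.clusters_per_supercluster, int):
            self.clusters_per_supercluster = (
                self.clusters_per_supercluster,
            ) * self.n_superclusters
        if len(self.clusters_per_supercluster) != self.n_superclusters:
            raise ValueError("clusters_per_supercluster length != n_superclusters")
        if not (
            0.0
            <= self.divergence_within
            <= self.divergence_between_clusters
            <= self.divergence_between_superclusters
        ):
            raise ValueError("divergence scales must be ordered within <= between-cluster <= between-supercluster")
        if not (0.0 <= self.invariant_fraction <= 1.0):
            raise ValueError("invariant_fraction must lie in [0,1]")
        if not (0.0 <= self.rare_codon_bias <= 1.0):
            raise ValueError("rare_codon_bias must lie in [0,1]")
        if self.protein_length_range[0] < 60:
            raise ValueError("proteins shorter than 60 codons cannot host the default exon layout")

    @property
    def n_clusters(self) -> int:
        return int(sum(self.clusters_per_supercluster))

    def exon_counts(self) -> tuple[int, ...]:
        """Coding-exon count per cluster (flattened supercluster order)."""
        if self.exons_per_cluster is not None:
            if len(self.exons_per_cluster) != self.n_clusters:
                raise ValueError("exons_per_cluster length != total cluster count")
            return tuple(self.exons_per_cluster)
        # five exons in every cluster of the first supercluster and in the
        # first cluster of the sixth; three elsewhere (the study layout)
        counts = []
        for s, k in enumerate(self.clusters_per_supercluster):
            for c in range(k):
                five = (s == 0) or (s == 5 and c == 0 and self.n_superclusters >= 6)
                counts.append(5 if five else 3)
        return tuple(counts)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated family."""

    species_tree: str
    cluster_membership: dict[str, tuple[str, str]]  # id -> (supercluster, cluster)
    invariant_site_positions: frozenset[int]  # 1-based protein positions
    rare_codon_set: frozenset[str]
    misassembly_injections: dict[str, str] = field(default_factory=dict)
    coverage_holes: dict[str, frozenset[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["invariant_site_positions"] = sorted(self.invariant_site_positions)
        d["rare_codon_set"] = sorted(self.rare_codon_set)
        d["coverage_holes"] = {k: sorted(v) for k, v in self.coverage_holes.items()}
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence evolution


def _pick_rare_codons(rng: np.random.Generator, n_rare: int) -> frozenset[str]:
    """Rare codons drawn only from families with >=2 synonymous
    alternatives, at most half of any family."""
    eligible = [
        (aa, codon)
        for aa, fam in sorted(_FAMILIES.items())
        for codon in sorted(fam)
        if len(fam) >= 3
    ]
    quota = {aa: len(fam) // 2 for aa, fam in _FAMILIES.items()}
    order = rng.permutation(len(eligible))
    chosen: list[str] = []
    for idx in order:
        aa, codon = eligible[idx]
        if quota[aa] > 0:
            chosen.append(codon)
            quota[aa] -= 1
        if len(chosen) == n_rare:
            break
    return frozenset(chosen)


def _ancestral_codons(
    rng: np.random.Generator, n_codons: int, rare: frozenset[str], bias: float
) -> list[str]:
    """Random ancestral CDS: ATG start, biased synonymous choice, one stop."""
    aas = sorted(set(_FAMILIES))
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        aa = aas[rng.integers(len(aas))]
        fam = sorted(_FAMILIES[aa])
        w = np.array([bias if c in rare else 1.0 for c in fam])
        codons.append(fam[rng.choice(len(fam), p=w / w.sum())])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return codons


def _evolve(
    codons: Sequence[str],
    t: float,
    rng: np.random.Generator,
    invariant: frozenset[int],
    rare: frozenset[str],
    kappa: float,
    bias: float,
) -> list[str]:
    """Evolve a codon sequence for ``t`` expected proposals per site.

    Per-site nucleotide proposals under a transition/transversion bias are
    rejected when they create a premature stop, change an invariant site's
    amino acid, or (with probability 1-bias) land on a rare codon
    synonymously.  The terminal stop may only wander among stop codons.
    """
    out = list(codons)
    L = 3 * len(out)
    last = len(out) - 1
    n_events = rng.poisson(t * L)
    bases = "ACGT"
    for _ in range(n_events):
        pos = int(rng.integers(L))
        ci, off = divmod(pos, 3)
        codon = out[ci]
        old = codon[off]
        others = [b for b in bases if b != old]
        w = np.array([kappa if _is_transition(old, b) else 1.0 for b in others])
        new = others[int(rng.choice(3, p=w / w.sum()))]
        cand = codon[:off] + new + codon[off + 1 :]
        if ci == last:
            if cand in _STOPS:
                out[ci] = cand
            continue
        if cand in _STOPS:
            continue
        if _CODON_TO_AA[cand] != _CODON_TO_AA[codon] and ci in invariant:
            continue
        # selection against rare codons applies to any move landing on one
        if cand in rare and rng.random() > bias:
            continue
        out[ci] = cand
    return out


def _evolve_along(node, codons, rng, invariant, rare, kappa, bias, out: dict):
    sub, bl = node
    evolved = _evolve(codons, bl, rng, invariant, rare, kappa, bias)
    if isinstance(sub, str):
        out[sub] = evolved
    else:
        for child in sub:
            _evolve_along(child, evolved, rng, invariant, rare, kappa, bias, out)


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    record: CodingSequenceRecord,
    mean_depth: float = 8.0,
    hole_probability: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[CoverageTrack, frozenset[int]]:
    """Per-base trace coverage, 1 + Poisson(mean_depth - 1) everywhere,
    with an optional contiguous zero-coverage hole.  Returns the track and
    the set of zeroed positions (empty when no hole was injected)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(record.cds_sequence)
    cov = 1 + rng.poisson(max(mean_depth - 1.0, 0.0), size=n)
    holes: frozenset[int] = frozenset()
    if rng.random() < hole_probability:
        length = int(rng.integers(10, max(11, n // 6 + 1)))
        start = int(rng.integers(0, n - length + 1))
        cov[start : start + length] = 0
        holes = frozenset(range(start, start + length))
    return CoverageTrack(record.id, tuple(int(c) for c in cov)), holes


# ---------------------------------------------------------------------------
# Misassembly injection

DEFECTS = ("inversion", "exon_loss", "reorder", "none")


def inject_misassembly(
    contig: GenomicContig,
    exon_model: Sequence[ExonSpan],
    defect: str,
    seed: int | np.random.Generator = 0,
) -> GenomicContig:
    """Return a copy of ``contig`` carrying one coding-exon misassembly.

    ``inversion`` reverse-complements one exon in place, ``exon_loss``
    deletes one exon span, ``reorder`` swaps the sequence content of two
    exon spans.  ``none`` returns the contig unchanged.
    """
    if defect == "none":
        return contig
    if defect not in DEFECTS:
        raise ValueError(f"unknown defect {defect!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spans = sorted(exon_model, key=lambda e: e.start)
    seq = contig.sequence
    if defect == "reorder" and len(spans) < 2:
        raise ValueError("reorder requires at least two exons")
    if defect == "inversion":
        e = spans[int(rng.integers(len(spans)))]
        seq = seq[: e.start] + revcomp(seq[e.start : e.end]) + seq[e.end :]
    elif defect == "exon_loss":
        e = spans[int(rng.integers(len(spans)))]
        seq = seq[: e.start] + seq[e.end :]
    else:  # reorder: swap two exon payloads (equal-length swap keeps spans valid)
        i, j = sorted(rng.choice(len(spans), size=2, replace=False))
        a, b = spans[int(i)], spans[int(j)]
        sa, sb = seq[a.start : a.end], seq[b.start : b.end]
        # place b's payload at a and vice versa; pad/trim not needed for detection
        seq = seq[: a.start] + sb + seq[a.end : b.start] + sa + seq[b.end :]
    return GenomicContig(contig.id, contig.taxon, seq, role=contig.role)


# ---------------------------------------------------------------------------
# Family simulation


def simulate_family(
    design: FamilyDesign, seed: int = 0
) -> tuple[list[CodingSequenceRecord], list[GenomicContig], list[CoverageTrack], SimulationTruth]:
    """Simulate a full gene family with contigs, coverage and truth.

    One ancestral protein per family evolves down a three-level hierarchy
    (family root -> supercluster ancestors -> cluster ancestors -> species
    tree leaves); coding sequences are split into each cluster's exon count
    and embedded in contigs with random intron/flank spacer.
    """
    rng = np.random.default_rng(seed)
    rare = _pick_rare_codons(rng, design.n_rare_codons)
    n_codons = int(rng.integers(design.protein_length_range[0], design.protein_length_range[1] + 1))
    n_inv = int(round(design.invariant_fraction * n_codons))
    # skip the terminal stop; the start codon may be designated invariant
    invariant = frozenset(int(i) for i in rng.choice(n_codons - 1, size=min(n_inv, n_codons - 1), replace=False))

    if tuple(design.taxa) == _DEFAULT_TAXA:
        scale = design.divergence_within / _DEFAULT_DEPTH
        tree = _scale_tree(_DEFAULT_TREE, scale)
    else:
        tree = _ladder_tree(tuple(design.taxa), design.divergence_within)
    newick = "(" + ",".join(_tree_newick(c) for c in tree[0]) + ");" if not isinstance(tree[0], str) else _tree_newick(tree) + ";"

    root = _ancestral_codons(rng, n_codons, rare, design.rare_codon_bias)
    exon_counts = design.exon_counts()

    records: list[CodingSequenceRecord] = []
    contigs: list[GenomicContig] = []
    tracks: list[CoverageTrack] = []
    membership: dict[str, tuple[str, str]] = {}
    holes_by_id: dict[str, frozenset[int]] = {}
    ev = dict(invariant=invariant, rare=rare, kappa=design.kappa, bias=design.rare_codon_bias)

    cluster_idx = 0
    for s, k_clusters in enumerate(design.clusters_per_supercluster):
        sc_name = str(s + 1)
        sc_anc = _evolve(root, design.divergence_between_superclusters / 2.0, rng, **ev)
        for c in range(k_clusters):
            cl_name = sc_name + chr(ord("A") + c)
            gene = f"GENE{cluster_idx + 1}"
            cl_anc = _evolve(sc_anc, design.divergence_between_clusters / 2.0, rng, **ev)
            leaves: dict[str, list[str]] = {}
            _evolve_along(tree, cl_anc, rng, out=leaves, **ev)
            n_exons = exon_counts[cluster_idx]
            cds_len = 3 * n_codons
            if n_exons * design.min_exon_bp > cds_len:
                raise ValueError(
                    f"cluster {cl_name}: {n_exons} exons of >= {design.min_exon_bp} bp "
                    f"do not fit a {cds_len} bp CDS"
                )
            extra = rng.multinomial(cds_len - n_exons * design.min_exon_bp, [1.0 / n_exons] * n_exons)
            exon_lens = [design.min_exon_bp + int(e) for e in extra]
            for taxon in design.taxa:
                cds = "".join(leaves[taxon])
                rid = f"{cl_name}_{taxon.replace(' ', '_')}"
                contig_id = rid + "_g"
                lo, hi = design.flank_length_range
                pieces = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, size=int(rng.integers(lo, hi + 1)))])]
                spans = []
                offset = 0
                pos = len(pieces[0])
                for x, elen in enumerate(exon_lens):
                    pieces.append(cds[offset : offset + elen])
                    spans.append(ExonSpan(contig_id, pos, pos + elen, "+"))
                    pos += elen
                    offset += elen
                    if x < n_exons - 1:
                        ilen = int(rng.integers(design.intron_length_range[0], design.intron_length_range[1] + 1))
                        pieces.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=ilen)]))
                        pos += ilen
                pieces.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=int(rng.integers(lo, hi + 1)))]))
                record = CodingSequenceRecord(
                    id=rid,
                    taxon=taxon,
                    cds_sequence=cds,
                    exon_model=tuple(spans),
                    gene_label=gene,
                )
                contig = GenomicContig(
                    contig_id,
                    taxon,
                    "".join(pieces),
                    role="base" if taxon == design.base_taxon else "target",
                )
                track, holes = simulate_coverage(
                    record, design.mean_depth, design.hole_probability, rng
                )
                records.append(record)
                contigs.append(contig)
                tracks.append(track)
                membership[rid] = (sc_name, cl_name)
                holes_by_id[rid] = holes
            cluster_idx += 1

    truth = SimulationTruth(
        species_tree=newick,
        cluster_membership=membership,
        invariant_site_positions=frozenset(p + 1 for p in invariant),
        rare_codon_set=rare,
        misassembly_injections={r.id: "none" for r in records},
        coverage_holes=holes_by_id,
    )
    return records, contigs, tracks, truth


def _scale_tree(node, scale: float):
    sub, bl = node
    if isinstance(sub, str):
        return (sub, bl * scale)
    return (tuple(_scale_tree(c, scale) for c in sub), bl * scale)
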