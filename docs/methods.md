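# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, in the order the pipeline runs them.

## Reliability classification

A record is *complete* iff every CDS nucleotide has coverage ≥ `min_depth`
(default 1: one supporting trace suffices; the stricter reading that
multiple independent traces are required is available by raising
`min_depth`). The verdict carries the exact set of uncovered positions, so
the classification is trivially monotone: adding coverage can only move a
record from putative to complete. Putative records are excluded from every
downstream stage.

## Pairwise genomic alignment and the contiguity test

The genomic aligner is a deterministic anchor-chaining aligner: exact
k-mer anchors (k = 12, both strands, seeds occurring more than 16 times in
the base skipped), greedy extraction of maximal co-linear chains by
weighted longest-increasing-subsequence, inter-anchor gaps filled by
global edit-distance alignment (edlib). Chains mixing orientations are
returned as separate orientation-homogeneous blocks; after a chain is
accepted, only anchors conflicting with its *matched* intervals are
retired, so sequence relocated elsewhere (an inverted or reordered exon)
remains available to form its own block. Extraction stops below a total
anchored length of 30 bp. Only the windowed-identity contract of the
alignment is consumed downstream, so the aligner is interchangeable with
any tool producing co-linear pairwise blocks.

Conserved regions are maximal runs of alignment columns in which **every**
window of the tier's length passes the tier's identity fraction (window
step 1; gap columns count as mismatches). The cutoff tiers are
per-target-taxon configuration with defaults 0.95/100 bp (Pan, Gorilla),
0.90 (Pongo, Nomascus), 0.85 (Macaca, Papio), 0.80 (Callithrix), 0.75
(Tarsius, Microcebus, Otolemur), 0.65 (Rodentia) and 0.70 otherwise.
Transposable elements are not masked.

An exon counts as conserved when it overlaps (≥ `min_overlap`, default
1 bp) a conserved segment in at least `min_targets` (default 1) target
alignments. Because a passing window tolerates `⌊w·(1−f)⌋` mismatches, a
segment can extend that many bases past the true end of homology; segment
ends are therefore shrunk by that margin before the overlap test —
without this guard, an exon deleted in a rodent-tier target (0.65/100:
35 bp of tolerated bleed) could still appear "conserved" through boundary
bleed alone. Orientation consistency uses the majority orientation of
exon-overlapping segments; order consistency requires the matched target
coordinates of the exons to be monotone per target. Defect hints follow
the signatures: orientation violation → inversion, order violation →
reorder, missing confirmation → missing exon. At rodent-level divergence
the sparse exact-anchor seeding sometimes degrades an inversion or
reorder hint to "missing exon"; the misassembly verdict itself is
unaffected.

## Codon-aware alignment

Translation uses the standard genetic code with stop codons rendered `&`
(they appear as alignment symbols, so terminal stops align like residues).
The progressive protein aligner uses 3-mer count distances, a UPGMA guide
tree (scipy average linkage), and profile–profile global dynamic
programming with BLOSUM62, gap open 10, gap extend 0.5 (a gap of length L
costs open + (L−1)·extend); ties resolve diagonal > up > left, making the
output deterministic. Codon threading expands each aligned amino acid to
its source codon and asserts the de-gap invariant (every row reproduces
its CDS exactly) on every construction, including imported curated
alignments, which are validated rather than repaired.

The aligner is intentionally modest: at saturating divergence (protein
identity near the random floor) no automatic aligner reproduces manually
curated homology. Analyses that depend on exact column homology across a
deeply diverged family (family-wide site classification in the acceptance
script and tests) therefore run on the simulator's gapless homology, which
is exact by construction; the progressive aligner carries its own tests at
divergences where alignment is well-posed.

## Distances, trees, identity patterns

Pairwise identity is matches over compared columns with pairwise deletion
(columns gapped in either row are excluded; a pair with zero comparable
columns is reported missing and excluded from statistics). The summary
statistics are the mean ā, average absolute deviation ā_ad, and extremes
a_max/a_min over all unordered pairs.

Distances follow TN93 with empirical base frequencies pooled over the
alignment. With joint estimation enabled, the two transition/transversion
rate ratios are shared across pairs and fitted by maximising the composite
log-likelihood (Nelder–Mead over the log-ratios; per-pair distances are
inner profile maximisers on [1e-9, 10]); with two sequences this reduces
to the per-pair maximum-likelihood estimate. The closed-form per-pair TN93
estimator is the fallback and the bootstrap workhorse (joint optimisation
inside every replicate would dominate runtime without changing supports
noticeably). Saturated pairs (log argument ≤ 0, or a distance hitting the
optimiser bound) are reported missing; affected taxa are dropped from the
tree with a logged warning, worst-offender first.

Trees start from deterministic neighbor joining (ties broken by lowest
index) and are refined by close-neighbor-interchange: for each internal
edge both nearest-neighbor interchanges are evaluated by re-fitting
ordinary-least-squares branch lengths (lstsq on the path-incidence
system), accepting the first swap that lowers the total branch length;
the trajectory of totals is exposed and is non-increasing by
construction. Bootstrap resamples nucleotide columns with replacement,
re-runs distances and tree search, and counts bipartitions; internal
branches of zero OLS length are treated as unresolved when counting, so
deterministic tie-breaking cannot inflate supports on uninformative data.
Branches under the collapse threshold (default 50%, after the
conventional 1000 replicates) are contracted in the collapsed tree.

Identity-pattern bins (very close ≥ 0.85 > close ≥ 0.75 > typical ≥ 0.60 >
distant ≥ 0.45 > very distant) are explicit configuration: the category
names are standard but no published boundary values exist for them, so
these defaults are this package's choice and every reported label can be
re-derived under user-supplied bins.

Cluster assignment takes the known gene labels (every orthologue of one
gene shares a label), checks each label's monophyly against the collapsed
tree (violations are flagged, never merged), and groups clusters into
superclusters by single-linkage clustering of mean inter-cluster path
distances, cut at the largest gap between consecutive merge heights — a
threshold-free rule that recovers well-separated divergence scales; with
fewer than three clusters everything falls into one supercluster.
Superclusters are numbered by size (descending, ties by traversal order)
and members lettered A, B, C… by post-order appearance; the lettering rule
is a determinism device, not a biological claim.

## RSCU and site classes

For each synonymous family the expected count of every codon is the family
total divided by the family size, so R = counts/expected averages to
exactly 1 over every family with a nonzero total; single-codon families
(ATG, TGG) have R ≡ 1 and can never be not-preferable. Stop codons are
tabulated but never classified. The not-preferable threshold defaults to
R ≤ 0.7.

Site classes are reference-anchored: a column where the reference is
gapped is skipped (logged); other rows' gaps are ignored per column. A
column is invariant iff exactly one amino acid is observed among non-gap
rows; variant columns are forward or compensatory according to whether any
aligned codon — in any row, reference included — is not-preferable.
Raising the threshold can only grow the not-preferable set, hence never
converts a compensatory site to forward.

Landmarks: common cysteines are columns universally C; splice-site
positions place an exon's boundary at the codon containing its last base
(a codon split by an intron belongs to the upstream exon), so an n-exon
gene contributes n−1 positions and "common" requires the same column in
every member; N-glycosylation sites use the canonical N-X-[S/T] (X ≠ P)
sequon rule (pluggable — no external predictor is bundled).

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, at
study-like scale: 8 superclusters holding (4, 2, 1, 3, 4, 3, 2, 3) = 22
major gene clusters, a 10-taxon eutherian panel spanning every cutoff
tier, one family protein length drawn from 190–250 codons (mean ≈ 220),
five coding exons in the first supercluster's clusters plus one more and
three elsewhere, and a coverage-hole probability of 0.5 (about half of
potential records fail reliability, matching the curation yield such
protocols report).

Sequences evolve down a three-level hierarchy — family root →
supercluster ancestors (branch 1.6/2 substitutions/site) → cluster
ancestors (0.6/2) → species-tree leaves (ultrametric tree of depth 0.07
with realistic relative depths: Pan at ~0.006 pairwise from Homo, rodents
at ~0.12) — under per-site nucleotide proposals with transition bias
κ = 2, rejected when they create a premature stop or change a designed
invariant site's amino acid; any proposal landing on a designed rare
codon is accepted only with probability `rare_codon_bias` (0.15), which
keeps rare codons depleted (R well under the 0.7 threshold) even though
amino-acid replacement traffic would otherwise repopulate them. The
terminal stop codon may only wander among stop codons. Invariant
positions are 8% of sites, shared family-wide; the 20 designed rare
codons are drawn only from families with at least two synonymous
alternatives, at most half of any family. Introns and flanks are i.i.d.
uniform nucleotides (the contiguity test consumes only identity windows,
so no splice-signal realism is needed). Coverage is 1 + Poisson(depth−1)
per base — mean `mean_depth`, never spuriously zero — with an optional
contiguous zeroed run recorded in the truth.

What the generator does **not** emulate: insertions/deletions (all
homologous sequences are equal length, so alignment columns are exact and
whole-family mean identity saturates near 0.36–0.46 rather than the ~0.3
with minima near 0.1 seen in real curated families, where gaps and length
variation push pairwise identities lower), rate heterogeneity across
sites beyond the invariant class, codon-position structure, GC/isochore
variation, and splice-site or repeat realism. Passing recovery tests
therefore demonstrates correctness of the *inference machinery* under the
assumed generative structure, not robustness to alignment error or indel
evolution on real data.

## Problem sizes and seeds

The test suite and the acceptance script run at sizes chosen to exercise
every code path at full fidelity: the full 22-cluster, 10-taxon design for
reliability, codon usage, identity statistics, site recovery and
landmarks; 10–20 single-cluster orthologue sets for contiguity injection
and false-flag rates; a 2 × 2 × 5 design with 100–200 bootstrap
replicates for tree recovery (supports at these sizes sit comfortably
above the 50% collapse threshold); and 1200-bp Jukes–Cantor pairs at a
true distance of 0.2 for the distance estimator, judged against the
analytic delta-method standard error. All randomness flows through
`numpy.random.default_rng` seeded from the single `--seed` argument, and
identical (design, seed) pairs give byte-identical simulator output.

## Known limitations

- The progressive aligner has no iterative refinement and will not match
  hand-curated alignments at saturating divergence (see above); the
  import path exists precisely for curated alignments.
- Composite-likelihood rate estimation assumes one shared rate pair for
  the whole alignment; lineage-specific rate variation is not modelled.
- Supercluster derivation by largest-gap single linkage assumes the
  within/between divergence scales are separated; on continuous radiations
  it will still cut somewhere, and the result should be read as a
  deterministic proposal, not an inference with support values.
- The contiguity test assumes the base gene's exon model is correct;
  errors in the base annotation itself are out of scope.
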