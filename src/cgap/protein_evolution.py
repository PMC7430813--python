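"""Tests of protein molecular evolution.

Relative synonymous codon usage (R = observed / expected counts, expected
being equal usage within each synonymous family), the not-preferable codon
set (R <= threshold, default 0.7), reference-anchored classification of
alignment positions into invariant / forward / compensatory amino-acid
sites, and extraction of protein-alignment landmarks (common cysteines,
common exon-intron splice-site positions, common N-glycosylation sequons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .msa import CodonAlignment, GAP_CODON, STOP_SYMBOL, _CODON_TO_AA
from .records import CodingSequenceRecord

log = logging.getLogger("cgap")

#: synonymous families over the 61 sense codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in sorted(_CODON_TO_AA):
    _aa = _CODON_TO_AA[_codon]
    if _aa != STOP_SYMBOL:
        FAMILIES.setdefault(_aa, ())
        FAMILIES[_aa] = FAMILIES[_aa] + (_codon,)

SENSE_CODONS = tuple(c for fam in FAMILIES.values() for c in fam)
STOP_CODONS = tuple(c for c, aa in _CODON_TO_AA.items() if aa == STOP_SYMBOL)


@dataclass
class RSCUTable:
    """Observed and expected codon counts with R = counts / expected.

    Within each synonymous family the expected count is the family total
    divided by the family size, so R averages to 1 over every family with a
    nonzero total.  Stop codons are tabulated but never classified
    not-preferable.
    """

    counts: dict[str, int]
    expected: dict[str, float]
    R: dict[str, float]
    threshold: float
    not_preferable: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.not_preferable = frozenset(
            c for c, r in self.R.items() if r <= self.threshold and self.counts_family_total(c) > 0
        )

    def counts_family_total(self, codon: str) -> int:
        fam = FAMILIES[_CODON_TO_AA[codon]]
        return sum(self.counts.get(c, 0) for c in fam)


def codon_usage(
    source: CodonAlignment | Iterable[CodingSequenceRecord] | Iterable[str],
    threshold: float = 0.7,
) -> RSCUTable:
    """Relative synonymous codon usage over a set of coding sequences.

    Accepts a codon alignment (gaps skipped), coding-sequence records, or
    raw CDS strings.
    """
    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    stop_counts: dict[str, int] = {c: 0 for c in STOP_CODONS}
    for codon in _iter_codons(source):
        if codon in counts:
            counts[codon] += 1
        elif codon in stop_counts:
            stop_counts[codon] += 1
    expected: dict[str, float] = {}
    R: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts[c] for c in fam)
        exp = total / len(fam)
        for c in fam:
            expected[c] = exp
            R[c] = counts[c] / exp if exp > 0 else 0.0
    table = RSCUTable({**counts, **stop_counts}, expected, R, threshold)
    log.debug(
        "RSCU over %d codons: %d not-preferable at R <= %g",
        sum(counts.values()),
        len(table.not_preferable),
        threshold,
    )
    return table


def _iter_codons(source):
    if isinstance(source, CodonAlignment):
        for row in source.codon_rows.values():
            for cell in row:
                if cell != GAP_CODON:
                    yield cell
        return
    for item in source:
        cds = item.cds_sequence if isinstance(item, CodingSequenceRecord) else str(item)
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            yield cds[i : i + 3]


# ---------------------------------------------------------------------------
# Site classification


@dataclass(frozen=True)
class SiteClass:
    reference_position: int  # 1-based amino-acid position in the reference
    label: str  # invariant | forward | compensatory
    amino_acids: frozenset[str]
    has_not_preferable: bool


@dataclass
class SiteClassification:
    reference_id: str
    sites: list[SiteClass]

    def positions(self, label: str) -> list[int]:
        return [s.reference_position for s in self.sites if s.label == label]

    def label_of(self, position: int) -> Optional[str]:
        for s in self.sites:
            if s.reference_position == position:
                return s.label
        return None


def classify_sites(
    aln: CodonAlignment,
    reference_id: str,
    rscu: RSCUTable,
) -> SiteClassification:
    """Classify reference-anchored alignment columns.

    A site is *invariant* when exactly one amino acid is observed across
    all non-gap rows of its column; otherwise it is *forward* if no aligned
    codon belongs to the not-preferable set and *compensatory* if at least
    one does.  Columns where the reference is gapped are skipped (logged);
    other rows' gaps are ignored per column.
    """
    if reference_id not in aln.codon_rows:
        raise KeyError(f"reference record {reference_id!r} absent from alignment")
    ref_map = aln.reference_map(reference_id)
    sites: list[SiteClass] = []
    for col, ref_pos in enumerate(ref_map):
        if ref_pos is None:
            log.debug("column %d skipped: reference gapped", col)
            continue
        cells = [aln.codon_rows[rid][col] for rid in aln.record_ids]
        codons = [c for c in cells if c != GAP_CODON]
        aas = frozenset(_CODON_TO_AA[c] for c in codons)
        if len(aas) == 1:
            label = "invariant"
            has_np = any(c in rscu.not_preferable for c in codons)
        else:
            has_np = any(c in rscu.not_preferable for c in codons)
            label = "compensatory" if has_np else "forward"
        sites.append(SiteClass(ref_pos, label, aas, has_np))
    return SiteClassification(reference_id, sites)


# ---------------------------------------------------------------------------
# Landmarks


@dataclass
class LandmarkSet:
    cluster_label: str
    common_cysteines: tuple[int, ...]  # alignment columns (0-based)
    common_splice_sites: tuple[int, ...]
    common_nglyc: tuple[int, ...]


def splice_boundary_positions(record: CodingSequenceRecord) -> list[int]:
    """0-based protein positions of exon-intron boundaries.

    The boundary position is the index of the codon containing the exon's
    last (full or partial) base; a codon split by an intron is attributed
    to the upstream exon.  A gene with n exons has n-1 boundaries.
    """
    out = []
    offset = 0
    for exon in record.exon_model[:-1]:
        offset += exon.length
        out.append((offset - 1) // 3)
    return out


def _sequon_starts(protein: str) -> list[int]:
    """0-based start positions of N-X-[S/T] sequons with X != P."""
    hits = []
    for i in range(len(protein) - 2):
        if (
            protein[i] == "N"
            and protein[i + 1] != "P"
            and protein[i + 2] in ("S", "T")
        ):
            hits.append(i)
    return hits


def extract_landmarks(
    aln: CodonAlignment,
    records: Iterable[CodingSequenceRecord],
    cluster_label: str = "",
    members: Optional[Sequence[str]] = None,
) -> LandmarkSet:
    """Landmarks common to every member of a cluster alignment.

    Common cysteines: columns where every member has C.  Common splice
    sites: columns hosting an exon-intron boundary at the homologous
    position in every member.  Common N-glycosylation sites: columns where
    every member starts an N-X-[S/T] (X != P) sequon.
    """
    rec_map = {r.id: r for r in records}
    ids = list(members) if members is not None else list(aln.record_ids)
    prot = aln.protein_rows()
    n_cols = aln.n_columns

    def res_to_col(rid: str) -> dict[int, int]:
        out = {}
        k = 0
        for col, aa in enumerate(prot[rid]):
            if aa != "-":
                out[k] = col
                k += 1
        return out

    maps = {rid: res_to_col(rid) for rid in ids}

    cys = [
        col
        for col in range(n_cols)
        if all(prot[rid][col] == "C" for rid in ids)
    ]

    splice_cols: Optional[set[int]] = None
    for rid in ids:
        rec = rec_map.get(rid)
        if rec is None:
            continue
        cols = {maps[rid][p] for p in splice_boundary_positions(rec) if p in maps[rid]}
        splice_cols = cols if splice_cols is None else (splice_cols & cols)
    splice_cols = splice_cols or set()

    nglyc: Optional[set[int]] = None
    for rid in ids:
        seq = prot[rid].replace("-", "")
        cols = {maps[rid][p] for p in _sequon_starts(seq)}
        nglyc = cols if nglyc is None else (nglyc & cols)
    nglyc = nglyc or set()

    return LandmarkSet(
        cluster_label=cluster_label,
        common_cysteines=tuple(sorted(cys)),
        common_splice_sites=tuple(sorted(splice_cols)),
        common_nglyc=tuple(sorted(nglyc)),
    )
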