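"""Core record types shared by every stage of the analysis protocol.

Coordinates are 0-based half-open internally; the GFF3 boundary converts
to and from the 1-based closed convention of the file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Optional

_DNA = set("ACGT")
_DNA_N = set("ACGTN")

STATUS_POTENTIAL = "potential"
STATUS_COMPLETE = "complete"
STATUS_PUTATIVE = "putative"
UNKNOWN = "unknown"


class ExonSpan(NamedTuple):
    """One coding-exon span on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CodingSequenceRecord:
    """A potential/complete/putative coding sequence with its exon model.

    ``cds_sequence`` is the spliced coding sequence in translation order
    (minus-strand exons already reverse-complemented); ``exon_model`` lists
    the genomic exon spans in transcript (5'->3') order.
    """

    id: str
    taxon: str
    cds_sequence: str
    exon_model: tuple[ExonSpan, ...]
    cluster_label: str = UNKNOWN
    supercluster_label: str = UNKNOWN
    gene_label: str = UNKNOWN
    status: str = STATUS_POTENTIAL

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        self.exon_model = tuple(ExonSpan(*e) for e in self.exon_model)
        self.validate()

    def validate(self) -> None:
        n = len(self.cds_sequence)
        if n == 0 or n % 3 != 0:
            raise ValueError(
                f"record {self.id}: CDS length {n} is not a positive multiple of 3"
            )
        bad = set(self.cds_sequence) - _DNA
        if bad:
            raise ValueError(f"record {self.id}: non-ACGT symbols {sorted(bad)}")
        if not self.exon_model:
            raise ValueError(f"record {self.id}: empty exon model")
        total = sum(e.length for e in self.exon_model)
        if total != n:
            raise ValueError(
                f"record {self.id}: exon spans sum to {total}, CDS length is {n}"
            )
        for e in self.exon_model:
            if e.start < 0 or e.end <= e.start:
                raise ValueError(f"record {self.id}: invalid exon span {e}")
            if e.strand not in "+-":
                raise ValueError(f"record {self.id}: invalid strand {e.strand!r}")
        # non-overlap within each contig
        by_contig: dict[str, list[ExonSpan]] = {}
        for e in self.exon_model:
            by_contig.setdefault(e.contig_id, []).append(e)
        for spans in by_contig.values():
            spans = sorted(spans, key=lambda e: e.start)
            for a, b in zip(spans, spans[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"record {self.id}: overlapping exon spans {a} and {b}"
                    )
        if self.status not in (STATUS_POTENTIAL, STATUS_COMPLETE, STATUS_PUTATIVE):
            raise ValueError(f"record {self.id}: invalid status {self.status!r}")

    @property
    def n_exons(self) -> int:
        return len(self.exon_model)

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def with_status(self, status: str) -> "CodingSequenceRecord":
        return replace(self, status=status)


@dataclass
class CoverageTrack:
    """Per-nucleotide sequencing-trace coverage over a CDS span."""

    record_id: str
    coverage: tuple[int, ...]

    def __post_init__(self) -> None:
        self.coverage = tuple(int(c) for c in self.coverage)
        if any(c < 0 for c in self.coverage):
            raise ValueError(f"track {self.record_id}: negative coverage")

    def __len__(self) -> int:
        return len(self.coverage)


@dataclass
class GenomicContig:
    """A genomic sequence used as base or target in pairwise alignment."""

    id: str
    taxon: str
    sequence: str
    role: str = "base"  # 'base' or 'target'

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.sequence) - _DNA_N
        if bad:
            raise ValueError(f"contig {self.id}: non-ACGTN symbols {sorted(bad)}")
        if self.role not in ("base", "target"):
            raise ValueError(f"contig {self.id}: invalid role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


#: Empirically determined windowed-identity cutoffs for detection of common
#: genomic regions in pairwise alignments against the base genome, keyed by
#: taxon or taxonomic group; the last entry is the fallback tier.
DEFAULT_CONTIGUITY_CUTOFFS: dict[str, tuple[float, int]] = {
    "Pan troglodytes": (0.95, 100),
    "Gorilla gorilla": (0.95, 100),
    "Pongo abelii": (0.90, 100),
    "Nomascus leucogenys": (0.90, 100),
    "Macaca mulatta": (0.85, 100),
    "Papio hamadryas": (0.85, 100),
    "Callithrix jacchus": (0.80, 100),
    "Tarsius syrichta": (0.75, 100),
    "Microcebus murinus": (0.75, 100),
    "Otolemur garnettii": (0.75, 100),
    "Rodentia": (0.65, 100),
    "default": (0.70, 100),
}

#: Taxa resolved to the Rodentia tier when not listed individually.
RODENTIA = frozenset(
    {
        "Mus musculus",
        "Rattus norvegicus",
        "Cavia porcellus",
        "Ictidomys tridecemlineatus",
        "Spermophilus tridecemlineatus",
        "Dipodomys ordii",
        "Heterocephalus glaber",
        "Cricetulus griseus",
        "Mesocricetus auratus",
        "Microtus ochrogaster",
        "Peromyscus maniculatus",
        "Jaculus jaculus",
        "Octodon degus",
        "Chinchilla lanigera",
    }
)

#: Identity-pattern bin boundaries (lower bounds, scanned in order).  The
#: category names follow the field's usage; the numeric boundaries are
#: configuration, not published constants.
DEFAULT_IDENTITY_BINS: tuple[tuple[str, float], ...] = (
    ("very_close", 0.85),
    ("close", 0.75),
    ("typical", 0.60),
    ("distant", 0.45),
    ("very_distant", 0.0),
)


@dataclass
class ProtocolConfig:
    """Tunable constants of the protocol with their published defaults."""

    contiguity_cutoffs: Mapping[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_CONTIGUITY_CUTOFFS)
    )
    rscu_threshold: float = 0.7
    bootstrap_replicates: int = 1000
    bootstrap_collapse: float = 50.0
    identity_pattern_bins: tuple[tuple[str, float], ...] = DEFAULT_IDENTITY_BINS
    min_depth: int = 1
    min_overlap: int = 1
    min_targets: int = 1
    random_seed: int = 0

    def __post_init__(self) -> None:
        for key, (frac, window) in self.contiguity_cutoffs.items():
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"cutoff for {key!r}: identity {frac} not in (0,1]")
            if window < 1:
                raise ValueError(f"cutoff for {key!r}: window {window} < 1")
        if not (0.0 < self.rscu_threshold < 1.0):
            raise ValueError("rscu_threshold must be in (0,1)")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not (0.0 <= self.bootstrap_collapse <= 100.0):
            raise ValueError("bootstrap_collapse must be a percentage")


def cutoff_for(taxon: str, config: Optional[ProtocolConfig] = None) -> tuple[float, int]:
    """Resolve the windowed-identity detection cutoff for a target taxon.

    Lookup order: exact taxon name, then Rodentia group membership, then the
    fallback tier; no taxon is ever unresolvable.
    """
    table = (config or ProtocolConfig()).contiguity_cutoffs
    if taxon in table:
        return tuple(table[taxon])
    if taxon in RODENTIA and "Rodentia" in table:
        return tuple(table["Rodentia"])
    return tuple(table["default"])


def filter_complete(records: Iterable[CodingSequenceRecord]) -> list[CodingSequenceRecord]:
    """Keep records that passed the reliability test (putative ones are
    excluded from all analyses)."""
    return [r for r in records if r.status == STATUS_COMPLETE]
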