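"""Aggregate stage outputs into cluster-level and per-record reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .contiguity import ContiguityVerdict
from .phylo import IdentityStats, classify_pattern
from .records import CodingSequenceRecord, DEFAULT_IDENTITY_BINS
from .reliability import ReliabilityVerdict

log = logging.getLogger("cgap")


@dataclass
class ClusterSummary:
    name: str
    supercluster: str
    n_members: int
    exon_count: Optional[int]  # None when heterogeneous
    exon_count_flagged: bool
    identity_pattern: Optional[str]


@dataclass
class ClusterReport:
    clusters: list[ClusterSummary]
    superclusters: dict[str, list[str]]  # supercluster -> member cluster names
    per_record: pd.DataFrame
    summary_text: str = field(default="")

    @property
    def n_records(self) -> int:
        return int(len(self.per_record))


def build_report(
    records: Iterable[CodingSequenceRecord],
    cluster_labels: Mapping[str, tuple[str, str]],
    reliability: Optional[Mapping[str, ReliabilityVerdict]] = None,
    contiguity: Optional[Mapping[str, ContiguityVerdict]] = None,
    identity_by_cluster: Optional[Mapping[str, IdentityStats]] = None,
    bins=DEFAULT_IDENTITY_BINS,
) -> ClusterReport:
    """Reconcile all stage outputs into one deterministic report.

    Member counts sum to the record count; a cluster whose members disagree
    on coding-exon number is flagged as a potential differential expansion
    or misassembly.  Stage outputs referencing unknown record ids are a
    hard error.
    """
    records = list(records)
    known = {r.id for r in records}
    for name, mapping in (
        ("cluster labels", cluster_labels),
        ("reliability", reliability or {}),
        ("contiguity", contiguity or {}),
    ):
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"{name} reference unknown record ids: {sorted(unknown)}")

    members: dict[str, list[CodingSequenceRecord]] = {}
    sc_of: dict[str, str] = {}
    for rec in records:
        sc, cl = cluster_labels.get(rec.id, ("unassigned", "unassigned"))
        members.setdefault(cl, []).append(rec)
        sc_of[cl] = sc

    clusters: list[ClusterSummary] = []
    superclusters: dict[str, list[str]] = {}
    for cl in sorted(members):
        recs = members[cl]
        exon_counts = {r.n_exons for r in recs}
        flagged = len(exon_counts) > 1
        if flagged:
            log.warning("cluster %s: heterogeneous exon counts %s", cl, sorted(exon_counts))
        pattern = None
        if identity_by_cluster and cl in identity_by_cluster:
            pattern = classify_pattern(
                identity_by_cluster[cl].a_bar, level="orthologue", bins=bins
            ).category
        clusters.append(
            ClusterSummary(
                name=cl,
                supercluster=sc_of[cl],
                n_members=len(recs),
                exon_count=None if flagged else next(iter(exon_counts)),
                exon_count_flagged=flagged,
                identity_pattern=pattern,
            )
        )
        superclusters.setdefault(sc_of[cl], []).append(cl)

    rows = []
    for rec in records:
        sc, cl = cluster_labels.get(rec.id, ("unassigned", "unassigned"))
        rel = (reliability or {}).get(rec.id)
        ctg = (contiguity or {}).get(rec.id)
        rows.append(
            {
                "record_id": rec.id,
                "taxon": rec.taxon,
                "supercluster": sc,
                "cluster": cl,
                "n_exons": rec.n_exons,
                "n_codons": rec.n_codons,
                "status": rel.status if rel else rec.status,
                "contiguity": ctg.verdict if ctg else "",
                "defect_hint": (ctg.defect_hint or "") if ctg else "",
            }
        )
    per_record = pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "taxon",
            "supercluster",
            "cluster",
            "n_exons",
            "n_codons",
            "status",
            "contiguity",
            "defect_hint",
        ],
    )

    n_sc = len(superclusters)
    lines = [
        f"{len(records)} records in {len(clusters)} major gene clusters "
        f"across {n_sc} superclusters",
    ]
    for summary in clusters:
        exons = summary.exon_count if summary.exon_count is not None else "heterogeneous!"
        pat = f", {summary.identity_pattern}" if summary.identity_pattern else ""
        lines.append(
            f"  {summary.name} (supercluster {summary.supercluster}): "
            f"{summary.n_members} members, {exons} coding exons{pat}"
        )
    report = ClusterReport(clusters, superclusters, per_record, "\n".join(lines))
    assert sum(c.n_members for c in report.clusters) == len(records)
    return report
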