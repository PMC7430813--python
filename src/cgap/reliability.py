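"""Test of reliability: complete vs putative coding sequences.

A potential coding sequence is *complete* when sequencing-trace coverage is
available for every CDS nucleotide, *putative* otherwise; putative records
are excluded from all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from .records import (
    CodingSequenceRecord,
    CoverageTrack,
    STATUS_COMPLETE,
    STATUS_PUTATIVE,
)

log = logging.getLogger("cgap")


@dataclass(frozen=True)
class ReliabilityVerdict:
    record_id: str
    status: str  # complete | putative
    uncovered_positions: tuple[int, ...]  # 0-based CDS positions

    def __post_init__(self) -> None:
        complete = self.status == STATUS_COMPLETE
        if complete != (len(self.uncovered_positions) == 0):
            raise ValueError(
                f"{self.record_id}: status {self.status} inconsistent with "
                f"{len(self.uncovered_positions)} uncovered positions"
            )


class ReliabilitySummary(NamedTuple):
    n_potential: int
    n_complete: int
    n_putative: int


def classify_reliability(
    record: CodingSequenceRecord,
    track: CoverageTrack,
    min_depth: int = 1,
) -> ReliabilityVerdict:
    """Classify one record from its per-nucleotide coverage track.

    Complete iff every CDS position has coverage >= ``min_depth`` (default:
    one trace suffices).  A track whose length differs from the CDS is a
    hard error naming the record.
    """
    if len(track) != len(record.cds_sequence):
        raise ValueError(
            f"record {record.id}: coverage track length {len(track)} != "
            f"CDS length {len(record.cds_sequence)}"
        )
    uncovered = tuple(i for i, c in enumerate(track.coverage) if c < min_depth)
    status = STATUS_COMPLETE if not uncovered else STATUS_PUTATIVE
    log.debug("reliability %s: %s (%d uncovered)", record.id, status, len(uncovered))
    return ReliabilityVerdict(record.id, status, uncovered)


def classify_batch(
    records: Iterable[CodingSequenceRecord],
    tracks: Mapping[str, CoverageTrack] | Iterable[CoverageTrack],
    min_depth: int = 1,
) -> tuple[list[CodingSequenceRecord], list[ReliabilityVerdict]]:
    """Classify every record and return updated records plus verdicts."""
    if not isinstance(tracks, Mapping):
        tracks = {t.record_id: t for t in tracks}
    out_records, verdicts = [], []
    for rec in records:
        if rec.id not in tracks:
            raise KeyError(f"no coverage track for record {rec.id}")
        verdict = classify_reliability(rec, tracks[rec.id], min_depth)
        verdicts.append(verdict)
        out_records.append(rec.with_status(verdict.status))
    return out_records, verdicts


def summarize_reliability(verdicts: Iterable[ReliabilityVerdict]) -> ReliabilitySummary:
    verdicts = list(verdicts)
    n_complete = sum(1 for v in verdicts if v.status == STATUS_COMPLETE)
    return ReliabilitySummary(len(verdicts), n_complete, len(verdicts) - n_complete)
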