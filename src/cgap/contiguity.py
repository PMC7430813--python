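"""Test of contiguity: conserved coding-exon regions in pairwise genomic
alignments, exon number / orientation / order verification, misassembly
flags.

The pairwise genomic aligner is a deterministic anchor-chaining aligner:
exact k-mer anchors on both strands, greedy extraction of maximal
co-linear chains (weighted longest-increasing-subsequence), inter-anchor
gaps filled by global edit-distance alignment (edlib).  Conserved regions
are maximal runs of alignment columns in which every window of the
taxon-tier length passes the tier's identity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .records import (
    CodingSequenceRecord,
    ExonSpan,
    GenomicContig,
    ProtocolConfig,
    cutoff_for,
)
from .simulate import revcomp

log = logging.getLogger("cgap")


@dataclass(frozen=True)
class Anchor:
    base_start: int
    pos: int  # position in the scanned sequence (target or its revcomp)
    length: int
    strand: str  # '+' or '-'


@dataclass
class AlignmentBlock:
    """One orientation-homogeneous co-linear block of a pairwise alignment.

    ``base_cols``/``target_cols`` give, per alignment column, the 0-based
    coordinate on the base / forward-strand target (or -1 at gaps).
    """

    aligned_base: str
    aligned_target: str
    base_cols: np.ndarray
    target_cols: np.ndarray
    orientation: str  # 'forward' | 'reverse'

    @property
    def base_span(self) -> tuple[int, int]:
        cols = self.base_cols[self.base_cols >= 0]
        return int(cols.min()), int(cols.max()) + 1

    @property
    def target_span(self) -> tuple[int, int]:
        cols = self.target_cols[self.target_cols >= 0]
        return int(cols.min()), int(cols.max()) + 1


@dataclass(frozen=True)
class ConservedSegment:
    base_start: int
    base_end: int
    target_start: int
    target_end: int
    orientation: str
    mean_identity: float


@dataclass(frozen=True)
class ContiguityVerdict:
    record_id: str
    expected_exons: int
    conserved_exons: int
    orientations_consistent: bool
    order_consistent: bool
    verdict: str  # 'consistent' | 'misassembly'
    defect_hint: Optional[str] = None  # inversion | missing_exon | reorder


# ---------------------------------------------------------------------------
# Anchors and chains


def _find_anchors(base: str, scanned: str, strand: str, k: int) -> list[Anchor]:
    index: dict[str, list[int]] = {}
    for i in range(len(base) - k + 1):
        kmer = base[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    raw: dict[int, list[tuple[int, int]]] = {}  # diagonal -> [(b, p)]
    for p in range(len(scanned) - k + 1):
        kmer = scanned[p : p + k]
        hits = index.get(kmer)
        if not hits or len(hits) > 16:  # skip highly repetitive seeds
            continue
        for b in hits:
            raw.setdefault(b - p, []).append((b, p))
    anchors: list[Anchor] = []
    for diag, items in raw.items():
        items.sort()
        cur_b, cur_p = items[0]
        cur_end = cur_b + k
        for b, p in items[1:]:
            if b <= cur_end:  # overlap/adjacent on the same diagonal
                cur_end = max(cur_end, b + k)
            else:
                anchors.append(Anchor(cur_b, cur_p, cur_end - cur_b, strand))
                cur_b, cur_p, cur_end = b, p, b + k
        anchors.append(Anchor(cur_b, cur_p, cur_end - cur_b, strand))
    return anchors


def _weighted_lis(anchors: list[Anchor]) -> list[Anchor]:
    """Best co-linear chain (increasing base and scan positions, no
    overlap), maximizing total anchored length."""
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a.base_start, a.pos))
    n = len(anchors)
    score = [a.length for a in anchors]
    back = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            if (
                aj.base_start + aj.length <= ai.base_start
                and aj.pos + aj.length <= ai.pos
                and score[j] + ai.length > score[i]
            ):
                score[i] = score[j] + ai.length
                back[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = back[best]
    return chain[::-1]


def _stitch(chain: list[Anchor], base: str, scanned: str) -> tuple[str, str]:
    """Build an explicit pairwise alignment over the chain's span."""
    parts_b: list[str] = []
    parts_t: list[str] = []
    for i, a in enumerate(chain):
        if i > 0:
            prev = chain[i - 1]
            gb = base[prev.base_start + prev.length : a.base_start]
            gt = scanned[prev.pos + prev.length : a.pos]
            if gb and gt:
                res = edlib.align(gb, gt, mode="NW", task="path")
                nice = edlib.getNiceAlignment(res, gb, gt)
                parts_b.append(nice["query_aligned"])
                parts_t.append(nice["target_aligned"])
            elif gb:
                parts_b.append(gb)
                parts_t.append("-" * len(gb))
            elif gt:
                parts_b.append("-" * len(gt))
                parts_t.append(gt)
        seg = base[a.base_start : a.base_start + a.length]
        parts_b.append(seg)
        parts_t.append(scanned[a.pos : a.pos + a.length])
    return "".join(parts_b), "".join(parts_t)


def _block_from_chain(
    chain: list[Anchor], base: str, target: str, scanned: str, strand: str
) -> AlignmentBlock:
    ab, at = _stitch(chain, base, scanned)
    L = len(ab)
    base_cols = np.full(L, -1, dtype=np.int64)
    scan_cols = np.full(L, -1, dtype=np.int64)
    b = chain[0].base_start
    p = chain[0].pos
    for i in range(L):
        if ab[i] != "-":
            base_cols[i] = b
            b += 1
        if at[i] != "-":
            scan_cols[i] = p
            p += 1
    if strand == "+":
        target_cols = scan_cols
        orientation = "forward"
    else:
        target_cols = np.where(scan_cols >= 0, len(target) - 1 - scan_cols, -1)
        orientation = "reverse"
    return AlignmentBlock(ab, at, base_cols, target_cols, orientation)


def pairwise_genomic_align(
    base: GenomicContig,
    target: GenomicContig,
    k: int = 12,
    min_chain: int = 30,
) -> list[AlignmentBlock]:
    """Co-linear alignment chain between two genomic contigs.

    Anchors are sought on both strands; chains mixing orientations are
    returned as separate orientation-homogeneous blocks.  An empty list is
    a valid result (no homology detected).
    """
    bseq, tseq = base.sequence, target.sequence
    rc = revcomp(tseq)
    anchors = _find_anchors(bseq, tseq, "+", k) + _find_anchors(bseq, rc, "-", k)
    blocks: list[AlignmentBlock] = []
    pool = anchors
    while pool:
        best_chain: list[Anchor] = []
        for strand in "+-":
            chain = _weighted_lis([a for a in pool if a.strand == strand])
            if sum(a.length for a in chain) > sum(a.length for a in best_chain):
                best_chain = chain
        total = sum(a.length for a in best_chain)
        if total < min_chain:
            break
        strand = best_chain[0].strand
        scanned = tseq if strand == "+" else rc
        blocks.append(_block_from_chain(best_chain, bseq, target.sequence, scanned, strand))

        def _t_interval(a: Anchor) -> tuple[int, int]:
            if a.strand == "+":
                return a.pos, a.pos + a.length
            return len(tseq) - (a.pos + a.length), len(tseq) - a.pos

        # retire anchors conflicting with the matched intervals of the
        # accepted chain (anchor-by-anchor, so that sequence relocated
        # elsewhere — a reordered or inverted exon — stays in the pool)
        used_b = [(a.base_start, a.base_start + a.length) for a in best_chain]
        used_t = [_t_interval(a) for a in best_chain]
        pool = [
            a
            for a in pool
            if all(a.base_start + a.length <= lo or a.base_start >= hi for lo, hi in used_b)
            and all(_t_interval(a)[1] <= lo or _t_interval(a)[0] >= hi for lo, hi in used_t)
        ]
    blocks.sort(key=lambda blk: blk.base_span)
    return blocks


# ---------------------------------------------------------------------------
# Conserved regions


def detect_conserved_regions(
    blocks: Iterable[AlignmentBlock] | AlignmentBlock,
    cutoff: tuple[float, int],
) -> list[ConservedSegment]:
    """Maximal runs of alignment columns whose every ``window_bp`` window
    has identity >= ``identity_fraction``; adjacent runs merged."""
    frac, window = cutoff
    if isinstance(blocks, AlignmentBlock):
        blocks = [blocks]
    segments: list[ConservedSegment] = []
    need = frac * window - 1e-9
    for blk in blocks:
        L = len(blk.aligned_base)
        if L < window:
            continue
        match = np.fromiter(
            (
                1.0
                if a == b and a != "-" and a != "N" and b != "N"
                else 0.0
                for a, b in zip(blk.aligned_base, blk.aligned_target)
            ),
            dtype=float,
            count=L,
        )
        sums = np.convolve(match, np.ones(window), mode="valid")
        passing = sums >= need
        i = 0
        n = len(passing)
        while i < n:
            if not passing[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and passing[j + 1]:
                j += 1
            cols = slice(i, j + window)
            bc = blk.base_cols[cols]
            tc = blk.target_cols[cols]
            bc = bc[bc >= 0]
            tc = tc[tc >= 0]
            segments.append(
                ConservedSegment(
                    base_start=int(bc.min()),
                    base_end=int(bc.max()) + 1,
                    target_start=int(tc.min()),
                    target_end=int(tc.max()) + 1,
                    orientation=blk.orientation,
                    mean_identity=float(match[cols].mean()),
                )
            )
            i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Verdicts


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def test_contiguity(
    record: CodingSequenceRecord,
    blocks_by_taxon: Mapping[str, Sequence[AlignmentBlock]],
    config: Optional[ProtocolConfig] = None,
) -> ContiguityVerdict:
    """Verify exon number, relative orientation and order against pairwise
    alignments with one or more target taxa.

    An exon counts as conserved when it overlaps (>= ``min_overlap`` bp) a
    conserved segment in at least ``min_targets`` target alignments at that
    taxon's cutoff tier.  Orientation consistency uses the majority
    orientation of exon-overlapping segments; order consistency requires
    the matched target coordinates to be monotone in exon order per taxon.
    """
    config = config or ProtocolConfig()
    exons = sorted(record.exon_model, key=lambda e: e.start)
    confirmed = np.zeros(len(exons), dtype=int)
    orientation_votes: list[str] = []
    exon_orientation_bad = False
    order_ok = True
    per_taxon_hits: dict[str, list[tuple[int, ConservedSegment]]] = {}
    for taxon, blocks in blocks_by_taxon.items():
        cutoff = cutoff_for(taxon, config)
        frac, window = cutoff
        # a passing window tolerates floor(w*(1-f)) mismatches, so a segment
        # may bleed that many bases past true homology; shrink segment ends
        # by that margin before testing exon overlap
        bleed = int(window * (1.0 - frac))
        segments = detect_conserved_regions(list(blocks), cutoff)
        hits: list[tuple[int, ConservedSegment]] = []
        taxon_confirmed = set()
        for idx, exon in enumerate(exons):
            for seg in segments:
                core_start, core_end = seg.base_start + bleed, seg.base_end - bleed
                if _overlap(exon.start, exon.end, core_start, core_end) >= config.min_overlap:
                    hits.append((idx, seg))
                    taxon_confirmed.add(idx)
                    orientation_votes.append(seg.orientation)
        for idx in taxon_confirmed:
            confirmed[idx] += 1
        per_taxon_hits[taxon] = hits
    majority = (
        "forward"
        if orientation_votes.count("forward") >= orientation_votes.count("reverse")
        else "reverse"
    )
    for taxon, hits in per_taxon_hits.items():
        if any(seg.orientation != majority for _, seg in hits):
            exon_orientation_bad = True
        # order: best-overlap segment per confirmed exon, target midpoints
        # must be monotone (either direction)
        by_exon: dict[int, ConservedSegment] = {}
        for idx, seg in hits:
            prev = by_exon.get(idx)
            exon = exons[idx]
            if prev is None or _overlap(exon.start, exon.end, seg.base_start, seg.base_end) > _overlap(
                exon.start, exon.end, prev.base_start, prev.base_end
            ):
                by_exon[idx] = seg
        mids = [
            (by_exon[idx].target_start + by_exon[idx].target_end) / 2.0
            for idx in sorted(by_exon)
        ]
        if len(mids) >= 2:
            inc = all(a < b for a, b in zip(mids, mids[1:]))
            dec = all(a > b for a, b in zip(mids, mids[1:]))
            if not (inc or dec):
                order_ok = False
    conserved = int(np.sum(confirmed >= config.min_targets))
    orientations_consistent = not exon_orientation_bad
    consistent = (
        conserved == len(exons) and orientations_consistent and order_ok
    )
    hint = None
    if not orientations_consistent:
        hint = "inversion"
    elif not order_ok:
        hint = "reorder"
    elif conserved < len(exons):
        hint = "missing_exon"
    verdict = ContiguityVerdict(
        record_id=record.id,
        expected_exons=len(exons),
        conserved_exons=conserved,
        orientations_consistent=orientations_consistent,
        order_consistent=order_ok,
        verdict="consistent" if consistent else "misassembly",
        defect_hint=hint,
    )
    log.debug("contiguity %s: %s (%s)", record.id, verdict.verdict, hint)
    return verdict
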