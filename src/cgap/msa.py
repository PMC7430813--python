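"""Protein-guided codon alignment.

Complete coding sequences are translated (stop codons rendered ``&``),
aligned at the amino-acid level by a progressive profile aligner (k-mer
guide distances, UPGMA guide tree, profile-profile Needleman-Wunsch with
affine gaps), and the nucleotide alignment is threaded back codon by codon.
A validated import path accepts externally curated alignments, since manual
corrections of automated alignments are common practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy.cluster.hierarchy import linkage

from .records import CodingSequenceRecord

STOP_SYMBOL = "&"
GAP_CODON = "---"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = STOP_SYMBOL

#: scoring alphabet: 20 residues + ambiguity codes + stop + gap (last)
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*-"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP_INDEX = _AA_INDEX["-"]


def translate(cds: str) -> str:
    """Translate a CDS under the standard genetic code, stop -> ``&``.

    Raises ``ValueError`` on a length that is not a multiple of 3 or on an
    ambiguous/non-DNA base, naming the offending codon position.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = _CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"unresolvable codon {codon!r} at codon position {i // 3 + 1}")
        out.append(aa)
    return "".join(out)


def _score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Square substitution-score matrix over ALPHABET; gap row/col zero."""
    blosum = substitution_matrices.load(name)
    n = len(ALPHABET)
    S = np.zeros((n, n), dtype=float)
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            key_a = "*" if a == STOP_SYMBOL else a
            key_b = "*" if b == STOP_SYMBOL else b
            try:
                S[i, j] = blosum[key_a, key_b]
            except (KeyError, IndexError):
                S[i, j] = 0.0
    return S


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, len(ALPHABET)), dtype=float)
    for row in rows:
        idx = [_AA_INDEX.get("*" if c == STOP_SYMBOL else c, _AA_INDEX["X"]) if c != "-" else GAP_INDEX for c in row]
        counts[np.arange(L), idx] += 1.0
    return counts


NEG = -1e30


def _gotoh(sim: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed column-similarity matrix.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``.  Returns the
    optimal score and the edit path as a list of ('D'|'U'|'L') moves in
    order; ties resolved diagonal > up > left.
    """
    n, m = sim.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in rows (consumes columns of 2nd)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in columns (consumes rows of 1st)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Ix[0, 1:] = -gap_open - (j - 1) * gap_extend
    i = np.arange(1, n + 1)
    Iy[1:, 0] = -gap_open - (i - 1) * gap_extend
    for i in range(1, n + 1):
        Iy[i, :] = np.maximum(M[i - 1, :] - gap_open, Iy[i - 1, :] - gap_extend)
        Iy[i, 0] = -gap_open - (i - 1) * gap_extend
        prev = np.maximum.reduce([M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        M[i, 1:] = sim[i - 1, :] + prev
        M[i, 0] = NEG
        # Ix[i, j] = max_{j' < j} M[i, j'] - open - (j-1-j')*extend (left moves)
        B = np.maximum(M[i, :-1], Iy[i, :-1]) + np.arange(m) * gap_extend
        run = np.maximum.accumulate(B)
        Ix[i, 1:] = run - gap_open - np.arange(m) * gap_extend
        Ix[i, 0] = NEG
    # traceback; ties resolved diagonal (M) > up (Iy) > left (Ix)
    eps = 1e-9

    def _pick(cands):
        best = max(v for _, v in cands)
        for name, v in cands:
            if v >= best - eps:
                return name
        return cands[0][0]

    i, j = n, m
    state = _pick([("M", M[i, j]), ("Iy", Iy[i, j]), ("Ix", Ix[i, j])])
    score = {"M": M, "Iy": Iy, "Ix": Ix}[state][i, j]
    path: list[str] = []
    while not (i == 0 and j == 0):
        if i == 0:
            state = "Ix"
        elif j == 0:
            state = "Iy"
        if state == "M":
            path.append("D")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick([("M", M[i, j]), ("Iy", Iy[i, j]), ("Ix", Ix[i, j])])
        elif state == "Iy":
            path.append("U")
            state = _pick(
                [("M", M[i - 1, j] - gap_open), ("Iy", Iy[i - 1, j] - gap_extend)]
            )
            i -= 1
        else:
            path.append("L")
            state = _pick(
                [
                    ("M", M[i, j - 1] - gap_open),
                    ("Iy", Iy[i, j - 1] - gap_open),
                    ("Ix", Ix[i, j - 1] - gap_extend),
                ]
            )
            j -= 1
    path.reverse()
    return score, path


def pairwise_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, str, str]:
    """Optimal global alignment of two protein sequences (affine gaps)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    S = _score_matrix(matrix)
    pa = _profile_counts([a])
    pb = _profile_counts([b])
    sim = pa @ S @ pb.T
    score, path = _gotoh(sim, gap_open, gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for move in path:
        if move == "D":
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif move == "U":
            out_a.append(a[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(b[j]); j += 1
    return score, "".join(out_a), "".join(out_b)


def _merge_profiles(rows1, rows2, S, gap_open, gap_extend):
    p1 = _profile_counts(list(rows1.values()))
    p2 = _profile_counts(list(rows2.values()))
    n1 = len(rows1)
    n2 = len(rows2)
    sim = (p1 @ S @ p2.T) / (n1 * n2)
    _, path = _gotoh(sim, gap_open, gap_extend)
    out = {k: [] for k in list(rows1) + list(rows2)}
    i = j = 0
    for move in path:
        use1 = move in ("D", "U")
        use2 = move in ("D", "L")
        for k, row in rows1.items():
            out[k].append(row[i] if use1 else "-")
        for k, row in rows2.items():
            out[k].append(row[j] if use2 else "-")
        if use1:
            i += 1
        if use2:
            j += 1
    return {k: "".join(v) for k, v in out.items()}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {}
    for i in range(len(a) - k + 1):
        ka[a[i : i + k]] = ka.get(a[i : i + k], 0) + 1
    shared = 0
    kb = {}
    for i in range(len(b) - k + 1):
        kb[b[i : i + k]] = kb.get(b[i : i + k], 0) + 1
    for kmer, c in kb.items():
        shared += min(c, ka.get(kmer, 0))
    return 1.0 - shared / min(len(a) - k + 1, len(b) - k + 1)


def align_proteins(
    proteins: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> dict[str, str]:
    """Progressive multiple alignment of protein sequences.

    Guide tree: UPGMA (average linkage) on pairwise k-mer distances;
    profiles merged by global profile-profile DP.  Deterministic for fixed
    inputs and parameters.
    """
    ids = list(proteins)
    if len(ids) < 1:
        raise ValueError("no sequences to align")
    for k, v in proteins.items():
        if not v:
            raise ValueError(f"empty sequence {k}")
    if len(ids) == 1:
        return {ids[0]: proteins[ids[0]]}
    S = _score_matrix(matrix)
    if len(ids) == 2:
        _, ra, rb = pairwise_align(
            proteins[ids[0]], proteins[ids[1]], matrix, gap_open, gap_extend
        )
        return {ids[0]: ra, ids[1]: rb}
    n = len(ids)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(_kmer_distance(proteins[ids[i]], proteins[ids[j]]))
    Z = linkage(np.asarray(cond), method="average")
    groups: dict[int, dict[str, str]] = {
        i: {ids[i]: proteins[ids[i]]} for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(Z):
        a = groups.pop(int(left))
        b = groups.pop(int(right))
        groups[n + step] = _merge_profiles(a, b, S, gap_open, gap_extend)
    (final,) = groups.values()
    return {rid: final[rid] for rid in ids}


def sp_score(
    rows: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_penalty: float = 10.0,
) -> float:
    """Sum-of-pairs score of an alignment: substitution score for residue
    pairs, -gap_penalty for residue-gap pairs, 0 for gap-gap."""
    S = _score_matrix(matrix)
    seqs = list(rows.values())
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            for a, b in zip(seqs[i], seqs[j]):
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total -= gap_penalty
                else:
                    total += S[_AA_INDEX.get(a, _AA_INDEX["X"]), _AA_INDEX.get(b, _AA_INDEX["X"])]
    return total


# ---------------------------------------------------------------------------
# Codon alignment container


@dataclass
class CodonAlignment:
    """Column-indexed codon alignment with a protein-level view.

    Invariants: all rows have the same number of codon cells; every non-gap
    cell is a sense or stop codon; removing gaps from a row reproduces the
    record's CDS exactly.
    """

    record_ids: list[str]
    codon_rows: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.codon_rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"codon rows differ in length: {sorted(lengths)}")
        for rid, row in self.codon_rows.items():
            for cell in row:
                if cell != GAP_CODON and cell not in _CODON_TO_AA:
                    raise ValueError(f"row {rid}: invalid codon cell {cell!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.codon_rows.values())))

    def nucleotide_rows(self) -> dict[str, str]:
        return {rid: "".join(row) for rid, row in self.codon_rows.items()}

    def protein_rows(self) -> dict[str, str]:
        return {
            rid: "".join("-" if c == GAP_CODON else _CODON_TO_AA[c] for c in row)
            for rid, row in self.codon_rows.items()
        }

    def degapped(self, rid: str) -> str:
        return "".join(c for c in self.codon_rows[rid] if c != GAP_CODON)

    def reference_map(self, reference_id: str) -> list[Optional[int]]:
        """Alignment column -> 1-based amino-acid position in the reference
        record (None where the reference is gapped)."""
        if reference_id not in self.codon_rows:
            raise KeyError(f"reference {reference_id!r} not in alignment")
        out: list[Optional[int]] = []
        pos = 0
        for cell in self.codon_rows[reference_id]:
            if cell == GAP_CODON:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def validate_against(self, cds_map: Mapping[str, str]) -> None:
        for rid in self.record_ids:
            if self.degapped(rid) != cds_map[rid].upper():
                raise ValueError(f"row {rid} does not de-gap to its CDS")

    def column(self, idx: int) -> dict[str, str]:
        return {rid: self.codon_rows[rid][idx] for rid in self.record_ids}


def thread_codons(
    protein_msa: Mapping[str, str], cds_map: Mapping[str, str]
) -> CodonAlignment:
    """Expand a protein alignment into the corresponding codon alignment.

    Each protein row must equal ``translate`` of its CDS; every amino acid
    column becomes its source codon, protein gaps become ``---``.
    """
    rows: dict[str, tuple[str, ...]] = {}
    for rid, prot_row in protein_msa.items():
        cds = cds_map[rid].upper()
        if translate(cds) != prot_row.replace("-", ""):
            raise ValueError(f"protein row of {rid} does not match translate(CDS)")
        cells = []
        k = 0
        for aa in prot_row:
            if aa == "-":
                cells.append(GAP_CODON)
            else:
                cells.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows[rid] = tuple(cells)
    aln = CodonAlignment(list(protein_msa), rows)
    aln.validate_against(cds_map)
    return aln


def align_records(
    records: Iterable[CodingSequenceRecord], **kwargs
) -> CodonAlignment:
    """Translate, align at protein level, and thread codons back."""
    recs = list(records)
    proteins = {r.id: translate(r.cds_sequence) for r in recs}
    msa = align_proteins(proteins, **kwargs)
    return thread_codons(msa, {r.id: r.cds_sequence for r in recs})


def accept_external_alignment(path, records: Iterable[CodingSequenceRecord]) -> CodonAlignment:
    """Import a curated nucleotide FASTA alignment over the given records.

    Rows must de-gap to the records' coding sequences exactly; anything else
    is a hard error (no silent repair of curated input).
    """
    from . import io as _io

    rows = _io.read_alignment(path)
    cds_map = {r.id: r.cds_sequence for r in records}
    missing = set(cds_map) - set(rows)
    if missing:
        raise ValueError(f"alignment lacks rows for records: {sorted(missing)}")
    codon_rows: dict[str, tuple[str, ...]] = {}
    for rid in cds_map:
        row = rows[rid].upper()
        if len(row) % 3 != 0:
            raise ValueError(f"row {rid}: aligned length not a multiple of 3")
        cells = tuple(row[i : i + 3] for i in range(0, len(row), 3))
        for cell in cells:
            if cell != GAP_CODON and "-" in cell:
                raise ValueError(f"row {rid}: frame-breaking gap in cell {cell!r}")
        codon_rows[rid] = cells
    aln = CodonAlignment(list(cds_map), codon_rows)
    aln.validate_against(cds_map)
    return aln
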