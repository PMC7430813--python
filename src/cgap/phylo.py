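"""Pairwise-identity statistics, composite-likelihood distances,
minimum-evolution trees and cluster classification.

Distances follow the Tamura-Nei (TN93) model with pairwise deletion;
substitution-rate ratios can be estimated jointly across all pairs by
maximising the composite (sum-over-pairs) log-likelihood, falling back to
the closed-form per-pair estimator.  Trees start from neighbor joining and
are refined by close-neighbor-interchange accepting swaps that reduce the
ordinary-least-squares total branch length; bootstrap supports come from
resampling alignment columns.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize, minimize_scalar

from .msa import CodonAlignment
from .records import DEFAULT_IDENTITY_BINS

log = logging.getLogger("cgap")

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def _as_rows(aln) -> dict[str, str]:
    if isinstance(aln, CodonAlignment):
        return aln.nucleotide_rows()
    return dict(aln)


def _encode(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(rows)
    L = len(next(iter(rows.values())))
    mat = np.full((len(ids), L), -1, dtype=np.int8)
    for i, rid in enumerate(ids):
        row = rows[rid].upper()
        for j, c in enumerate(row):
            mat[i, j] = _BASE_IDX.get(c, -1)
    return ids, mat


# ---------------------------------------------------------------------------
# Pairwise identity


def pairwise_identity(aln, id_i: str, id_j: str) -> Optional[float]:
    """Fraction of matching nucleotides over columns comparable in both
    rows (pairwise deletion).  ``None`` when no column is comparable."""
    rows = _as_rows(aln)
    a, b = rows[id_i].upper(), rows[id_j].upper()
    matches = compared = 0
    for x, y in zip(a, b):
        if x in _BASE_IDX and y in _BASE_IDX:
            compared += 1
            if x == y:
                matches += 1
    if compared == 0:
        return None
    return matches / compared


def identity_matrix(aln, subset: Optional[Sequence[str]] = None):
    rows = _as_rows(aln)
    if subset is not None:
        rows = {rid: rows[rid] for rid in subset}
    ids, mat = _encode(rows)
    n = len(ids)
    M = np.full((n, n), np.nan)
    np.fill_diagonal(M, 1.0)
    valid = mat >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            if c:
                M[i, j] = M[j, i] = float((mat[i, both] == mat[j, both]).sum()) / c
    return ids, M


@dataclass(frozen=True)
class IdentityStats:
    """Summary of all unordered pairwise nucleotide identities: mean (ā),
    average absolute deviation (ā_ad), largest and smallest values."""

    a_bar: float
    a_bar_ad: float
    a_max: float
    a_min: float
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_min <= self.a_bar <= self.a_max <= 1.0 + 1e-12):
            raise ValueError("identity statistics violate a_min <= a_bar <= a_max")


def identity_stats(aln, subset: Optional[Sequence[str]] = None) -> IdentityStats:
    ids, M = identity_matrix(aln, subset)
    vals = M[np.triu_indices(len(ids), k=1)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("need at least one comparable pair")
    return IdentityStats(
        a_bar=float(vals.mean()),
        a_bar_ad=float(np.abs(vals - vals.mean()).mean()),
        a_max=float(vals.max()),
        a_min=float(vals.min()),
        ids=tuple(ids),
        matrix=M,
    )


@dataclass(frozen=True)
class PatternLabel:
    category: str
    level: str  # 'orthologue' | 'homologue'


def classify_pattern(
    identity: float,
    level: str = "orthologue",
    bins: Sequence[tuple[str, float]] = DEFAULT_IDENTITY_BINS,
) -> PatternLabel:
    """Bin an identity value into a similarity-pattern category (the bin
    boundaries are configuration, not published constants)."""
    if not (0.0 <= identity <= 1.0):
        raise ValueError(f"identity {identity} outside [0,1]")
    for name, lower in bins:
        if identity >= lower:
            return PatternLabel(name, level)
    return PatternLabel(bins[-1][0], level)


# ---------------------------------------------------------------------------
# TN93 / composite-likelihood distances


def _pair_count_matrices(mat: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    n = mat.shape[0]
    out = []
    valid = mat >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            C = np.zeros((4, 4))
            if both.any():
                np.add.at(C, (mat[i, both], mat[j, both]), 1.0)
            out.append((i, j, C))
    return out


def _tn93_closed_form(C: np.ndarray, freqs: np.ndarray) -> float:
    """Closed-form TN93 distance from a pair's 4x4 count matrix."""
    n = C.sum()
    if n == 0:
        return np.nan
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    P1 = (C[0, 2] + C[2, 0]) / n  # A<->G
    P2 = (C[1, 3] + C[3, 1]) / n  # C<->T
    Q = (C.sum() - np.trace(C) - (C[0, 2] + C[2, 0] + C[1, 3] + C[3, 1])) / n
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0) - (gT * gC * gR / gY if gY > 0 else 0.0))
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY) if gR * gY > 0 else 1.0
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.nan
    d = 0.0
    if k1 > 0:
        d -= k1 * np.log(w1)
    if k2 > 0:
        d -= k2 * np.log(w2)
    d -= k3 * np.log(w3)
    return float(max(d, 0.0))


def _tn93_P(d: float, k1: float, k2: float, freqs: np.ndarray) -> np.ndarray:
    """TN93 transition-probability matrix at distance ``d`` (expected
    substitutions per site), with transition/transversion rate ratios
    ``k1`` (purines) and ``k2`` (pyrimidines)."""
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    mu = 2.0 * gA * gG * k1 + 2.0 * gC * gT * k2 + 2.0 * gR * gY
    beta = d / mu if mu > 0 else 0.0
    a1 = k1 * beta
    a2 = k2 * beta
    e2 = np.exp(-beta)
    e3R = np.exp(-(gR * a1 + gY * beta))
    e3Y = np.exp(-(gY * a2 + gR * beta))
    P = np.zeros((4, 4))
    pi = {0: gA, 1: gC, 2: gG, 3: gT}
    purine = {0, 2}
    for i in range(4):
        for j in range(4):
            pj = pi[j]
            if i == j:
                if i in purine:
                    P[i, j] = pj + pj * (gY / gR) * e2 + ((gR - pj) / gR) * e3R
                else:
                    P[i, j] = pj + pj * (gR / gY) * e2 + ((gY - pj) / gY) * e3Y
            elif i in purine and j in purine:
                P[i, j] = pj + pj * (gY / gR) * e2 - (pj / gR) * e3R
            elif i not in purine and j not in purine:
                P[i, j] = pj + pj * (gR / gY) * e2 - (pj / gY) * e3Y
            else:
                P[i, j] = pj * (1.0 - e2)
    return P


def _pair_loglik(d: float, C: np.ndarray, k1: float, k2: float, freqs: np.ndarray) -> float:
    P = _tn93_P(d, k1, k2, freqs)
    pi = freqs.reshape(4, 1)
    with np.errstate(divide="ignore"):
        logM = np.log(np.maximum(pi * P, 1e-300))
    return float((C * logM).sum())


def _best_d(C: np.ndarray, k1: float, k2: float, freqs: np.ndarray) -> tuple[float, float]:
    res = minimize_scalar(
        lambda d: -_pair_loglik(d, C, k1, k2, freqs),
        bounds=(1e-9, 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


def mcl_distances(
    aln,
    joint: bool = True,
    subset: Optional[Sequence[str]] = None,
) -> tuple[list[str], np.ndarray]:
    """TN93 evolutionary distances under pairwise deletion.

    With ``joint=True`` the two transition/transversion rate ratios are
    shared across all pairs and estimated by maximising the composite
    log-likelihood (sum of pair likelihoods); per-pair distances are then
    profile likelihood maximisers.  Falls back to the closed-form per-pair
    TN93 estimator if the joint optimisation fails.  Saturated pairs get
    ``nan`` and a logged warning.
    """
    rows = _as_rows(aln)
    if subset is not None:
        rows = {rid: rows[rid] for rid in subset}
    ids, mat = _encode(rows)
    n = len(ids)
    counts = np.bincount(mat[mat >= 0].ravel(), minlength=4).astype(float)
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    pairs = _pair_count_matrices(mat)
    D = np.zeros((n, n))
    closed = {}
    for i, j, C in pairs:
        closed[(i, j)] = _tn93_closed_form(C, freqs)
    if joint and n > 1:
        try:
            def neg_cll(logk):
                k1, k2 = float(np.exp(logk[0])), float(np.exp(logk[1]))
                total = 0.0
                for i, j, C in pairs:
                    if C.sum() == 0:
                        continue
                    _, ll = _best_d(C, k1, k2, freqs)
                    total += ll
                return -total

            res = minimize(
                neg_cll,
                x0=np.log([2.0, 2.0]),
                method="Nelder-Mead",
                options={"maxiter": 60, "xatol": 1e-3, "fatol": 1e-4},
            )
            k1, k2 = np.exp(res.x)
            for i, j, C in pairs:
                if C.sum() == 0:
                    D[i, j] = D[j, i] = np.nan
                    continue
                d, _ = _best_d(C, float(k1), float(k2), freqs)
                if d >= 9.99:  # hit the bound: effectively saturated
                    d = np.nan
                D[i, j] = D[j, i] = d
        except Exception as exc:  # pragma: no cover - defensive fallback
            log.warning("joint rate estimation failed (%s); per-pair TN93 used", exc)
            joint = False
    if not joint or n <= 1:
        for (i, j), d in closed.items():
            D[i, j] = D[j, i] = d
    for (i, j), d in closed.items():
        if np.isnan(D[i, j]):
            log.warning("saturated pair (%s, %s): distance undefined", ids[i], ids[j])
    return ids, D


# ---------------------------------------------------------------------------
# Unrooted trees: NJ start, OLS branch lengths, CNI refinement


class Tree:
    """Unrooted tree on integer nodes; leaves carry names."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.names: dict[int, str] = {}

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    @property
    def leaves(self) -> list[int]:
        return sorted(n for n in self.adj if len(self.adj[n]) == 1)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: set(vs) for u, vs in self.adj.items()}
        t.names = dict(self.names)
        return t

    def bipartition(self, u: int, v: int) -> frozenset[str]:
        """Leaf names on the ``u`` side of edge (u, v), normalised to the
        side not containing the lowest-numbered leaf."""
        side = self._side(u, v)
        names = frozenset(self.names[x] for x in side if x in self.names)
        ref = self.names[min(self.names)]
        if ref in names:
            all_names = frozenset(self.names.values())
            names = all_names - names
        return names

    def _side(self, u: int, v: int) -> set[int]:
        seen = {v, u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        seen.discard(v)
        return seen

    def newick(self, lengths: Optional[Mapping[frozenset, float]] = None,
               labels: Optional[Mapping[frozenset, str]] = None) -> str:
        # root at an internal node if any, else at the first leaf
        internal = [n for n in self.adj if len(self.adj[n]) > 1]
        root = min(internal) if internal else min(self.adj)

        def fmt(node: int, parent: Optional[int]) -> str:
            children = [c for c in self.adj[node] if c != parent]
            if not children:
                name = self.names.get(node, str(node))
                s = name.replace(" ", "_")
            else:
                s = "(" + ",".join(fmt(c, node) for c in children) + ")"
                if labels is not None and parent is not None:
                    lab = labels.get(frozenset((node, parent)))
                    if lab is not None:
                        s += lab
            if parent is not None and lengths is not None:
                bl = lengths.get(frozenset((node, parent)))
                if bl is not None:
                    s += f":{bl:.6g}"
            return s

        return fmt(root, None) + ";"


def neighbor_joining(D: np.ndarray, names: Sequence[str]) -> Tree:
    """Deterministic neighbor joining (ties broken by lowest index pair)."""
    n = len(names)
    tree = Tree()
    if n == 1:
        tree.adj[0] = set()
        tree.names[0] = names[0]
        return tree
    if n == 2:
        tree.add_edge(0, 1)
        tree.names = {0: names[0], 1: names[1]}
        return tree
    active = list(range(n))
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    for i in range(n):
        tree.names[i] = names[i]
        tree.adj.setdefault(i, set())
    next_node = n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        u = next_node
        next_node += 1
        tree.adj.setdefault(u, set())
        tree.add_edge(i, u)
        tree.add_edge(j, u)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            key = (min(u, k), max(u, k))
            dist[key] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    a, b = active
    tree.add_edge(a, b)
    return tree


def _leaf_paths(tree: Tree) -> dict[int, dict[int, Optional[int]]]:
    """BFS parent maps from each leaf."""
    out = {}
    for leaf in tree.leaves:
        parent: dict[int, Optional[int]] = {leaf: None}
        stack = [leaf]
        while stack:
            x = stack.pop()
            for y in tree.adj[x]:
                if y not in parent:
                    parent[y] = x
                    stack.append(y)
        out[leaf] = parent
    return out


def ols_branch_lengths(
    tree: Tree, D: np.ndarray, names: Sequence[str]
) -> tuple[dict[frozenset, float], float]:
    """Ordinary-least-squares branch lengths and total tree length."""
    name_to_node = {v: k for k, v in tree.names.items()}
    leaves = [name_to_node[nm] for nm in names]
    edges = tree.edges()
    edge_idx = {frozenset(e): k for k, e in enumerate(edges)}
    parents = _leaf_paths(tree)
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        y[row] = D[i, j]
        parent = parents[leaves[i]]
        node = leaves[j]
        while parent[node] is not None:
            A[row, edge_idx[frozenset((node, parent[node]))]] = 1.0
            node = parent[node]
    b, *_ = np.linalg.lstsq(A, y, rcond=None)
    lengths = {frozenset(e): float(b[k]) for k, e in enumerate(edges)}
    return lengths, float(b.sum())


def _internal_edges(tree: Tree) -> list[tuple[int, int]]:
    return [
        (u, v)
        for u, v in tree.edges()
        if len(tree.adj[u]) > 1 and len(tree.adj[v]) > 1
    ]


def _nni_neighbors(tree: Tree, u: int, v: int):
    """The two alternative topologies around internal edge (u, v)."""
    nu = sorted(x for x in tree.adj[u] if x != v)
    nv = sorted(x for x in tree.adj[v] if x != u)
    for swap_v in nv[:2] if len(nv) >= 2 else nv:
        alt = tree.copy()
        b = nu[1] if len(nu) >= 2 else nu[0]
        alt.remove_edge(u, b)
        alt.remove_edge(v, swap_v)
        alt.add_edge(u, swap_v)
        alt.add_edge(v, b)
        yield alt


def minimum_evolution(
    D: np.ndarray, names: Sequence[str], max_rounds: int = 50
) -> tuple[Tree, dict[frozenset, float], list[float]]:
    """NJ starting tree refined by close-neighbor-interchange, accepting
    swaps that reduce OLS total branch length (first improvement,
    deterministic edge order).  Returns the tree, fitted branch lengths and
    the trajectory of total lengths across accepted swaps."""
    tree = neighbor_joining(D, names)
    if len(names) < 4:
        lengths, total = ols_branch_lengths(tree, D, names)
        return tree, lengths, [total]
    lengths, total = ols_branch_lengths(tree, D, names)
    trajectory = [total]
    for _ in range(max_rounds):
        improved = False
        for u, v in _internal_edges(tree):
            for alt in _nni_neighbors(tree, u, v):
                alt_lengths, alt_total = ols_branch_lengths(alt, D, names)
                if alt_total < total - 1e-10:
                    tree, lengths, total = alt, alt_lengths, alt_total
                    trajectory.append(total)
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return tree, lengths, trajectory


@dataclass
class PhyloResult:
    ids: list[str]
    distance_matrix: np.ndarray
    tree: Tree
    branch_lengths: dict
    supports: dict  # bipartition (frozenset of names) -> percent
    collapsed_tree: Tree
    ols_trajectory: list[float] = field(default_factory=list)

    def newick(self) -> str:
        labels = {}
        for u, v in _internal_edges(self.tree):
            bip = self.tree.bipartition(u, v)
            if bip in self.supports:
                labels[frozenset((u, v))] = f"{self.supports[bip]:.0f}"
        return self.tree.newick(self.branch_lengths, labels)

    def collapsed_newick(self) -> str:
        return self.collapsed_tree.newick()

    def clade_support(self, leaf_names: Iterable[str]) -> float:
        """Bootstrap support (percent) of the clade containing exactly the
        given leaves; 0 if the bipartition is absent from the tree."""
        want = frozenset(leaf_names)
        all_names = frozenset(self.tree.names.values())
        ref = self.tree.names[min(self.tree.names)]
        if ref in want:
            want = all_names - want
        return self.supports.get(want, 0.0)


def _drop_missing(D: np.ndarray, ids: list[str]) -> tuple[np.ndarray, list[str]]:
    D = D.copy()
    ids = list(ids)
    while np.isnan(D).any():
        bad = np.isnan(D).sum(axis=1)
        worst = int(np.argmax(bad))
        log.warning("dropping %s: %d undefined distances", ids[worst], int(bad[worst]))
        keep = [k for k in range(len(ids)) if k != worst]
        D = D[np.ix_(keep, keep)]
        ids = [ids[k] for k in keep]
    return D, ids


def me_tree(
    aln,
    n_bootstrap: int = 1000,
    seed: int = 0,
    collapse: float = 50.0,
    subset: Optional[Sequence[str]] = None,
    joint_rates: bool = False,
) -> PhyloResult:
    """Minimum-evolution tree with column-resampling bootstrap supports.

    Internal branches with support below ``collapse`` percent are
    contracted in ``collapsed_tree``.  Bootstrap replicates resample
    nucleotide columns with replacement and re-run the whole
    distance-and-tree computation.
    """
    rows = _as_rows(aln)
    if subset is not None:
        rows = {rid: rows[rid] for rid in subset}
    ids, D = mcl_distances(rows, joint=joint_rates)
    D, ids = _drop_missing(D, ids)
    tree, lengths, trajectory = minimum_evolution(D, ids)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    kept = {rid: rows[rid] for rid in ids}
    L = len(next(iter(kept.values())))
    row_arr = {rid: np.frombuffer(kept[rid].encode(), dtype="S1") for rid in ids}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        resampled = {rid: row_arr[rid][cols].tobytes().decode() for rid in ids}
        bids, BD = mcl_distances(resampled, joint=False)
        BD, bids = _drop_missing(BD, bids)
        if len(bids) < 4:
            continue
        btree, blengths, _ = minimum_evolution(BD, bids)
        for u, v in _internal_edges(btree):
            # a zero-length internal branch carries no signal; treating it
            # as resolved would let deterministic tie-breaking inflate
            # supports on uninformative data
            if blengths.get(frozenset((u, v)), 0.0) > 1e-9:
                counts[btree.bipartition(u, v)] = counts.get(btree.bipartition(u, v), 0) + 1
    supports = {}
    for u, v in _internal_edges(tree):
        bip = tree.bipartition(u, v)
        supports[bip] = 100.0 * counts.get(bip, 0) / max(n_bootstrap, 1)
    # contract low-support internal edges (tracking node merges)
    collapsed = tree.copy()
    merged: dict[int, int] = {}

    def _rep(x: int) -> int:
        while x in merged:
            x = merged[x]
        return x

    for u, v in _internal_edges(tree):
        bip = tree.bipartition(u, v)
        if supports.get(bip, 0.0) < collapse:
            ru, rv = _rep(u), _rep(v)
            if ru != rv and rv in collapsed.adj.get(ru, set()):
                _contract(collapsed, ru, rv)
                merged[rv] = ru
    return PhyloResult(ids, D, tree, lengths, supports, collapsed, trajectory)


def _contract(tree: Tree, u: int, v: int) -> None:
    if v not in tree.adj.get(u, set()):
        return
    for w in list(tree.adj[v]):
        if w != u:
            tree.remove_edge(v, w)
            tree.add_edge(u, w)
    tree.remove_edge(u, v)
    tree.adj.pop(v, None)


# ---------------------------------------------------------------------------
# Cluster / supercluster assignment


def _tree_leaf_distances(tree: Tree, lengths: Mapping[frozenset, float]) -> tuple[list[int], np.ndarray]:
    leaves = tree.leaves
    idx = {n: i for i, n in enumerate(leaves)}
    n = len(leaves)
    M = np.zeros((n, n))
    parents = _leaf_paths(tree)
    for a in leaves:
        parent = parents[a]
        for b in leaves:
            if b <= a:
                continue
            d = 0.0
            node = b
            while parent[node] is not None:
                d += max(lengths.get(frozenset((node, parent[node])), 0.0), 0.0)
                node = parent[node]
            M[idx[a], idx[b]] = M[idx[b], idx[a]] = d
    return leaves, M


@dataclass
class ClusterAssignment:
    labels: dict[str, tuple[str, str]]  # record id -> (supercluster, cluster)
    non_monophyletic: list[str]


def assign_clusters(result: PhyloResult, records) -> ClusterAssignment:
    """Derive (supercluster, cluster) labels from the tree.

    Major gene clusters are the leaf groups sharing a known gene label
    (checked for monophyly in the collapsed tree and flagged when violated,
    never silently merged).  Clusters are grouped into superclusters by
    single-linkage clustering of mean inter-cluster path distances, cut at
    the largest gap between consecutive merge heights.  Superclusters are
    numbered by size (descending, ties by traversal order); members are
    lettered A, B, C... by post-order appearance in the tree.
    """
    in_tree = set(result.tree.names.values())
    by_label: dict[str, list[str]] = {}
    for rec in records:
        if rec.id not in in_tree:  # dropped upstream (saturated distances)
            continue
        label = rec.gene_label if rec.gene_label != "unknown" else rec.cluster_label
        by_label.setdefault(label, []).append(rec.id)
    # monophyly check against collapsed-tree bipartitions
    tree = result.collapsed_tree
    bips = {tree.bipartition(u, v) for u, v in tree.edges()}
    all_names = frozenset(tree.names.values())
    ref = tree.names[min(tree.names)]
    non_mono = []
    for label, members in sorted(by_label.items()):
        want = frozenset(members)
        if len(want) in (1, len(all_names)):
            continue
        key = (all_names - want) if ref in want else want
        if key not in bips:
            non_mono.append(label)
            log.warning("label %s is not monophyletic in the collapsed tree", label)
    # inter-cluster distances on the full tree
    leaves, M = _tree_leaf_distances(result.tree, result.branch_lengths)
    leaf_name = {n: result.tree.names[n] for n in leaves}
    name_idx = {leaf_name[n]: i for i, n in enumerate(leaves)}
    labels_sorted = _postorder_label_order(result.tree, by_label)
    k = len(labels_sorted)
    if k == 1:
        groups = [0]
    else:
        CM = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                ia = [name_idx[m] for m in by_label[labels_sorted[a]]]
                ib = [name_idx[m] for m in by_label[labels_sorted[b]]]
                CM[a, b] = CM[b, a] = float(M[np.ix_(ia, ib)].mean())
        cond = CM[np.triu_indices(k, 1)]
        Z = linkage(cond, method="single")
        heights = Z[:, 2]
        if len(heights) >= 2:
            gaps = np.diff(heights)
            cut_at = int(np.argmax(gaps))
            threshold = (heights[cut_at] + heights[cut_at + 1]) / 2.0
        else:
            threshold = heights[-1] + 1.0  # <=2 clusters: one supercluster
        groups = _cut_linkage(Z, k, threshold)
    # number superclusters by size desc then traversal order
    order: dict[int, list[int]] = {}
    for pos, g in enumerate(groups):
        order.setdefault(g, []).append(pos)
    ranked = sorted(order.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    out: dict[str, tuple[str, str]] = {}
    for sc_rank, (g, positions) in enumerate(ranked, start=1):
        for letter_idx, pos in enumerate(sorted(positions)):
            cl_name = f"{sc_rank}{chr(ord('A') + letter_idx)}"
            for member in by_label[labels_sorted[pos]]:
                out[member] = (str(sc_rank), cl_name)
    return ClusterAssignment(out, non_mono)


def _postorder_label_order(tree: Tree, by_label: Mapping[str, list[str]]) -> list[str]:
    member_label = {m: lab for lab, ms in by_label.items() for m in ms}
    internal = [n for n in tree.adj if len(tree.adj[n]) > 1]
    root = min(internal) if internal else min(tree.adj)
    seen: list[str] = []

    def walk(node, parent):
        children = sorted(c for c in tree.adj[node] if c != parent)
        for c in children:
            walk(c, node)
        if node in tree.names:
            lab = member_label.get(tree.names[node])
            if lab is not None and lab not in seen:
                seen.append(lab)

    walk(root, None)
    for lab in sorted(by_label):
        if lab not in seen:
            seen.append(lab)
    return seen


def _cut_linkage(Z: np.ndarray, k: int, threshold: float) -> list[int]:
    """Flat groups from a linkage matrix, merging below ``threshold``."""
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    clusters: dict[int, list[int]] = {i: [i] for i in range(k)}
    nxt = k
    reps = {i: i for i in range(k)}  # linkage node -> representative original
    for a, b, h, _ in Z:
        if h < threshold:
            ra, rb = find(reps[int(a)]), find(reps[int(b)])
            parent[rb] = ra
        reps[nxt] = find(reps[int(a)])
        nxt += 1
    roots = {}
    out = []
    for i in range(k):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out.append(roots[r])
    return out
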