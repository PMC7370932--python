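"""Distance phylogeny of ERF proteins and B1-B6 group assignment.

Pipeline: pairwise global alignment (Needleman-Wunsch, affine gaps,
BLOSUM62 by default) → p-distance matrix → Saitou-Nei neighbor joining →
column-bootstrap support on a center-star multiple alignment → group labels
transferred from reference leaves, by monophyletic clade when supported and
by nearest patristic reference otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

Bipartition = frozenset  # canonical side (the one not containing the first leaf)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("non-zero diagonal")


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map; leaves carry string names."""

    adjacency: dict[object, list[tuple[object, float]]]
    leaf_names: list[str]
    support: Optional[dict[Bipartition, float]] = None
    clamped: bool = False          # a negative NJ branch estimate was clamped
    unresolved: bool = False       # no distance signal (all-zero matrix)

    def edges(self) -> list[tuple[object, object, float]]:
        seen = set()
        out = []
        for u, nbrs in self.adjacency.items():
            for v, ln in nbrs:
                key = frozenset((id(u), id(v)))
                if key in seen:
                    continue
                seen.add(key)
                out.append((u, v, ln))
        return out

    def total_length(self) -> float:
        return sum(ln for _, _, ln in self.edges())

    def _side(self, u, v) -> set[str]:
        """Leaves on the v side of edge (u, v)."""
        stack = [v]
        seen = {u, v}
        leaves = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                leaves.add(node)
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return leaves

    def canonical(self, side: set[str]) -> Bipartition:
        anchor = min(self.leaf_names)
        if anchor in side:
            side = set(self.leaf_names) - side
        return frozenset(side)

    def bipartitions(self) -> set[Bipartition]:
        """Internal (non-trivial) bipartitions."""
        out = set()
        n = len(self.leaf_names)
        for u, v, _ in self.edges():
            side = self._side(u, v)
            if 2 <= len(side) <= n - 2:
                out.add(self.canonical(side))
        return out

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        dists: dict[tuple[str, str], float] = {}
        for leaf in self.leaf_names:
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nbr, ln in self.adjacency[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + ln
                        stack.append(nbr)
            for other in self.leaf_names:
                dists[(leaf, other)] = dist[other]
        return dists

    def newick(self) -> str:
        internal = [n for n in self.adjacency if not isinstance(n, str)]
        root = internal[0] if internal else self.leaf_names[0]

        def fmt(node, parent, incoming: float) -> str:
            if isinstance(node, str):
                return f"{node}:{incoming:.6f}"
            parts = [
                fmt(nbr, node, ln)
                for nbr, ln in self.adjacency[node]
                if nbr is not parent
            ]
            label = ""
            if self.support is not None and parent is not None:
                side = self._side(parent, node)
                key = self.canonical(side)
                if key in self.support:
                    label = f"{self.support[key]:.3f}"
            tail = "" if parent is None else f":{incoming:.6f}"
            return f"({','.join(parts)}){label}{tail}"

        return fmt(root, None, 0.0) + ";"


@dataclass
class GroupAssignment:
    protein_id: str
    group: str
    evidence: str                  # clade | nearest-reference
    support: float
    tie: bool = False


# ---------------------------------------------------------------------------
# pairwise alignment and distances

def _aligner(substitution_matrix=None, gap_open: float = -10.0, gap_extend: float = -0.5):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        substitution_matrix
        if substitution_matrix is not None
        else substitution_matrices.load("BLOSUM62")
    )
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_global_align(
    a: str,
    b: str,
    substitution_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[str, str, float]:
    """Optimal global alignment (affine gaps); returns gapped strings and score."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(substitution_matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Mismatch fraction over columns where neither sequence is gapped."""
    pairs = [
        (x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
    ]
    if not pairs:
        raise ValueError("no comparable (gap-free) columns")
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def distance_matrix(
    domains: Sequence[tuple[str, str]],
    substitution_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> DistanceMatrix:
    """p-distances on pairwise global alignments of (id, sequence) pairs."""
    if len(domains) < 2:
        raise ValueError("need at least two sequences")
    labels = [d[0] for d in domains]
    n = len(domains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aa, ab, _ = pairwise_global_align(
                domains[i][1], domains[j][1], substitution_matrix, gap_open, gap_extend
            )
            d[i, j] = d[j, i] = p_distance(aa, ab)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ; ties in the Q criterion break to the smallest (i, j)
    index pair; negative branch estimates are clamped to zero (flagged)."""
    labels = list(D.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    adjacency: dict[object, list[tuple[object, float]]] = {lab: [] for lab in labels}
    clamped = False
    unresolved = bool(np.allclose(D.d, 0) and n > 2)

    def connect(u, v, ln):
        nonlocal clamped
        if ln < 0:
            clamped = True
            ln = 0.0
        adjacency[u].append((v, ln))
        adjacency[v].append((u, ln))

    class Internal:
        __slots__ = ("idx",)

        def __init__(self, idx):
            self.idx = idx

        def __repr__(self):
            return f"_n{self.idx}"

    if n == 2:
        mid = Internal(0)
        adjacency[mid] = []
        connect(labels[0], mid, D.d[0, 1] / 2)
        connect(labels[1], mid, D.d[0, 1] / 2)
        return PhyloTree(adjacency, labels, clamped=clamped)

    active: list[object] = list(labels)
    d = D.d.copy()
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        node = Internal(counter)
        counter += 1
        adjacency[node] = []
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        connect(active[i], node, li)
        connect(active[j], node, lj)
        new_row = np.array(
            [max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2) for k in range(m)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [node]
    # close the 3-taxon star with the closed-form branch lengths
    x, y, z = active
    hub = Internal(counter)
    adjacency[hub] = []
    connect(x, hub, (d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    connect(y, hub, (d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    connect(z, hub, (d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    return PhyloTree(adjacency, labels, clamped=clamped, unresolved=unresolved)


# ---------------------------------------------------------------------------
# center-star MSA and bootstrap

def center_star_msa(
    sequences: Sequence[tuple[str, str]],
    substitution_matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> list[tuple[str, str]]:
    """Approximate MSA: align everything to the center sequence (the one
    with maximal summed pairwise alignment score) and merge gaps."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    aligner = _aligner(substitution_matrix, gap_open, gap_extend)
    n = len(sequences)
    score_sum = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(sequences[i][1], sequences[j][1])
            score_sum[i] += s
            score_sum[j] += s
    center = int(np.argmax(score_sum))
    master_center = sequences[center][1]
    rows: list[str] = []          # aligned non-center rows, insertion order
    order: list[int] = []
    for idx, (name, seq) in enumerate(sequences):
        if idx == center:
            continue
        alignment = aligner.align(master_center.replace("-", ""), seq)[0]
        pc, po = str(alignment[0]), str(alignment[1])
        # re-gap pc to the running master, merging the two gapped center versions
        mc = master_center
        new_mc, new_rows, new_po = [], [[] for _ in rows], []
        i = j = 0
        while i < len(mc) or j < len(pc):
            mi = mc[i] if i < len(mc) else None
            pj = pc[j] if j < len(pc) else None
            if mi is not None and pj is not None and (mi == "-") == (pj == "-"):
                new_mc.append(mi)
                for r, row in zip(new_rows, rows):
                    r.append(row[i])
                new_po.append(po[j])
                i += 1
                j += 1
            elif mi == "-":
                new_mc.append("-")
                for r, row in zip(new_rows, rows):
                    r.append(row[i])
                new_po.append("-")
                i += 1
            else:
                # gap in the pair's center: column exists only in the new row
                new_mc.append("-")
                for r in new_rows:
                    r.append("-")
                new_po.append(po[j])
                j += 1
        master_center = "".join(new_mc)
        rows = ["".join(r) for r in new_rows] + ["".join(new_po)]
        order.append(idx)
    out: dict[int, str] = {center: master_center}
    for idx, row in zip(order, rows):
        out[idx] = row
    return [(sequences[i][0], out[i]) for i in range(n)]


def msa_distance_matrix(msa: Sequence[tuple[str, str]]) -> DistanceMatrix:
    labels = [name for name, _ in msa]
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(msa[i][1], msa[j][1])
    return DistanceMatrix(labels=labels, d=d)


def _replicate_distance(msa_array: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    gaps = msa_array == ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            total = int(ok.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0      # no signal: maximal distance
            else:
                d[i, j] = d[j, i] = float(
                    (msa_array[i, ok] != msa_array[j, ok]).sum() / total
                )
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    tree: Optional[PhyloTree] = None,
) -> PhyloTree:
    """Column bootstrap: resample MSA columns with replacement, rebuild NJ,
    report per-bipartition support on the (given or full-data) tree."""
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows differ in length")
    (ncol,) = lengths
    if ncol < 2:
        raise ValueError("need at least two alignment columns")
    labels = [name for name, _ in msa]
    arr = np.array(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for _, s in msa]
    )
    base = tree if tree is not None else neighbor_joining(msa_distance_matrix(msa))
    if base.unresolved:
        base.support = {}
        return base
    targets = base.bipartitions()
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = _replicate_distance(arr[:, cols], labels)
        rep_tree = neighbor_joining(rep)
        rep_bps = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    base.support = {bp: counts[bp] / n_replicates for bp in targets}
    return base


# ---------------------------------------------------------------------------
# group assignment

def assign_groups(
    tree: PhyloTree,
    references: Sequence[tuple[str, str]],
    support_threshold: float = 0.5,
) -> list[GroupAssignment]:
    """Transfer group labels from reference leaves to query leaves.

    A query takes group G by clade evidence when its smallest bipartition
    side containing a reference holds only group-G references with support
    at or above the threshold; otherwise the nearest reference by patristic
    distance decides (ties to the lexicographically first reference id).
    Trees without bootstrap supports treat every bipartition as fully
    supported.
    """
    leaf_set = set(tree.leaf_names)
    ref_group = dict(references)
    missing = sorted(set(ref_group) - leaf_set)
    if missing:
        raise ValueError(f"references absent from tree: {missing}")
    groups = set(ref_group.values())
    if not groups:
        raise ValueError("no references given")
    queries = sorted(leaf_set - set(ref_group))
    sides: list[set[str]] = []
    n = len(tree.leaf_names)
    for u, v, _ in tree.edges():
        side = tree._side(u, v)
        if 1 <= len(side) <= n - 1:
            sides.append(side)
            sides.append(leaf_set - side)
    patristic = tree.patristic_distances()
    out = []
    for q in queries:
        candidate_sides = sorted(
            (s for s in sides if q in s and any(r in s for r in ref_group)),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        assigned = None
        for side in candidate_sides:
            refs_in = {ref_group[r] for r in side if r in ref_group}
            if len(refs_in) != 1:
                break
            key = tree.canonical(side)
            if tree.support is None:
                support = 1.0
            else:
                support = tree.support.get(key, 1.0 if len(side) in (1, n - 1) else 0.0)
            if support >= support_threshold:
                assigned = GroupAssignment(q, refs_in.pop(), "clade", support)
            break
        if assigned is None:
            ranked = sorted(ref_group, key=lambda r: (patristic[(q, r)], r))
            nearest = ranked[0]
            tie = len(ranked) > 1 and np.isclose(
                patristic[(q, ranked[0])], patristic[(q, ranked[1])]
            ) and ref_group[ranked[0]] != ref_group[ranked[1]]
            assigned = GroupAssignment(
                q, ref_group[nearest], "nearest-reference", 0.0, tie=tie
            )
        out.append(assigned)
    return out
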