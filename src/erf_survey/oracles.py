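"""Independent brute-force reference implementations.

Deliberately naive re-derivations used to validate the fast paths:
exhaustive alignment enumeration, exhaustive least-squares topology search,
a fine-grid isoelectric-point scan, and an exhaustive-pathway Nei-Gojobori
count.  None of these share code with the implementations they check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from math import log
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# exhaustive affine-gap global alignment

def brute_force_alignment_score(
    a: str, b: str, substitution_matrix, gap_open: float, gap_extend: float
) -> float:
    """Maximum affine-gap global alignment score by enumerating every
    monotone alignment (op strings over M/I/D).  Exponential; tiny inputs only.
    """

    best = -np.inf

    def score_ops(ops: str) -> float:
        i = j = 0
        total = 0.0
        prev = ""
        for op in ops:
            if op == "M":
                total += substitution_matrix[a[i], b[j]]
                i += 1
                j += 1
            elif op == "D":
                total += gap_open if prev != "D" else gap_extend
                i += 1
            else:
                total += gap_open if prev != "I" else gap_extend
                j += 1
            prev = op
        return total

    def recurse(i: int, j: int, ops: list[str]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_ops("".join(ops)))
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, ops + ["M"])
        if i < len(a):
            recurse(i + 1, j, ops + ["D"])
        if j < len(b):
            recurse(i, j + 1, ops + ["I"])

    recurse(0, 0, [])
    return float(best)


# ---------------------------------------------------------------------------
# exhaustive least-squares topology search

def _all_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Nodes >= n are internal.  Built by sequential edge insertion, giving
    (2n-5)!! distinct topologies.
    """
    if n < 3:
        raise ValueError("need at least three leaves")
    base = [(0, n), (1, n), (2, n)]
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_internal in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                mid = next_internal
                new_edges = edges[:k] + edges[k + 1 :] + [
                    (u, mid),
                    (v, mid),
                    (leaf, mid),
                ]
                nxt.append((new_edges, next_internal + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _paths(edges: Sequence[tuple[int, int]], n_leaves: int) -> dict[tuple[int, int], list[int]]:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for s in range(n_leaves):
        stack = [(s, [])]
        seen = {s}
        while stack:
            node, path = stack.pop()
            if node < n_leaves and node != s:
                if s < node:
                    out[(s, node)] = path
            for nbr, idx in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, path + [idx]))
    return out

def topology_bipartitions(edges: Sequence[tuple[int, int]], n_leaves: int) -> set[frozenset]:
    """Canonical internal bipartitions (side not containing leaf 0)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = set()
    for u, v in edges:
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if 2 <= len(side) <= n_leaves - 2:
            if 0 in side:
                side = set(range(n_leaves)) - side
            out.add(frozenset(side))
    return out


def exhaustive_ls_topology(d: np.ndarray) -> tuple[set[frozenset], float]:
    """Best-fitting topology by non-negative least squares over every
    unrooted topology; returns its bipartitions (leaf indices) and RSS."""
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best_rss = np.inf
    best_bps: set[frozenset] = set()
    for edges in _all_topologies(n):
        paths = _paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            for idx in paths[(i, j)]:
                A[row, idx] = 1.0
        y = np.array([d[i, j] for i, j in pairs])
        _, rnorm = nnls(A, y)
        rss = rnorm**2
        if rss < best_rss - 1e-12:
            best_rss = rss
            best_bps = topology_bipartitions(edges, n)
    return best_bps, float(best_rss)


# ---------------------------------------------------------------------------
# fine-grid isoelectric point (Bjellqvist constants)

_POS_PK = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEG_PK = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
# terminal pKa depends on the terminal residue in the Bjellqvist tables
_NTERM_PK = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_CTERM_PK = {"D": 4.55, "E": 4.75}


def net_charge(sequence: str, ph) -> float | np.ndarray:
    """Net charge at pH (scalar or array), Bjellqvist constants."""
    ph = np.asarray(ph, dtype=float)
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    nterm = _NTERM_PK.get(sequence[0], _POS_PK["Nterm"])
    cterm = _CTERM_PK.get(sequence[-1], _NEG_PK["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm))
    for aa in "KRH":
        charge = charge + counts[aa] / (1.0 + 10 ** (ph - _POS_PK[aa]))
    charge = charge - 1.0 / (1.0 + 10 ** (cterm - ph))
    for aa in "DECY":
        charge = charge - counts[aa] / (1.0 + 10 ** (_NEG_PK[aa] - ph))
    return charge if charge.shape else float(charge)


def grid_search_pi(sequence: str, step: float = 0.001) -> float:
    """pH grid point of minimal absolute net charge."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.abs(net_charge(sequence, grid))
    return float(grid[int(np.argmin(charges))])


# ---------------------------------------------------------------------------
# exhaustive-pathway Nei-Gojobori on a single codon pair

@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


def ng86_codon_oracle(codon_a: str, codon_b: str) -> Optional[tuple[float, float, float, float]]:
    """(S, N, Sd, Nd) for one codon pair, or None when either codon is a stop.

    Stop-creating single changes are excluded from site denominators;
    difference pathways through stops are excluded (all minimal pathways
    used when every one is blocked).
    """
    if _is_stop(codon_a) or _is_stop(codon_b):
        return None
    S = 0.0
    for codon in (codon_a, codon_b):
        for pos in range(3):
            alts = [
                codon[:pos] + base + codon[pos + 1 :]
                for base in "ACGT"
                if base != codon[pos]
            ]
            alts = [alt for alt in alts if not _is_stop(alt)]
            if alts:
                S += sum(1 for alt in alts if _aa(alt) == _aa(codon)) / len(alts)
    S /= 2.0
    N = 3.0 - S
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return S, N, 0.0, 0.0
    ok_paths = []
    all_paths = []
    for order in permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _is_stop(nxt) and nxt != codon_b:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            ok_paths.append(steps)
    paths = ok_paths or all_paths
    sd = nd = 0.0
    for steps in paths:
        for before, after in steps:
            if _aa(before) == _aa(after):
                sd += 1
            else:
                nd += 1
    sd /= len(paths)
    nd /= len(paths)
    return S, N, sd, nd


def ng86_oracle(pairs: Sequence[tuple[str, str]]) -> tuple[Optional[float], Optional[float]]:
    """(ka, ks) over paired codons, Jukes-Cantor corrected; None when the
    correction saturates."""
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        res = ng86_codon_oracle(ca, cb)
        if res is None:
            raise ValueError("stop codon in pair")
        s, n, sd, nd = res
        S += s
        N += n
        Sd += sd
        Nd += nd
    def jc(p: float) -> Optional[float]:
        if p >= 0.75:
            return None
        return 0.0 if p == 0 else -0.75 * log(1 - 4 * p / 3)
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    return jc(pn), jc(ps)
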