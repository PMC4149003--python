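"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
global alignment scores are found by exhaustive enumeration of every
alignment path (exponential, so only tiny inputs), local scores by
maximizing the global oracle over all substring pairs, and additive
distance matrices are built from explicit random trees by path summation.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _subst(x: str, y: str, scheme) -> float:
    if scheme.matrix is not None:
        return float(_BLOSUM62[x, y])
    if scheme.alphabet == "nucleotide" and ("N" in (x, y)):
        return float(scheme.mismatch)
    return float(scheme.match if x == y else scheme.mismatch)


def nw_score_oracle(a: str, b: str, scheme) -> float:
    """Best global alignment score by enumerating every alignment path.

    Gap of length L costs gap_open + L * gap_extend: the first residue of a
    gap run costs open+extend, each further residue costs extend.
    """
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    best = [-np.inf]

    def rec(i: int, j: int, last: str, acc: float) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + _subst(a[i], b[j], scheme))
        if i < len(a):
            rec(i + 1, j, "X", acc - (ge if last == "X" else go + ge))
        if j < len(b):
            rec(i, j + 1, "Y", acc - (ge if last == "Y" else go + ge))

    rec(0, 0, "M", 0.0)
    return best[0]


def sw_score_oracle(a: str, b: str, scheme) -> float:
    """Best local score: max of the global oracle over all substring pairs."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            s = nw_score_oracle(a[i1:i2], b[j1:j2], scheme)
            if s > best:
                best = s
    return best


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random unrooted binary tree with uniform(0.5, 2) branch lengths.

    Returns (taxon_labels, distance_matrix) where the matrix holds exact
    path-length distances on the tree (hence additive by construction).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    adj: dict[object, list[tuple[object, float]]] = {}
    next_internal = [0]

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def blen():
        return rng.uniform(0.5, 2.0)

    center = ("int", next_internal[0])
    next_internal[0] += 1
    for lab in labels[:3]:
        add_edge(lab, center, blen())
    for lab in labels[3:]:
        # pick a random existing edge and subdivide it with a new node
        edges = [(u, v, w) for u in adj for v, w in adj[u] if str(u) < str(v)]
        u, v, w = rng.choice(edges)
        adj[u] = [(x, ww) for x, ww in adj[u] if x != v]
        adj[v] = [(x, ww) for x, ww in adj[v] if x != u]
        mid = ("int", next_internal[0])
        next_internal[0] += 1
        split = rng.uniform(0.2, 0.8)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(lab, mid, blen())

    d = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return labels, d
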