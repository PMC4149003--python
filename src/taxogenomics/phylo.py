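"""Distance-based phylogeny: distances from an MSA, Saitou-Nei
neighbor-joining, column bootstrap with majority-rule consensus, newick I/O.

Distances use pairwise deletion (columns gapped in either member of a pair
are skipped for that pair) under a p-distance, Jukes-Cantor or
Kimura-2-parameter model. Neighbor-joining follows the standard Q-criterion
with deterministic tie-breaking (smallest index pair) and negative branch
length estimates clamped to zero. Trees are held as (unrooted) dendropy
trees; newick round-trips and majority-rule consensus go through dendropy.

Bootstrap supports are bipartition frequencies over column-resampled
replicates, expressed as integer percentages. Zero-length internal edges
are collapsed in each replicate before counting bipartitions, so data with
no signal yields a star-like consensus rather than spurious full support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "distance_from_msa",
    "neighbor_joining",
    "bootstrap_consensus",
    "write_newick",
    "read_newick",
]

GAP = "-"


@dataclass
class DistanceMatrix:
    taxon_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxon_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxon list")
        if len(set(self.taxon_ids)) != n:
            raise ValueError("duplicate taxon ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.taxon_ids)


@dataclass
class PhyloTree:
    """Unrooted branch-length tree, optionally with bootstrap supports.

    Internal-node labels hold integer percent supports after bootstrapping.
    """

    tree: dendropy.Tree

    @property
    def taxon_labels(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def patristic_matrix(self, order: Sequence[str]) -> np.ndarray:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(order)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(taxa[order[i]], taxa[order[j]])
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as leaf-label sets (smaller side)."""
        labels = set(self.taxon_labels)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                other = frozenset(labels - side)
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def supports(self) -> dict[frozenset[str], int]:
        """Map bipartition (smaller side) -> integer percent support."""
        labels = set(self.taxon_labels)
        out: dict[frozenset[str], int] = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                other = frozenset(labels - side)
                key = min(side, other, key=lambda s: (len(s), sorted(s)))
                out[key] = int(node.label)
        return out

    def rooted_on(self, outgroup: str) -> "PhyloTree":
        """Display-rooted copy with the named leaf as outgroup."""
        t = self.tree.clone(depth=1)
        node = t.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not found among leaves")
        t.reroot_at_edge(node.edge, update_bipartitions=False)
        return PhyloTree(t)


def _msa_rows(msa: Sequence[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    ids = [rid for rid, _ in msa]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids in MSA")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows have unequal lengths")
    arr = np.array([list(s.upper()) for _, s in msa])
    return ids, arr


def _model_distance(x: np.ndarray, y: np.ndarray, model: str, pair: tuple[str, str]) -> float:
    ok = (x != GAP) & (y != GAP)
    n_comp = int(ok.sum())
    if n_comp == 0:
        raise ValueError(f"no comparable (gap-free) columns for pair {pair}")
    xs, ys = x[ok], y[ok]
    diff = xs != ys
    p = diff.sum() / n_comp
    if model == "p_distance":
        return float(p)
    if model == "jukes_cantor":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise ValueError(f"Jukes-Cantor distance undefined for pair {pair} (p={p:.3f} >= 0.75)")
        return float(-0.75 * math.log(arg))
    if model == "kimura_2p":
        purines = {"A", "G"}
        is_transition = np.array(
            [a != b and ((a in purines) == (b in purines)) for a, b in zip(xs, ys)]
        )
        P = is_transition.sum() / n_comp
        Q = p - P
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            raise ValueError(f"Kimura-2p distance undefined for pair {pair}")
        return float(-0.5 * math.log(a1) - 0.25 * math.log(a2))
    raise ValueError(f"unknown distance model {model!r}")


def distance_from_msa(msa: Sequence[tuple[str, str]], model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances over an aligned set of sequences (>=3 taxa).

    Columns gapped in either member of a pair are excluded for that pair
    (pairwise deletion).
    """
    ids, arr = _msa_rows(msa)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _model_distance(arr[i], arr[j], model, (ids[i], ids[j]))
    return DistanceMatrix(ids, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining with non-negative branch lengths.

    Exact on additive matrices; Q-criterion ties broken by smallest index
    pair for determinism. Negative branch-length estimates are clamped to 0.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxon_ids)
    nodes: list[dendropy.Node] = []
    for label in dm.taxon_ids:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
    D = dm.d.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        """Join active positions i_pos<j_pos into a new internal node."""
        parent = dendropy.Node()
        ci, cj = nodes[i_pos], nodes[j_pos]
        parent.add_child(ci)
        ci.edge.length = max(0.0, li)
        parent.add_child(cj)
        cj.edge.length = max(0.0, lj)
        nodes[i_pos] = parent
        del nodes[j_pos]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # argmin is first minimum: row-major => smallest index pair
        i_pos, j_pos = sorted(best)
        dij = sub[i_pos, j_pos]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        lj = dij - li
        join(i_pos, j_pos, li, lj)
        # distances from the new node (stored at active[i_pos]) to the rest
        gi, gj = active[i_pos], active[j_pos]
        for k_pos in range(m):
            if k_pos in (i_pos, j_pos):
                continue
            gk = active[k_pos]
            duk = max(0.0, 0.5 * (D[gi, gk] + D[gj, gk] - dij))
            D[gi, gk] = D[gk, gi] = duk
        del active[j_pos]

    # final three-point join
    gi, gj, gk = active
    root = dendropy.Node()
    lx = 0.5 * (D[gi, gj] + D[gi, gk] - D[gj, gk])
    ly = 0.5 * (D[gi, gj] + D[gj, gk] - D[gi, gk])
    lz = 0.5 * (D[gi, gk] + D[gj, gk] - D[gi, gj])
    for child, length in zip(nodes, (lx, ly, lz)):
        root.add_child(child)
        child.edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree)


def _collapse_zero_edges(tree: dendropy.Tree, eps: float = 1e-12) -> None:
    for edge in list(tree.preorder_edge_iter()):
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        if edge.length is not None and edge.length <= eps:
            edge.collapse()


def bootstrap_consensus(
    msa: Sequence[tuple[str, str]],
    model: str = "p_distance",
    n_replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Majority-rule (>50%) consensus of NJ trees over column-resampled MSAs.

    Internal-node labels on the returned tree are integer percent supports.
    Replicate trees have zero-length internal edges collapsed before
    bipartition counting, so uninformative data gives a star-like consensus.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, arr = _msa_rows(msa)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    length = arr.shape[1]
    tns = dendropy.TaxonNamespace(ids)
    trees = dendropy.TreeList(taxon_namespace=tns)
    n = len(ids)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep = arr[:, cols]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _model_distance(rep[i], rep[j], model, (ids[i], ids[j]))
        ptree = neighbor_joining(DistanceMatrix(ids, d))
        t = dendropy.Tree.get(
            data=ptree.newick(), schema="newick", taxon_namespace=tns
        )
        _collapse_zero_edges(t)
        trees.append(t)
    cons = trees.consensus(min_freq=0.5)
    cons.is_rooted = False
    for node in cons.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            node.label = None
            continue
        support = getattr(node, "support", None)
        node.label = str(int(round(100 * support))) if support is not None else None
    return PhyloTree(cons)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    try:
        t = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted parse error types
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
    t.is_rooted = False
    return PhyloTree(t)
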