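"""Alignment-free clustering of variable filler sequences.

The interiors of Ds-l4 elements carry filler DNA unrelated to Ac; families of
related filler can be recovered by pairwise distances and a neighbor-joining
tree.  Distances here are alignment-free: 1 minus the cosine similarity of
k-mer count vectors (k = 8 by default).  Cosine distance is not a metric
(triangle-inequality violations are possible and are logged, not treated as
errors), but it separates filler families cleanly and is orders of magnitude
cheaper than a multiple sequence alignment.

Neighbor joining is the standard Q-criterion agglomeration with deterministic
tie-breaking (lexicographically smallest label pair) and negative branch
lengths clamped to zero.  On additive distance matrices the path-length
matrix of the reconstructed tree equals the input exactly.  Clusters are
obtained by cutting the longest internal edges of the tree.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger("acds")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with labelled rows."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def d(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _kmer_vector(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_distance(seqs: Mapping[str, str], k: int = 8) -> DistanceMatrix:
    """Pairwise 1 - cosine(k-mer count vectors) distances.

    Deterministic; identical sequences are at distance 0 and sequences with
    disjoint k-mer sets at distance 1.  Triangle-inequality violations are
    possible (logged at debug level when detected on small inputs).
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("kmer_distance requires at least two sequences")
    for name in labels:
        if len(seqs[name]) < k:
            raise ValueError(f"sequence {name!r} is shorter than k={k}")
    vectors = {name: _kmer_vector(seqs[name], k) for name in labels}
    norms = {name: math.sqrt(sum(c * c for c in vec.values()))
             for name, vec in vectors.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vi, vj = vectors[labels[i]], vectors[labels[j]]
        if len(vj) < len(vi):
            vi, vj = vj, vi
        dot = sum(c * vj.get(kmer, 0) for kmer, c in vi.items())
        cos = dot / (norms[labels[i]] * norms[labels[j]])
        d[i, j] = d[j, i] = max(0.0, 1.0 - cos)
    return DistanceMatrix(labels, d)


@dataclass
class Node:
    """A node of an (arbitrarily rooted) binary tree with branch lengths."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class NJTree:
    """Unrooted tree from neighbor joining, stored with an arbitrary root."""

    def __init__(self, root: Node):
        self.root = root

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def edges(self) -> list[tuple[Node, Node, float]]:
        out = []

        def walk(node: Node) -> None:
            for child, length in node.children:
                out.append((node, child, length))
                walk(child)

        walk(self.root)
        return out

    def _adjacency(self) -> dict[int, list[tuple[Node, float]]]:
        adj: dict[int, list[tuple[Node, float]]] = {}
        for parent, child, length in self.edges():
            adj.setdefault(id(parent), []).append((child, length))
            adj.setdefault(id(child), []).append((parent, length))
        return adj

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (the tree's additive metric)."""
        adj = self._adjacency()
        leaf_nodes: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                leaf_nodes.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        labels = [n.name for n in leaf_nodes]
        index = {id(n): i for i, n in enumerate(leaf_nodes)}
        n = len(labels)
        d = np.zeros((n, n))
        for src in leaf_nodes:
            dist = {id(src): 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nxt, w in adj.get(id(cur), []):
                    if id(nxt) not in dist:
                        dist[id(nxt)] = dist[id(cur)] + w
                        stack.append(nxt)
            i = index[id(src)]
            for other in leaf_nodes:
                d[i, index[id(other)]] = dist[id(other)]
        order = sorted(range(n), key=lambda i: labels[i])
        return DistanceMatrix([labels[i] for i in order], d[np.ix_(order, order)])

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{length:.10g}"
                             for c, length in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"


def neighbor_joining(matrix: DistanceMatrix) -> NJTree:
    """Standard neighbor joining with deterministic tie-breaking.

    The minimal-Q pair is joined at each step; ties are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest member leaf).  Negative branch lengths are clamped to
    zero with a log note.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[Node] = [Node(name) for name in matrix.labels]
    tags: list[str] = list(matrix.labels)        # tie-break labels
    d = matrix.values.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # only the upper triangle: q[a,b] and q[b,a] can differ by an ulp
        q[np.tril_indices(m)] = np.inf
        qmin = q.min()
        ties = np.argwhere(q == qmin)
        i, j = min((tuple(sorted((tags[a], tags[b]))), a, b)
                   for a, b in ties)[1:]
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_d = np.zeros((m - 1, m - 1))
        keep = [x for x in range(m) if x not in (i, j)]
        for a, x in enumerate(keep):
            for b, y in enumerate(keep):
                new_d[a, b] = d[x, y]
            new_d[a, m - 2] = new_d[m - 2, a] = (d[x, i] + d[x, j] - d[i, j]) / 2
        nodes = [nodes[x] for x in keep] + [parent]
        tags = [tags[x] for x in keep] + [min(tags[i], tags[j])]
        d = new_d

    # resolve the final three clusters with the three-point formulas
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    root = Node(children=[(a, clamp(la)), (b, clamp(lb)), (c, clamp(lc))])
    return NJTree(root)


def cut_clusters(tree: NJTree, n_clusters: int) -> list[set[str]]:
    """Partition leaves by removing the longest internal edges of the tree.

    ``n_clusters - 1`` edges are cut, preferring internal edges (both ends
    internal nodes); leaf edges are used only when the tree has too few
    internal edges.  The returned blocks are disjoint, cover all leaves, and
    are sorted by their smallest member.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    leaves = tree.leaves()
    if n_clusters > len(leaves):
        raise ValueError("more clusters requested than leaves")
    edges = tree.edges()
    internal = [e for e in edges if not e[1].is_leaf]
    external = [e for e in edges if e[1].is_leaf]
    ranked = (sorted(internal, key=lambda e: -e[2])
              + sorted(external, key=lambda e: -e[2]))
    node_by_id: dict[int, Node] = {id(tree.root): tree.root}
    for p, c, _ in edges:
        node_by_id[id(p)] = p
        node_by_id[id(c)] = c

    def leaf_blocks(cut: set[tuple[int, int]]) -> list[set[str]]:
        adj: dict[int, list[Node]] = {}
        for p, c, _ in edges:
            if (id(p), id(c)) in cut:
                continue
            adj.setdefault(id(p), []).append(c)
            adj.setdefault(id(c), []).append(p)
        seen: set[int] = set()
        blocks: list[set[str]] = []
        for nid, start in node_by_id.items():
            if nid in seen:
                continue
            comp: set[str] = set()
            stack = [start]
            seen.add(nid)
            while stack:
                cur = stack.pop()
                if cur.is_leaf:
                    comp.add(cur.name)
                for nxt in adj.get(id(cur), []):
                    if id(nxt) not in seen:
                        seen.add(id(nxt))
                        stack.append(nxt)
            if comp:
                blocks.append(comp)
        return blocks

    # cut edges longest-first, skipping cuts that strand a leafless
    # component (those would not split the leaf partition further)
    cut: set[tuple[int, int]] = set()
    blocks = leaf_blocks(cut)
    for p, c, _ in ranked:
        if len(blocks) >= n_clusters:
            break
        trial = cut | {(id(p), id(c))}
        trial_blocks = leaf_blocks(trial)
        if len(trial_blocks) > len(blocks):
            cut, blocks = trial, trial_blocks
    blocks.sort(key=lambda block: min(block))
    return blocks
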