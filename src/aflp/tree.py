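"""Neighbor-joining clustering of samples and Newick output.

Implements the Saitou-Nei agglomerative algorithm with the standard
Q-criterion on a dissimilarity matrix.  The distance update after a join
is the *unweighted* variant: the distance from the new node to every
other cluster is the plain average of ``d - branch`` over the joined
clusters' constituent taxa (i.e. weighted by taxon counts), rather than
the classical half-and-half update.  On an additive matrix both rules
are exact; on noisy data the taxon-count average uses every underlying
sample and places outliers more stably.  Two further behaviors are
pinned down for reproducibility:

* ties in the Q-minimization are broken toward the lexicographically
  smallest active pair, so identical inputs give identical trees;
* a negative branch length at a join is clamped to zero and its deficit
  transferred to the sister branch (total preserved); the raw, unclamped
  values are retained in ``Tree.raw_branch_lengths`` for diagnostics.

The resulting tree is unrooted; it is represented with a basal node of
degree three (degree two for the two-taxon case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import DistanceMatrix

__all__ = ["Node", "Tree", "nj_tree", "write_newick"]


@dataclass
class Node:
    """A tree node; ``children`` holds (child, branch length) pairs."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """An unrooted tree over the sample ids, stored from a basal node."""

    root: Node
    leaf_names: tuple[str, ...]
    raw_branch_lengths: list[float] = field(default_factory=list)

    def newick(self) -> str:
        return write_newick(self)

    def _edges(self):
        """(parent, child, length) over all branches."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                yield node, child, length
                stack.append(child)

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set splits induced by every branch; each split is reported
        as the frozenset of leaf names on the child side."""
        out = set()
        for _, child, _ in self._edges():
            side = frozenset(leaf.name for leaf in child.leaves())
            out.add(side)
        return out

    def has_bipartition(self, names) -> bool:
        """True if some branch separates exactly *names* from the rest."""
        target = frozenset(names)
        rest = frozenset(self.leaf_names) - target
        parts = self.bipartitions()
        return target in parts or rest in parts

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances along the tree."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: Node):
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, length in node.children:
                cid = id(child)
                adj.setdefault(cid, []).append((nid, length))
                adj[nid].append((cid, length))
                walk(child)

        walk(self.root)
        leaf_ids = {names[k]: k for k in names}
        order = list(self.leaf_names)
        n = len(order)
        D = np.zeros((n, n))
        for i, name in enumerate(order):
            # Dijkstra is overkill on a tree; simple DFS accumulation
            dist = {leaf_ids[name]: 0.0}
            stack = [leaf_ids[name]]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(order):
                D[i, j] = dist[leaf_ids[other]]
        np.fill_diagonal(D, 0.0)
        return DistanceMatrix(ids=tuple(order), values=(D + D.T) / 2)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths at a join, moving the deficit to the
    sister branch so the path length between the pair is preserved."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a sample dissimilarity matrix.

    Requires at least two samples; two samples yield the single-edge tree
    (drawn with the distance split evenly around the basal node).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("at least two samples are required")
    D = dm.values.copy()
    raw_lengths: list[float] = []

    if n == 2:
        d = float(D[0, 1])
        root = Node(children=[(Node(dm.ids[0]), d / 2), (Node(dm.ids[1]), d / 2)])
        return Tree(root, tuple(dm.ids), [d / 2, d / 2])

    nodes: list[Node] = [Node(name) for name in dm.ids]
    sizes: list[int] = [1] * n  # taxa per active cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # argmin over the upper triangle in row-major order: the first
        # occurrence of the minimum is the lexicographically smallest pair
        iu = np.triu_indices(m, 1)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        raw_lengths.extend([li, lj])
        li, lj = _clamp_pair(li, lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])

        keep = [k for k in range(m) if k not in (i, j)]
        # unweighted update: average d - branch over constituent taxa
        lam = sizes[i] / (sizes[i] + sizes[j])
        new_row = lam * (D[i, keep] - li) + (1 - lam) * (D[j, keep] - lj)
        new_row = np.maximum(new_row, 0.0)
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row
        D2[:-1, -1] = new_row
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]

    # resolve the last three nodes around a basal node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    raw_lengths.extend([l0, l1, l2])
    root = Node(
        children=[
            (nodes[0], max(l0, 0.0)),
            (nodes[1], max(l1, 0.0)),
            (nodes[2], max(l2, 0.0)),
        ]
    )
    return Tree(root, tuple(dm.ids), raw_lengths)


def _format_label(name: str) -> str:
    safe = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")
    if name and set(name) <= safe:
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(node: Node) -> str:
    if node.is_leaf:
        return _format_label(node.name or "")
    inner = ",".join(
        f"{_newick_node(child)}:{length:.6f}" for child, length in node.children
    )
    return f"({inner})"


def write_newick(tree: Tree) -> str:
    """Newick 1.0 with branch lengths in 6-decimal fixed format.

    Leaf labels containing characters outside ``[A-Za-z0-9_.-]`` (spaces
    in particular) are single-quoted.  Round-trips through standard
    Newick readers.
    """
    return _newick_node(tree.root) + ";"
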