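"""Coancestry network construction and recursive Leiden clustering.

The network has one node per individual and symmetrised chunkcount edges,
band-filtered to suppress both deep (weak) and very recent (close-relative)
relationships.  Leiden community detection is applied recursively: each
community is re-clustered on its induced subgraph down to a maximum depth,
with communities below a minimum size never subdivided.  The result is a
cluster tree whose leaves partition the individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .paint import CoancestryMatrix


def build_graph(chunkcounts, low: float = 2.0, high: float = 25.0) -> ig.Graph:
    """Undirected coancestry graph with w_ij = (c_ij + c_ji)/2, keeping
    strictly low < w < high; isolated nodes are retained."""
    if isinstance(chunkcounts, CoancestryMatrix):
        chunkcounts = chunkcounts.chunkcounts
    if isinstance(chunkcounts, pd.DataFrame):
        ids = list(chunkcounts.index)
        M = chunkcounts.values
    else:
        M = np.asarray(chunkcounts, dtype=float)
        ids = [str(i) for i in range(M.shape[0])]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("chunkcounts must be square")
    W = (M + M.T) / 2.0
    iu, ju = np.triu_indices(W.shape[0], k=1)
    w = W[iu, ju]
    keep = (w > low) & (w < high)
    g = ig.Graph(
        n=W.shape[0],
        edges=list(zip(iu[keep].tolist(), ju[keep].tolist())),
        edge_attrs={"weight": w[keep].tolist()},
    )
    g.vs["name"] = ids
    return g


@dataclass
class ClusterNode:
    label: str  # path in the tree, e.g. "0.2.1"
    members: list  # individual ids
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    root: ClusterNode
    max_depth: int
    min_size: int

    def leaves(self) -> list:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def assignment(self) -> pd.Series:
        """individual id -> leaf label."""
        data = {}
        for leaf in self.leaves():
            for m in leaf.members:
                data[m] = leaf.label
        return pd.Series(data, name="cluster")

    def to_newick(self) -> str:
        def rec(node: ClusterNode) -> str:
            if node.is_leaf:
                return node.label.replace(".", "_")
            return "(" + ",".join(rec(c) for c in node.children) + ")" + node.label.replace(".", "_")

        return rec(self.root) + ";"


def _membership(groups, n: int) -> list:
    lab = [0] * n
    for ci, idxs in enumerate(groups):
        for i in idxs:
            lab[i] = ci
    return lab


def _null_modularity(g: ig.Graph, seed: int, n_null: int, resolution: float) -> float:
    """Mean modularity that Leiden attains on degree-preserving rewirings of
    the graph with shuffled weights — the no-structure baseline."""
    import random as _pyrandom

    rng = np.random.default_rng(seed)
    out = []
    state = _pyrandom.getstate()
    try:
        for r in range(n_null):
            null = g.copy()
            _pyrandom.seed(int(rng.integers(2**31)))
            null.rewire(n=10 * null.ecount())
            w = np.array(g.es["weight"], dtype=float)
            rng.shuffle(w)
            null.es["weight"] = list(w)
            part = leidenalg.find_partition(
                null,
                leidenalg.RBConfigurationVertexPartition,
                weights="weight",
                resolution_parameter=resolution,
                seed=int(rng.integers(2**31)),
                n_iterations=-1,
            )
            out.append(
                null.modularity(_membership(list(part), null.vcount()), weights=null.es["weight"])
            )
    finally:
        _pyrandom.setstate(state)
    return float(np.mean(out))


def leiden_recursive(
    graph: ig.Graph,
    max_depth: int = 4,
    min_size: int = 100,
    resolution: float = 1.0,
    seed: int = 0,
    min_gain: float = 0.1,
    n_null: int = 3,
) -> ClusterTree:
    """Recursive Leiden partition (weighted modularity-type quality).

    A community is subdivided only while (a) it has at least ``min_size``
    members, (b) the depth bound is not reached, and (c) the proposed
    sub-partition is supported by the data: its modularity must exceed, by
    ``min_gain``, the modularity Leiden attains on degree-preserving
    rewirings of the same subgraph (homogeneous communities are left whole
    instead of being shredded into noise clusters).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    names = graph.vs["name"] if "name" in graph.vs.attributes() else [
        str(i) for i in range(graph.vcount())
    ]

    def rec(g: ig.Graph, member_names: list, label: str, depth: int) -> ClusterNode:
        node = ClusterNode(label=label, members=member_names)
        if depth >= max_depth or len(member_names) < min_size or g.ecount() == 0:
            return node
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed + depth,
            n_iterations=-1,
        )
        groups = list(part)
        if len(groups) <= 1:
            return node
        q_obs = g.modularity(_membership(groups, g.vcount()), weights=g.es["weight"])
        q_null = _null_modularity(g, seed + depth + 1, n_null, resolution)
        if q_obs - q_null < min_gain:
            return node
        for ci, idxs in enumerate(groups):
            sub = g.induced_subgraph(idxs)
            sub_names = [member_names[i] for i in idxs]
            child_label = f"{label}.{ci}" if label else str(ci)
            node.children.append(rec(sub, sub_names, child_label, depth + 1))
        return node

    root = rec(graph, list(names), "", 0)
    if root.is_leaf and not root.label:
        root.label = "0"
    return ClusterTree(root=root, max_depth=max_depth, min_size=min_size)
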