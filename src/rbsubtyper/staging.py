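"""Differentiation staging against an organoid time-course, and
minimal-evolution phylogenies on cone-marker expression.

Tumor subtype centroids are staged by Pearson correlation of an 8-gene
cone-differentiation panel against retinal-organoid centroids per
differentiation time point.  Phylogenies over samples and organoids are
inferred from the Euclidean distance on the panel genes, by neighbor
joining or by balanced minimum evolution (NJ start, nearest-neighbor-
interchange search on the Pauplin length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from .matrix import OmicsMatrix
from .simulate import CONE_PANEL, timepoint_of_column


@dataclass
class StagingPanel:
    """Ordered marker panel with early/late designation."""

    markers: Sequence[str] = tuple(CONE_PANEL)
    early: Sequence[str] = tuple(CONE_PANEL[:4])
    late: Sequence[str] = tuple(CONE_PANEL[4:])

    def __post_init__(self) -> None:
        m = list(self.markers)
        if len(m) < 3:
            raise ValueError("panel needs at least 3 markers")
        if len(set(m)) != len(m):
            raise ValueError("duplicate markers in panel")


def _check_panel(features, panel: StagingPanel) -> List[str]:
    missing = [g for g in panel.markers if g not in features]
    if missing:
        raise ValueError(f"panel gene(s) missing from matrix: {missing}")
    return list(panel.markers)


def organoid_centroids(organoids: OmicsMatrix,
                       panel: Optional[StagingPanel] = None) -> pd.DataFrame:
    """Median expression per differentiation time point (genes x days)."""
    panel = panel or StagingPanel()
    genes = _check_panel(organoids.features, panel)
    days = sorted({timepoint_of_column(c) for c in organoids.samples})
    out = {}
    for d in days:
        cols = [c for c in organoids.samples if timepoint_of_column(c) == d]
        out[d] = organoids.values.loc[genes, cols].median(axis=1)
    return pd.DataFrame(out)


def stage_by_centroid_correlation(group_centroids: pd.DataFrame,
                                  organoids: OmicsMatrix,
                                  panel: Optional[StagingPanel] = None
                                  ) -> Tuple[pd.DataFrame, pd.Series]:
    """Correlate group centroids with organoid time points over the panel.

    Returns the (group x time point) Pearson correlation table and the
    assigned stage per group (argmax correlation; ties resolved toward
    the latest time point).
    """
    panel = panel or StagingPanel()
    genes = _check_panel(group_centroids.index, panel)
    oc = organoid_centroids(organoids, panel)
    corr = pd.DataFrame(index=group_centroids.columns, columns=oc.columns,
                        dtype=float)
    for g in group_centroids.columns:
        q = group_centroids.loc[genes, g].to_numpy(dtype=float)
        if np.std(q) == 0:
            raise ValueError(f"constant profile for group {g!r}: "
                             "correlation undefined")
        for d in oc.columns:
            corr.loc[g, d] = float(np.corrcoef(q, oc[d].to_numpy())[0, 1])
    assigned = {}
    for g in corr.index:
        row = corr.loc[g]
        best = row.max()
        assigned[g] = max(d for d in row.index if row[d] == best)
    return corr, pd.Series(assigned, name="stage")


def euclidean_distance_matrix(matrix: OmicsMatrix,
                              panel: Optional[StagingPanel] = None
                              ) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over the panel genes."""
    panel = panel or StagingPanel()
    genes = _check_panel(matrix.features, panel)
    X = matrix.values.loc[genes].to_numpy(dtype=float).T
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(D, index=matrix.samples, columns=matrix.samples)


# ---------------------------------------------------------------------------
# minimal-evolution trees

def _validate_distmat(distmat: pd.DataFrame) -> None:
    D = distmat.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix diagonal must be zero")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if distmat.shape[0] < 3:
        raise ValueError("need at least 3 taxa")


class _Topology:
    """Unrooted binary tree as an adjacency map over integer node ids."""

    def __init__(self, adj: Dict[int, Set[int]], leaf_name: Dict[int, str]):
        self.adj = adj
        self.leaf_name = leaf_name

    @classmethod
    def from_treenode(cls, tree: TreeNode) -> "_Topology":
        adj: Dict[int, Set[int]] = {}
        leaf_name: Dict[int, str] = {}
        ids: Dict[int, int] = {}

        def nid(node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = len(ids)
                adj[ids[key]] = set()
            return ids[key]

        for node in tree.traverse(include_self=True):
            u = nid(node)
            if node.is_tip():
                leaf_name[u] = node.name
            for child in node.children:
                v = nid(child)
                adj[u].add(v)
                adj[v].add(u)
        topo = cls(adj, leaf_name)
        topo._suppress_degree_two()
        return topo

    def _suppress_degree_two(self) -> None:
        # a rooted binary tree read as unrooted has a degree-2 root
        for u in list(self.adj):
            if u not in self.leaf_name and len(self.adj[u]) == 2:
                a, b = sorted(self.adj[u])
                self.adj[a].discard(u)
                self.adj[b].discard(u)
                self.adj[a].add(b)
                self.adj[b].add(a)
                del self.adj[u]

    def leaves(self) -> List[int]:
        return sorted(self.leaf_name)

    def leaf_edge_counts(self) -> Dict[Tuple[int, int], int]:
        """Topological (edge-count) distances between all leaf pairs."""
        from collections import deque
        out: Dict[Tuple[int, int], int] = {}
        for src in self.leaves():
            dist = {src: 0}
            dq = deque([src])
            while dq:
                u = dq.popleft()
                for v in self.adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        dq.append(v)
            for dst in self.leaves():
                if dst > src:
                    out[(src, dst)] = dist[dst]
        return out

    def internal_edges(self) -> List[Tuple[int, int]]:
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if u < v and u not in self.leaf_name and v not in self.leaf_name:
                    out.append((u, v))
        return sorted(out)


def _balanced_length(topo: _Topology, D: pd.DataFrame,
                     name_of: Dict[int, str]) -> float:
    """Pauplin's balanced tree length: sum_ij D_ij * 2^(1 - p_ij)."""
    total = 0.0
    for (i, j), p in topo.leaf_edge_counts().items():
        total += D.loc[name_of[i], name_of[j]] * 2.0 ** (1 - p)
    return total


def _nni_neighbors(topo: _Topology, edge: Tuple[int, int]):
    """Yield the two NNI rearrangements across an internal edge."""
    u, v = edge
    a, b = sorted(n for n in topo.adj[u] if n != v)
    c, d = sorted(n for n in topo.adj[v] if n != u)
    for (x, y) in ((b, c), (b, d)):
        adj = {k: set(s) for k, s in topo.adj.items()}
        adj[u].discard(x); adj[x].discard(u)
        adj[v].discard(y); adj[y].discard(v)
        adj[u].add(y); adj[y].add(u)
        adj[v].add(x); adj[x].add(v)
        yield _Topology(adj, topo.leaf_name)


def _ols_branch_lengths(topo: _Topology, D: pd.DataFrame) -> Dict[Tuple[int, int], float]:
    """Least-squares branch lengths on a fixed topology, clamped at 0."""
    from collections import deque
    edges = sorted({tuple(sorted((u, v)))
                    for u in topo.adj for v in topo.adj[u]})
    eidx = {e: i for i, e in enumerate(edges)}
    leaves = topo.leaves()
    rows, rhs = [], []
    for ii, src in enumerate(leaves):
        # BFS recording the edge path to every other node
        prev = {src: None}
        dq = deque([src])
        while dq:
            u = dq.popleft()
            for v in topo.adj[u]:
                if v not in prev:
                    prev[v] = u
                    dq.append(v)
        for dst in leaves[ii + 1:]:
            row = np.zeros(len(edges))
            node = dst
            while prev[node] is not None:
                e = tuple(sorted((node, prev[node])))
                row[eidx[e]] = 1.0
                node = prev[node]
            rows.append(row)
            rhs.append(D.loc[topo.leaf_name[src], topo.leaf_name[dst]])
    A = np.vstack(rows)
    b, *_ = np.linalg.lstsq(A, np.asarray(rhs, float), rcond=None)
    return {e: max(0.0, float(b[i])) for e, i in eidx.items()}


def _to_newick(topo: _Topology, lengths: Dict[Tuple[int, int], float]) -> str:
    # root at the internal node adjacent to the lowest-id leaf
    leaves = topo.leaves()
    root = next(iter(topo.adj[leaves[0]]))
    if root in topo.leaf_name:  # 2-leaf degenerate case
        root = leaves[0]

    def fmt(u: int, parent: Optional[int]) -> str:
        children = [v for v in topo.adj[u] if v != parent]
        if not children:
            label = topo.leaf_name[u]
        else:
            label = "(" + ",".join(fmt(v, u) for v in sorted(children)) + ")"
        if parent is None:
            return label + ";"
        br = lengths[tuple(sorted((u, parent)))]
        return f"{label}:{br:.6g}"

    return fmt(root, None)


@dataclass
class MeTree:
    """A minimal-evolution tree with its newick serialization."""

    newick: str
    balanced_length: float
    method: str

    def as_treenode(self) -> TreeNode:
        return TreeNode.read([self.newick])


def build_me_tree(distmat: pd.DataFrame, method: str = "balanced_me") -> MeTree:
    """Infer an unrooted tree by NJ or balanced minimum evolution.

    ``nj`` returns the neighbor-joining tree (negative branch lengths
    clamped to zero).  ``balanced_me`` starts from the NJ topology and
    applies nearest-neighbor-interchange moves while the Pauplin balanced
    tree length improves, then fits ordinary-least-squares branch lengths.
    """
    _validate_distmat(distmat)
    ids = [str(t) for t in distmat.index]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon labels")
    distmat = pd.DataFrame(distmat.to_numpy(dtype=float), index=ids, columns=ids)
    dm = DistanceMatrix(distmat.to_numpy(dtype=float), ids=ids)
    njt = skbio_nj(dm, neg_as_zero=True)
    if method == "nj":
        topo = _Topology.from_treenode(njt)
        name_of = topo.leaf_name
        return MeTree(newick=str(njt).strip(), method="nj",
                      balanced_length=_balanced_length(topo, distmat, name_of))
    if method != "balanced_me":
        raise ValueError("method must be 'nj' or 'balanced_me'")
    topo = _Topology.from_treenode(njt)
    best_len = _balanced_length(topo, distmat, topo.leaf_name)
    improved = True
    while improved:
        improved = False
        for edge in topo.internal_edges():
            for cand in _nni_neighbors(topo, edge):
                L = _balanced_length(cand, distmat, cand.leaf_name)
                if L < best_len - 1e-12:
                    topo, best_len, improved = cand, L, True
                    break
            if improved:
                break
    lengths = _ols_branch_lengths(topo, distmat)
    return MeTree(newick=_to_newick(topo, lengths),
                  balanced_length=best_len, method="balanced_me")
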