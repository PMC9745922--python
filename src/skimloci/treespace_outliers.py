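"""Gene-tree treespace analysis: tree distances, ordination, outlier flagging.

Per-locus gene trees estimated from shallow skim data vary in quality; loci
whose trees sit far from the cloud of gene trees are candidate artifacts
(alignment error, paralogy, starved signal). The treespace procedure builds a
pairwise tree distance matrix (quartet distance by default, Robinson-Foulds as
an alternative), ordinates it by classical Principal Coordinates Analysis,
flags outliers by squared Mahalanobis distance on the first axes (upper-tail
chi-square p below alpha), and compares locus descriptors between flagged and
unflagged loci with rank-sum tests under Holm multiple-testing adjustment.

Quartet topologies are inferred from the four-point condition on topological
(unit-branch-length) path distances: for tips i,j,k,l the pairing with the
strictly smallest distance sum is the induced resolution, and a three-way tie
means the quartet is unresolved (star). An unresolved-vs-resolved quartet pair
counts as half a difference; two conflicting resolutions count as one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .seq_io import parse_newick

logger = logging.getLogger(__name__)

UNRESOLVED = 3  # sentinel in quartet resolution vectors
MISSING_FOR_DISTANCE = frozenset("N-?RYSWKMBDHV")


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _nontrivial_bipartitions(tree: dendropy.Tree, tips: set[str]) -> set[frozenset]:
    """Bipartitions induced on ``tips``, as unordered side pairs; trivial
    (singleton / full-set) splits excluded. Restricting to a tip subset gives
    the induced subtree's splits."""
    n = len(tips)
    splits: set[frozenset] = set()
    clades: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[id(node)] = {node.taxon.label} & tips
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= clades[id(child)]
            clades[id(node)] = acc
            side = acc
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset({frozenset(side), frozenset(tips - side)}))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree.

    The trees must carry identical tip sets; prune first if they do not.
    """
    tips1, tips2 = tip_labels(t1), tip_labels(t2)
    if tips1 != tips2:
        raise ValueError(
            f"tip sets differ; symmetric difference: {sorted(tips1 ^ tips2)}"
        )
    b1 = _nontrivial_bipartitions(t1, tips1)
    b2 = _nontrivial_bipartitions(t2, tips1)
    return len(b1 ^ b2)


def _topo_distances(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Pairwise path lengths in edges between the named tips (BFS per tip)."""
    # adjacency over all nodes
    adj: dict[int, list[int]] = {}
    nodes: dict[int, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.child_nodes():
            adj.setdefault(id(child), [])
            adj[id(node)].append(id(child))
            adj[id(child)].append(id(node))
    leaf_of = {
        leaf.taxon.label: id(leaf)
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label in set(labels)
    }
    idx = {lab: i for i, lab in enumerate(labels)}
    s = len(labels)
    D = np.zeros((s, s), dtype=np.int64)
    for lab in labels:
        start = leaf_of[lab]
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for other, j in idx.items():
            D[idx[lab], j] = dist[leaf_of[other]]
    return D


def quartet_resolution_vector(
    tree: dendropy.Tree, labels: Sequence[str]
) -> np.ndarray:
    """Induced resolution of every 4-subset of ``labels``: 0 for ij|kl, 1 for
    ik|jl, 2 for il|jk (subsets in lexicographic index order), 3 unresolved."""
    s = len(labels)
    if s < 4:
        raise ValueError("need >= 4 tips for quartets")
    D = _topo_distances(tree, labels)
    quads = np.array(list(itertools.combinations(range(s), 4)))
    i, j, k, l = quads.T
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    mins = sums.min(axis=0)
    n_at_min = (sums == mins).sum(axis=0)
    return np.where(n_at_min == 1, sums.argmin(axis=0), UNRESOLVED)


def _quartet_diff(r1: np.ndarray, r2: np.ndarray) -> float:
    """Weighted count of differing quartets between two resolution vectors."""
    both = (r1 != UNRESOLVED) & (r2 != UNRESOLVED)
    conflicting = float(np.sum(both & (r1 != r2)))
    one_sided = float(np.sum((r1 == UNRESOLVED) ^ (r2 == UNRESOLVED)))
    return conflicting + 0.5 * one_sided


def quartet_distance(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[float, int]:
    """(weighted number of differing quartets, number of shared-tip quartets).

    Trees are restricted to their shared tips; fewer than 4 shared tips makes
    the distance undefined (error). Divide the two to normalize.
    """
    shared = sorted(tip_labels(t1) & tip_labels(t2))
    if len(shared) < 4:
        raise ValueError(
            f"quartet distance undefined: only {len(shared)} shared tips"
        )
    r1 = quartet_resolution_vector(t1, shared)
    r2 = quartet_resolution_vector(t2, shared)
    return _quartet_diff(r1, r2), len(r1)


def build_distance_matrix(
    trees: Sequence[dendropy.Tree], metric: str = "quartet"
) -> np.ndarray:
    """Pairwise normalized tree distances (quartet: fraction of differing
    quartets; rf: fraction of the 2(s-3) maximum on shared tips).

    Pairs with an undefined distance (too few shared tips) are mean-imputed so
    ordination keeps every tree aligned with its locus; imputation is logged.
    """
    if metric not in {"quartet", "rf"}:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(trees)
    if n < 3:
        raise ValueError("need >= 3 trees for a distance matrix")
    tipsets = [tip_labels(t) for t in trees]
    D = np.zeros((n, n))
    same_tips = all(ts == tipsets[0] for ts in tipsets)

    if metric == "quartet" and same_tips:
        labels = sorted(tipsets[0])
        vecs = [quartet_resolution_vector(t, labels) for t in trees]
        total = len(vecs[0])
        for a in range(n):
            for b in range(a + 1, n):
                D[a, b] = D[b, a] = _quartet_diff(vecs[a], vecs[b]) / total
        return D

    undefined = []
    for a in range(n):
        for b in range(a + 1, n):
            shared = tipsets[a] & tipsets[b]
            s = len(shared)
            try:
                if metric == "quartet":
                    diff, total = quartet_distance(trees[a], trees[b])
                    d = diff / total
                else:
                    if s < 4:
                        raise ValueError("too few shared tips")
                    ba = _nontrivial_bipartitions(trees[a], shared)
                    bb = _nontrivial_bipartitions(trees[b], shared)
                    denom = 2 * (s - 3)
                    d = len(ba ^ bb) / denom if denom > 0 else np.nan
                    if np.isnan(d):
                        raise ValueError("normalization undefined")
            except ValueError:
                undefined.append((a, b))
                d = np.nan
            D[a, b] = D[b, a] = d
    if undefined:
        off_diag = D[~np.eye(n, dtype=bool)]
        fill = float(np.nanmean(off_diag))
        logger.warning(
            "mean-imputing %d undefined tree-pair distances with %.4f",
            len(undefined), fill,
        )
        for a, b in undefined:
            D[a, b] = D[b, a] = fill
    return D


def pcoa(distance_matrix: np.ndarray, n_axes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Classical (metric) PCoA by double-centering of -D^2/2.

    Axes with negative eigenvalues are dropped (no Lingoes/Cailliez
    correction); returns coordinates for min(n_axes, positive axes) and the
    full descending eigenvalue spectrum.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    positive = eigval > tol
    n_keep = min(n_axes, int(positive.sum()))
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    return coords, eigval


def mahalanobis_outliers(
    coords: np.ndarray, n_axes: int = 3, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Squared Mahalanobis distance of each row on the first ``n_axes`` axes,
    chi-square upper-tail p (df = n_axes), and flags where p < alpha."""
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2:
        raise ValueError("coords must be 2-D")
    n_axes = min(n_axes, X.shape[1])
    X = X[:, :n_axes]
    if X.shape[0] <= n_axes + 1:
        raise ValueError("need more rows than axes + 1")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance on the chosen axes; use fewer axes"
        ) from exc
    diff = X - center
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    pvals = sps.chi2.sf(d2, df=n_axes)
    return d2, pvals, pvals < alpha


@dataclass
class TreespaceResult:
    tree_ids: list[str]
    distances: np.ndarray
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    mahalanobis_d2: np.ndarray
    p_values: np.ndarray
    outlier_flags: np.ndarray

    def outliers(self) -> list[str]:
        return [tid for tid, f in zip(self.tree_ids, self.outlier_flags) if f]


def analyze_treespace(
    trees: Sequence[dendropy.Tree],
    tree_ids: Sequence[str] | None = None,
    metric: str = "quartet",
    n_axes: int = 3,
    alpha: float = 0.05,
) -> TreespaceResult:
    """Distance matrix -> PCoA -> Mahalanobis flagging, in one call."""
    ids = list(tree_ids) if tree_ids is not None else [f"tree{i}" for i in range(len(trees))]
    if len(ids) != len(trees):
        raise ValueError("tree_ids length must match trees")
    D = build_distance_matrix(trees, metric=metric)
    coords, eigval = pcoa(D, n_axes=n_axes)
    d2, pvals, flags = mahalanobis_outliers(coords, n_axes=n_axes, alpha=alpha)
    return TreespaceResult(ids, D, coords, eigval, d2, pvals, flags)


def compare_groups(
    descriptors: pd.DataFrame, flags: Sequence[bool]
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of every numeric descriptor between
    flagged and unflagged loci, Holm-adjusted across the descriptor family.

    Returns a table with columns (metric, W, p_raw, p_holm); W is the
    rank-sum statistic of the flagged group.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(descriptors):
        raise ValueError("flags length must match descriptor rows")
    if flags.all() or not flags.any():
        raise ValueError("both groups must be non-empty")
    metrics, stats_, praw = [], [], []
    for col in descriptors.columns:
        x = descriptors.loc[flags, col].to_numpy(dtype=float)
        y = descriptors.loc[~flags, col].to_numpy(dtype=float)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        metrics.append(col)
        stats_.append(float(res.statistic))
        praw.append(float(res.pvalue))
    _, p_holm, _, _ = multipletests(praw, method="holm")
    return pd.DataFrame(
        {"metric": metrics, "W": stats_, "p_raw": praw, "p_holm": p_holm}
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone cumulative-max form)."""
    _, adj, _, _ = multipletests(list(pvalues), method="holm")
    return adj


def _edge_supports(tree: dendropy.Tree) -> list[float]:
    vals = []
    for node in tree.internal_nodes():
        support = getattr(node.edge, "support", None)
        if support is None and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None:
            vals.append(float(support))
    return vals


def mean_support(tree: dendropy.Tree, statistic: str = "mean") -> float:
    """Mean (or median) of the internal-edge support values."""
    vals = _edge_supports(tree)
    if not vals:
        raise ValueError("tree carries no support values")
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown statistic {statistic!r}")


def p_distance_matrix(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances between aligned sequences, ignoring positions
    where either sequence is missing or ambiguous; labels sorted."""
    labels = sorted(rows)
    arrs = {
        lab: np.frombuffer(rows[lab].encode(), dtype=np.uint8) for lab in labels
    }
    valid_base = {
        lab: np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))
        for lab, a in arrs.items()
    }
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            ok = valid_base[a] & valid_base[b]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable positions between {a!r} and {b!r}"
                )
            diff = int((arrs[a][ok] != arrs[b][ok]).sum())
            D[i, j] = D[j, i] = diff / total
    return labels, D


def nj_tree(alignment_or_matrix) -> dendropy.Tree:
    """Neighbor-joining tree from an alignment (p-distances) or a distance
    matrix; deterministic, ties broken by taxon-label order. A testing and
    diagnostics utility, not a substitute for model-based tree inference.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(alignment_or_matrix, tuple):
        labels, D = alignment_or_matrix
        labels = list(labels)
        D = np.asarray(D, dtype=float)
    else:
        rows = getattr(alignment_or_matrix, "rows", alignment_or_matrix)
        labels, D = p_distance_matrix(rows)
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa for neighbor joining")
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    D = D[np.ix_(order, order)]
    dm = DistanceMatrix(D, ids=labels)
    newick = str(nj(dm))
    return parse_newick(newick)
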