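"""Link dendrograms to numeric profile matrices and validate partitions.

Rows of a :class:`ProfileMatrix` are items (typically genes), columns are
conditions; values may be missing.  Once leaves are linked to their rows,
every internal node defines a cluster (its leaf set), for which mean/std
profiles, inter/intra-cluster distances, the Dunn index and the Silhouette
index can be computed.

Distances between profiles use pairwise-complete columns (only columns
where both rows are non-missing); a pair sharing no observed column is an
error.  The silhouette of an item contrasts its mean distance to the other
members of its cluster (a) with its mean distance to all linked leaves
outside the cluster's subtree (b): s = (b - a) / max(a, b).  The outside
set is the tree-partition complement rather than the nearest other flat
cluster, because a dendrogram node has no canonical sibling partition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import TreeError, TreeNode

#: feature key under which a leaf holds its profile row
PROFILE_FEATURE = "profile"

METRICS = ("euclidean", "pearson_dissimilarity", "spearman_dissimilarity")


class ProfileError(Exception):
    """Raised for invalid profile matrices or degenerate distance input."""


class ProfileMatrix:
    """Named rows x named columns of real values with missing support."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = sorted(set(data.index[data.index.duplicated()]))
            raise ProfileError(f"duplicate row names: {dupes}")
        if data.columns.has_duplicates:
            raise ProfileError("duplicate column names")
        values = data.astype(float)
        empty = values.index[values.isna().all(axis=1)]
        if len(empty):
            raise ProfileError(
                f"rows with no observed value: {sorted(map(str, empty))}")
        self.data = values

    @classmethod
    def from_array(cls, values, row_names: Sequence[str],
                   col_names: Sequence[str]) -> "ProfileMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(row_names),
                                columns=list(col_names)))

    @classmethod
    def from_tsv(cls, source) -> "ProfileMatrix":
        """Read a tab-delimited matrix: header ``#NAMES<TAB>cols...``,
        first column row names, empty cell or ``NA`` missing."""
        frame = pd.read_csv(source, sep="\t", index_col=0,
                            na_values=["NA"], keep_default_na=True)
        frame.index.name = None
        return cls(frame)

    def to_tsv(self, path) -> None:
        frame = self.data.copy()
        frame.index.name = "#NAMES"
        frame.to_csv(path, sep="\t", na_rep="NA")

    @property
    def row_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_names(self) -> list[str]:
        return list(self.data.columns)

    def row(self, name: str) -> np.ndarray:
        return self.data.loc[name].to_numpy(dtype=float)

    def __contains__(self, name: str) -> bool:
        return name in self.data.index


# ------------------------------------------------------------------ metrics
def profile_distance(x: np.ndarray, y: np.ndarray, metric: str = "euclidean",
                     names: tuple[str, str] = ("?", "?")) -> float:
    """Distance between two profile rows over pairwise-complete columns."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if not mask.any():
        raise ProfileError(f"rows {names[0]!r} and {names[1]!r} share no "
                           "non-missing column")
    xv, yv = x[mask], y[mask]
    if metric == "euclidean":
        return float(np.sqrt(np.sum((xv - yv) ** 2)))
    if xv.size < 2:
        raise ProfileError(f"correlation between rows {names[0]!r} and "
                           f"{names[1]!r} needs >= 2 shared columns")
    if metric == "pearson_dissimilarity":
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            raise ProfileError(f"zero variance in rows {names!r}: Pearson "
                               "dissimilarity undefined")
        r = float(np.corrcoef(xv, yv)[0, 1])
    else:  # spearman
        r = float(stats.spearmanr(xv, yv).statistic)
        if np.isnan(r):
            raise ProfileError(f"Spearman dissimilarity undefined for rows "
                               f"{names!r}")
    return 1.0 - r


# ------------------------------------------------------------------ linking
def link_profiles(tree: TreeNode, matrix: ProfileMatrix,
                  strict: bool = True) -> list[str]:
    """Attach each leaf's matrix row to its ``profile`` feature.

    Strict mode requires every leaf name to be a row; lenient mode returns
    the list of unmatched leaf names instead of raising.
    """
    unmatched = []
    any_linked = False
    for leaf in tree.iter_leaves():
        if leaf.name in matrix:
            leaf.features[PROFILE_FEATURE] = matrix.row(leaf.name)
            any_linked = True
        else:
            unmatched.append(leaf.name)
    if not any_linked:
        raise ProfileError("no leaf name matches any matrix row")
    if unmatched and strict:
        raise ProfileError("leaves without a matrix row: "
                           + ", ".join(sorted(unmatched)))
    return unmatched


def linked_leaves(node: TreeNode) -> list[TreeNode]:
    return [l for l in node.iter_leaves() if PROFILE_FEATURE in l.features]


def _profiles(node: TreeNode) -> list[tuple[str, np.ndarray]]:
    out = [(l.name, l.features[PROFILE_FEATURE]) for l in linked_leaves(node)]
    if not out:
        raise ProfileError("node has no linked leaves")
    return out


# ------------------------------------------------------------------ profiles
def node_profile(node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean and standard deviation over the node's leaves.

    Missing values are skipped per column; a column unobserved across the
    whole cluster is missing (NaN) in both outputs.
    """
    rows = np.vstack([p for _, p in _profiles(node)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
        std = np.nanstd(rows, axis=0)
    return mean, std


def intracluster_distance(node: TreeNode, metric: str = "euclidean") -> float:
    """Mean pairwise distance among the node's leaf profiles (0 for
    singletons)."""
    profs = _profiles(node)
    if len(profs) == 1:
        return 0.0
    dists = [profile_distance(x, y, metric, (a, b))
             for (a, x), (b, y) in combinations(profs, 2)]
    return float(np.mean(dists))


def intercluster_distance(a: TreeNode, b: TreeNode,
                          metric: str = "euclidean",
                          linkage: str = "mean") -> float:
    """min/max/mean (default mean) cross-pair distance between two
    disjoint clusters."""
    if linkage not in ("min", "max", "mean"):
        raise ValueError(f"unknown linkage {linkage!r}")
    pa, pb = _profiles(a), _profiles(b)
    ids_a = {id(l) for l in linked_leaves(a)}
    if ids_a & {id(l) for l in linked_leaves(b)}:
        raise ProfileError("clusters share leaves; inter-cluster distance "
                           "requires disjoint leaf sets")
    dists = [profile_distance(x, y, metric, (na, nb))
             for na, x in pa for nb, y in pb]
    if linkage == "min":
        return float(min(dists))
    if linkage == "max":
        return float(max(dists))
    return float(np.mean(dists))


# ------------------------------------------------------------------ indexes
@dataclass
class ClusterValidation:
    """Validation summary of one tree partition (cluster = node leaves)."""
    node: TreeNode
    silhouette: float
    intra_distance: float
    inter_distance: float
    std_deviation: float


def silhouette_index(node: TreeNode,
                     metric: str = "euclidean") -> ClusterValidation:
    """Silhouette of the cluster defined by ``node`` against the rest.

    For each member i: a(i) = mean distance to the other members, b(i) =
    mean distance to every linked leaf outside the node's subtree,
    s(i) = (b - a) / max(a, b); a singleton cluster scores 0 by
    convention.  The node silhouette is the mean of s(i); it always lies
    in [-1, 1].
    """
    root = node.get_tree_root()
    members = linked_leaves(node)
    if not members:
        raise ProfileError("node has no linked leaves")
    member_ids = {id(l) for l in members}
    outside = [l for l in linked_leaves(root) if id(l) not in member_ids]
    if not outside:
        raise TreeError("node spans every linked leaf: silhouette needs a "
                        "non-empty outside set (do not pass the root)")

    def d(u, v):
        return profile_distance(u.features[PROFILE_FEATURE],
                                v.features[PROFILE_FEATURE],
                                metric, (u.name, v.name))

    scores = []
    cross = []
    for i in members:
        b = float(np.mean([d(i, o) for o in outside]))
        cross.append(b)
        if len(members) == 1:
            scores.append(0.0)
            continue
        a = float(np.mean([d(i, j) for j in members if j is not i]))
        top = max(a, b)
        scores.append(0.0 if top == 0 else (b - a) / top)
    _, std_vec = node_profile(node)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        std = float(np.nanmean(std_vec))
    return ClusterValidation(
        node=node,
        silhouette=float(np.mean(scores)),
        intra_distance=intracluster_distance(node, metric),
        inter_distance=float(np.mean(cross)),
        std_deviation=std,
    )


def dunn_index(clusters: Sequence[TreeNode],
               metric: str = "euclidean") -> float:
    """Minimum between-cluster (single-linkage) distance over maximum
    cluster diameter.

    Raises when every diameter is zero (the ratio would be unbounded,
    which signals a degenerate partition rather than a perfect one).
    """
    if len(clusters) < 2:
        raise ProfileError("Dunn index needs at least two clusters")
    seen: set[int] = set()
    for c in clusters:
        ids = {id(l) for l in linked_leaves(c)}
        if not ids:
            raise ProfileError("cluster with no linked leaves")
        if ids & seen:
            raise ProfileError("clusters must have disjoint leaf sets")
        seen |= ids
    min_inter = min(
        intercluster_distance(a, b, metric, linkage="min")
        for a, b in combinations(clusters, 2))
    diameters = []
    for c in clusters:
        profs = _profiles(c)
        if len(profs) == 1:
            diameters.append(0.0)
        else:
            diameters.append(max(
                profile_distance(x, y, metric, (na, nb))
                for (na, x), (nb, y) in combinations(profs, 2)))
    max_diam = max(diameters)
    if max_diam == 0:
        raise ProfileError("all cluster diameters are zero; "
                           "Dunn index is unbounded")
    return float(min_inter / max_diam)


def annotate_validation(tree: TreeNode, metric: str = "euclidean"
                        ) -> list[ClusterValidation]:
    """Store silhouette/intra/inter/std as features on every proper
    internal node (used by the cluster rendering layout and the CLI)."""
    results = []
    for node in tree.traverse("preorder"):
        if node.up is None or not node.children:
            continue
        if not linked_leaves(node):
            continue
        cv = silhouette_index(node, metric)
        node.features.update(
            silhouette=cv.silhouette, intra_dist=cv.intra_distance,
            inter_dist=cv.inter_distance, profile_std=cv.std_deviation)
        results.append(cv)
    return results


# ------------------------------------------------------------ synthetic data
def generate_profiles(n_clusters: int, items_per_cluster: int, n_cols: int,
                      separation: float = 5.0, noise_sd: float = 1.0,
                      seed: int = 0) -> tuple[ProfileMatrix, TreeNode]:
    """Synthetic expression-like matrix with a ground-truth dendrogram.

    Cluster k's centre sits at ``k * separation`` along the first
    coordinate axis; items are the centre plus i.i.d. Gaussian noise of
    standard deviation ``noise_sd``.  The returned tree has one subtree
    (named ``cluster_k``) per ground-truth cluster with the items as its
    leaves.  The same seed always yields the same matrix.
    """
    if min(n_clusters, items_per_cluster, n_cols) < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    names = []
    root = TreeNode(name="root")
    for k in range(n_clusters):
        centre = np.zeros(n_cols)
        centre[0] = k * separation
        cluster = root.add_child(name=f"cluster_{k}")
        for j in range(items_per_cluster):
            name = f"g{k}_{j}"
            rows.append(centre + rng.normal(0.0, noise_sd, n_cols)
                        if noise_sd > 0 else centre.copy())
            names.append(name)
            cluster.add_child(name=name)
    matrix = ProfileMatrix.from_array(
        np.vstack(rows), names, [f"c{j}" for j in range(n_cols)])
    return matrix, root
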