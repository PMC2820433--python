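"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (ancestor-set intersections, graph
walks over the undirected tree, textbook index formulas on an explicit
distance matrix) and shares no code path with the package internals it
checks.
"""
from itertools import combinations

import numpy as np


def ancestor_path(node):
    """Node plus its parent chain up to the root."""
    out = [node]
    while out[-1].up is not None:
        out.append(out[-1].up)
    return out


def brute_lca(nodes):
    """Deepest common ancestor by intersecting full ancestor sets."""
    nodes = list(nodes)
    common = set(map(id, ancestor_path(nodes[0])))
    for n in nodes[1:]:
        common &= set(map(id, ancestor_path(n)))
    # deepest member of the intersection
    best, best_depth = None, -1
    for n in ancestor_path(nodes[0]):
        if id(n) in common:
            depth = len(ancestor_path(n)) - 1
            if depth > best_depth:
                best, best_depth = n, depth
    return best


def brute_distance(a, b, topology_only=False):
    """Path length via a weighted walk over the undirected tree."""
    dist = {id(a): 0.0}
    stack = [a]
    while stack:
        n = stack.pop()
        if n is b:
            return dist[id(n)]
        neighbours = list(n.children)
        if n.up is not None:
            neighbours.append(n.up)
        for nb in neighbours:
            if id(nb) in dist:
                continue
            w = 1.0 if topology_only else (nb.dist if nb.up is n else n.dist)
            dist[id(nb)] = dist[id(n)] + w
            stack.append(nb)
    raise AssertionError("nodes not connected")


def leaf_pair_distances(root):
    """{frozenset({name_a, name_b}): distance} over all leaf pairs."""
    leaves = root.get_leaves()
    out = {}
    for a, b in combinations(leaves, 2):
        out[frozenset((a.name, b.name))] = brute_distance(a, b)
    return out


def pairwise_matrix(rows, metric="euclidean"):
    """Dense distance matrix over profile rows (no missing values)."""
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "euclidean":
                d = float(np.sqrt(np.sum((rows[i] - rows[j]) ** 2)))
            elif metric == "pearson_dissimilarity":
                d = 1.0 - float(np.corrcoef(rows[i], rows[j])[0, 1])
            else:
                raise ValueError(metric)
            mat[i, j] = mat[j, i] = d
    return mat


def brute_silhouette(member_idx, outside_idx, dmat):
    """Textbook silhouette with b(i) = mean distance to all outsiders."""
    scores = []
    for i in member_idx:
        b = float(np.mean([dmat[i, o] for o in outside_idx]))
        if len(member_idx) == 1:
            scores.append(0.0)
            continue
        a = float(np.mean([dmat[i, j] for j in member_idx if j != i]))
        top = max(a, b)
        scores.append(0.0 if top == 0 else (b - a) / top)
    return float(np.mean(scores))


def brute_dunn(cluster_indices, dmat):
    """min inter-cluster single-linkage distance / max cluster diameter."""
    min_inter = min(
        dmat[i, j]
        for ca, cb in combinations(cluster_indices, 2)
        for i in ca for j in cb)
    max_diam = max(
        (max((dmat[i, j] for i, j in combinations(c, 2)), default=0.0)
         for c in cluster_indices))
    return min_inter / max_diam


def brute_intra(member_idx, dmat):
    if len(member_idx) == 1:
        return 0.0
    return float(np.mean([dmat[i, j]
                          for i, j in combinations(member_idx, 2)]))


def brute_inter(a_idx, b_idx, dmat, linkage="mean"):
    vals = [dmat[i, j] for i in a_idx for j in b_idx]
    return {"min": min, "max": max, "mean": lambda v: float(np.mean(v))
            }[linkage](vals)
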