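"""Annotated tree data structure and generic manipulation.

A tree is a set of :class:`TreeNode` instances connected through mutually
consistent parent/child references.  Every node doubles as the root of its
own fully featured subtree, so all operations accept internal nodes and act
on the subtree hanging from them (``get_farthest`` and ``get_distance`` see
the whole tree, since the farthest node from *n* may lie outside *n*'s
subtree).

All traversals and bulk operations are iterative (explicit stack or queue),
never bounded by the interpreter recursion limit: trees at the scale of the
NCBI taxonomy (hundreds of thousands of nodes) are a design target.

Branch lengths (``dist``) and support values default to
:data:`DEFAULT_DIST` / :data:`DEFAULT_SUPPORT` when not given; the newick
layer fills the same defaults for absent fields.
"""
from __future__ import annotations

import random
from collections import deque
from typing import Callable, Iterable, Iterator, Sequence

#: branch length assigned when none is given (node creation and parsing)
DEFAULT_DIST = 1.0
#: support value assigned when none is given
DEFAULT_SUPPORT = 1.0

# attribute names that the feature map must never shadow
_STRUCTURAL_FIELDS = frozenset({"name", "dist", "support", "up", "children",
                                "features"})

_MISSING = object()


class TreeError(Exception):
    """Raised for structurally invalid tree operations."""


class TreeNode:
    """One node of an annotated tree.

    Parameters
    ----------
    name:
        Node label; may be empty.
    dist:
        Branch length to the parent (``DEFAULT_DIST`` when omitted).
    support:
        Node support value (``DEFAULT_SUPPORT`` when omitted).
    """

    def __init__(self, name: str = "", dist: float | None = None,
                 support: float | None = None):
        self.name = name
        self.dist = DEFAULT_DIST if dist is None else float(dist)
        self.support = DEFAULT_SUPPORT if support is None else float(support)
        self.up: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.features: dict = {}

    # ------------------------------------------------------------------ basics
    def is_leaf(self) -> bool:
        return not self.children

    def is_root(self) -> bool:
        return self.up is None

    def get_tree_root(self) -> "TreeNode":
        n = self
        while n.up is not None:
            n = n.up
        return n

    def add_feature(self, name: str, value) -> None:
        """Attach an annotation, refusing names of structural fields."""
        if name in _STRUCTURAL_FIELDS:
            raise TreeError(f"feature name {name!r} shadows a structural field")
        self.features[name] = value

    def get_ancestors(self) -> list["TreeNode"]:
        """Parent chain from the immediate parent up to the root."""
        out = []
        n = self.up
        while n is not None:
            out.append(n)
            n = n.up
        return out

    def get_sisters(self) -> list["TreeNode"]:
        if self.up is None:
            return []
        return [c for c in self.up.children if c is not self]

    # -------------------------------------------------------------- traversal
    def traverse(self, strategy: str = "postorder") -> Iterator["TreeNode"]:
        """Iterate over the subtree in pre-, post- or level-order.

        Iterative on an explicit stack/queue; safe for very deep trees.
        """
        if strategy == "preorder":
            return self._iter_preorder()
        if strategy == "postorder":
            return self._iter_postorder()
        if strategy == "levelorder":
            return self._iter_levelorder()
        raise ValueError(f"unknown traversal strategy {strategy!r}")

    def _iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def _iter_postorder(self) -> Iterator["TreeNode"]:
        # reverse of a right-to-left preorder
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def _iter_levelorder(self) -> Iterator["TreeNode"]:
        queue = deque([self])
        while queue:
            node = queue.popleft()
            yield node
            queue.extend(node.children)

    def iter_descendants(self, strategy: str = "preorder") -> Iterator["TreeNode"]:
        for node in self.traverse(strategy):
            if node is not self:
                yield node

    def iter_leaves(self) -> Iterator["TreeNode"]:
        """Leaves of the subtree in left-to-right order."""
        for node in self._iter_preorder():
            if not node.children:
                yield node

    def get_leaves(self) -> list["TreeNode"]:
        return list(self.iter_leaves())

    def get_leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.iter_leaves()]

    # ---------------------------------------------------------------- editing
    def add_child(self, child: "TreeNode | None" = None, name: str = "",
                  dist: float | None = None,
                  support: float | None = None) -> "TreeNode":
        """Append ``child`` (created if omitted) to this node's children.

        Attaching the root of another tree concatenates the two trees.
        """
        if child is None:
            child = self.__class__(name=name, dist=dist, support=support)
        else:
            if child.up is not None:
                raise TreeError("child already has a parent; detach it first")
            if dist is not None:
                child.dist = float(dist)
            if support is not None:
                child.support = float(support)
        # cycle guard: self must not live inside child's subtree
        n = self
        while n is not None:
            if n is child:
                raise TreeError("cannot attach a node to its own descendant")
            n = n.up
        self.children.append(child)
        child.up = self
        return child

    def detach(self) -> "TreeNode":
        """Cut this node off its parent; it becomes a standalone root."""
        if self.up is None:
            raise TreeError("cannot detach the root")
        self.up.children.remove(self)
        self.up = None
        return self

    def delete(self, preserve_dist: bool = False) -> None:
        """Remove this node, re-attaching its children to its parent.

        With ``preserve_dist`` each re-attached child's branch length grows
        by the deleted node's, so root-to-leaf path lengths are unchanged.
        """
        if self.up is None:
            raise TreeError("cannot delete the root")
        parent = self.up
        idx = parent.children.index(self)
        for child in self.children:
            child.up = parent
            if preserve_dist:
                child.dist += self.dist
        parent.children[idx:idx + 1] = self.children
        self.up = None
        self.children = []

    def prune(self, keep: Iterable[str], preserve_dist: bool = True) -> "TreeNode":
        """Reduce the subtree to exactly the leaves named in ``keep``.

        Unary internal nodes created by the removal are collapsed; with
        ``preserve_dist`` their branch lengths are merged so that pairwise
        path distances among kept leaves are unchanged.
        """
        keep = set(keep)
        if not keep:
            raise TreeError("cannot prune to an empty leaf set")
        leaf_map: dict[str, TreeNode] = {}
        for leaf in self.iter_leaves():
            leaf_map.setdefault(leaf.name, leaf)
        missing = sorted(keep - leaf_map.keys())
        if missing:
            raise TreeError(f"unknown leaf names: {', '.join(missing)}")

        retained = {self}
        for name in keep:
            n = leaf_map[name]
            while n is not None and n not in retained:
                retained.add(n)
                n = n.up
        for node in [n for n in self.iter_descendants()
                     if n not in retained and n.up in retained]:
            node.detach()
        for node in list(self.traverse("postorder")):
            if node is not self and len(node.children) == 1:
                node.delete(preserve_dist=preserve_dist)
        # a unary chain at the root sits above the kept-leaf LCA: collapse
        # it without merging lengths (no kept pairwise path crosses it)
        while len(self.children) == 1 and self.children[0].children:
            self.children[0].delete(preserve_dist=False)
        return self

    def copy(self, return_map: bool = False):
        """Deep-copy the subtree (annotation maps are copied per node)."""
        mapping: dict[TreeNode, TreeNode] = {}
        for node in self._iter_preorder():
            new = self.__class__()
            for key, value in node.__dict__.items():
                if key not in ("up", "children", "features"):
                    setattr(new, key, value)
            new.features = dict(node.features)
            new.up = None
            new.children = []
            mapping[node] = new
            if node.up in mapping:
                parent = mapping[node.up]
                parent.children.append(new)
                new.up = parent
        root = mapping[self]
        return (root, mapping) if return_map else root

    # ----------------------------------------------------------------- search
    def search_nodes(self, **conditions) -> list["TreeNode"]:
        """Nodes of the subtree matching every attribute/feature condition.

        Structural attributes (``name``, ``dist``, ...) take precedence over
        feature-map entries of the same key.
        """
        hits = []
        for node in self._iter_preorder():
            for key, wanted in conditions.items():
                value = getattr(node, key, _MISSING)
                if value is _MISSING:
                    value = node.features.get(key, _MISSING)
                if value is _MISSING or value != wanted:
                    break
            else:
                hits.append(node)
        return hits

    def get_common_ancestor(self, nodes) -> "TreeNode":
        """Deepest node whose subtree contains every input node.

        ``nodes`` may be TreeNode instances or leaf/node names resolved in
        this node's tree.  With a single input the input itself is returned.
        """
        root = self.get_tree_root()
        resolved = []
        if isinstance(nodes, (TreeNode, str)):
            nodes = [nodes]
        for item in nodes:
            resolved.append(self._resolve_node(item, root))
        if not resolved:
            raise TreeError("need at least one node")
        first = resolved[0]
        path = [first] + first.get_ancestors()
        index = {id(n): i for i, n in enumerate(path)}
        best = 0
        for other in resolved[1:]:
            n = other
            while n is not None and id(n) not in index:
                n = n.up
            if n is None:
                raise TreeError("nodes do not belong to the same tree")
            best = max(best, index[id(n)])
        return path[best]

    @staticmethod
    def _resolve_node(item, root: "TreeNode") -> "TreeNode":
        if isinstance(item, TreeNode):
            if item.get_tree_root() is not root:
                raise TreeError("node belongs to a different tree")
            return item
        hits = root.search_nodes(name=item)
        if not hits:
            raise TreeError(f"no node named {item!r}")
        return hits[0]

    def __contains__(self, item) -> bool:
        if isinstance(item, TreeNode):
            return any(n is item for n in self._iter_preorder())
        return bool(self.search_nodes(name=item))

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    def __iter__(self) -> Iterator["TreeNode"]:
        return self.iter_leaves()

    def __repr__(self) -> str:
        return f"TreeNode({self.name!r})" if type(self) is TreeNode else \
            f"{type(self).__name__}({self.name!r})"

    def __str__(self) -> str:
        return self.ascii()

    # -------------------------------------------------------------- distances
    def get_distance(self, target, topology_only: bool = False) -> float:
        """Sum of branch lengths along the path to ``target``.

        With ``topology_only`` every edge counts 1 regardless of length.
        """
        root = self.get_tree_root()
        other = self._resolve_node(target, root)
        lca = self.get_common_ancestor([self, other])
        total = 0.0
        for endpoint in (self, other):
            n = endpoint
            while n is not lca:
                total += 1.0 if topology_only else n.dist
                n = n.up
        return total

    def _undirected_distances(self, topology_only: bool = False) -> dict:
        """Distance from this node to every node of the whole tree."""
        dist = {id(self): 0.0}
        nodes = {id(self): self}
        stack = [self]
        while stack:
            n = stack.pop()
            base = dist[id(n)]
            neighbours = list(n.children)
            if n.up is not None:
                neighbours.append(n.up)
            for nb in neighbours:
                if id(nb) in dist:
                    continue
                edge = nb.dist if nb.up is n else n.dist
                dist[id(nb)] = base + (1.0 if topology_only else edge)
                nodes[id(nb)] = nb
                stack.append(nb)
        return {nodes[k]: v for k, v in dist.items()}

    def get_farthest(self, leaves_only: bool = False,
                     topology_only: bool = False,
                     descendants_only: bool = False) -> tuple["TreeNode", float]:
        """Node (or leaf) of the whole tree farthest from this node.

        ``descendants_only`` restricts the search to this node's subtree
        (the "farthest descendant" variant).  Ties resolve to the first
        candidate in preorder of the search domain.
        """
        dmap = self._undirected_distances(topology_only=topology_only)
        domain = self if descendants_only else self.get_tree_root()
        best_node, best_dist = None, -1.0
        for n in domain._iter_preorder():
            if leaves_only and n.children:
                continue
            d = dmap[n]
            if d > best_dist:
                best_node, best_dist = n, d
        return best_node, best_dist

    def get_farthest_leaf(self, topology_only: bool = False,
                          descendants_only: bool = False):
        return self.get_farthest(leaves_only=True, topology_only=topology_only,
                                 descendants_only=descendants_only)

    # ---------------------------------------------------------------- rooting
    def get_midpoint_outgroup(self) -> "TreeNode":
        """Node whose parent edge contains the midpoint of the tree diameter.

        The diameter is the longest leaf-to-leaf path; ties between diameter
        pairs resolve to the lexicographically first leaf-name pair.  When
        the midpoint falls exactly on an internal node, that node is
        returned (or, if it is the root, the path node on the side of the
        first endpoint).
        """
        root = self.get_tree_root()
        leaves = root.get_leaves()
        if len(leaves) < 2:
            raise TreeError("midpoint rooting needs at least two leaves")
        best_d = -1.0
        best_pair: tuple | None = None
        best_nodes: tuple | None = None
        for leaf in leaves:
            dmap = leaf._undirected_distances()
            for other in leaves:
                if other is leaf:
                    continue
                d = dmap[other]
                pair = tuple(sorted((leaf.name, other.name)))
                if d > best_d or (d == best_d and pair < best_pair):
                    best_d, best_pair = d, pair
                    a, b = ((leaf, other) if leaf.name <= other.name
                            else (other, leaf))
                    best_nodes = (a, b)
        if best_d <= 0:
            raise TreeError("all branch lengths are zero; "
                            "consider topology-only rooting")
        a, b = best_nodes
        lca = root.get_common_ancestor([a, b])
        up_a = []
        n = a
        while n is not lca:
            up_a.append(n)
            n = n.up
        up_b = []
        n = b
        while n is not lca:
            up_b.append(n)
            n = n.up
        path = up_a + [lca] + list(reversed(up_b))
        target = best_d / 2.0
        tol = 1e-12 * max(1.0, best_d)
        cum = 0.0
        for u, v in zip(path, path[1:]):
            child_side = u if u.up is v else v
            w = child_side.dist
            nxt = cum + w
            if abs(nxt - target) <= tol:
                # exactly on node v
                return v if v.up is not None else u
            if nxt > target:
                return child_side
            cum = nxt
        return path[-1]

    def set_outgroup(self, outgroup, split: float | None = None) -> "TreeNode":
        """Re-root the tree on the edge above ``outgroup``.

        Returns a new root with exactly two children: the outgroup subtree
        and everything else.  All pairwise leaf distances are preserved for
        any position of the new root on the bisected edge; by default the
        split point is chosen to balance the maximal leaf depths of the two
        sides (clamped to the edge), which makes rooting at the midpoint
        outgroup equalize the diameter-endpoint depths.  ``split`` overrides
        the position as a distance from ``outgroup`` along its parent edge.
        """
        root = self.get_tree_root()
        outgroup = self._resolve_node(outgroup, root)
        if outgroup.up is None:
            raise TreeError("the outgroup cannot be the current root")

        L = outgroup.dist
        if split is None:
            dmap = outgroup._undirected_distances()
            sub = set(map(id, outgroup.iter_leaves()))
            h_out = max(dmap[l] for l in root.iter_leaves() if id(l) in sub)
            outside = [dmap[l] for l in root.iter_leaves() if id(l) not in sub]
            if not outside:
                raise TreeError("outgroup subtree spans the whole tree")
            h_rest = max(outside) - L
            x = (h_rest + L - h_out) / 2.0
            x = min(max(x, 0.0), L)
        else:
            x = min(max(float(split), 0.0), L)

        chain = [outgroup] + outgroup.get_ancestors()
        dists = [n.dist for n in chain]
        sups = [n.support for n in chain]
        parent1 = chain[1]
        parent1.children.remove(outgroup)
        outgroup.up = None
        # reverse parent links along the chain above the outgroup
        for i in range(1, len(chain) - 1):
            c, p = chain[i], chain[i + 1]
            p.children.remove(c)
            c.children.append(p)
            p.up = c
            p.dist = dists[i]
            p.support = sups[i]
        old_root = chain[-1]
        if old_root is not parent1 and len(old_root.children) == 1:
            only = old_root.children[0]
            holder = old_root.up
            j = holder.children.index(old_root)
            only.dist += old_root.dist
            only.up = holder
            holder.children[j] = only
            old_root.up = None
            old_root.children = []

        new_root = self.__class__()
        new_root.dist = 0.0
        new_root.children = [outgroup, parent1]
        outgroup.up = new_root
        parent1.up = new_root
        outgroup.dist = x
        parent1.dist = L - x
        if len(parent1.children) == 1:
            lone = parent1.children[0]
            lone.dist += parent1.dist
            lone.up = new_root
            new_root.children[1] = lone
            parent1.up = None
            parent1.children = []
        return new_root

    # ------------------------------------------------------------ text output
    def ascii(self, show_internal: bool = False) -> str:
        """Multi-line text dendrogram; one line per leaf name."""
        blocks: dict[int, tuple[list[str], int]] = {}
        for node in self.traverse("postorder"):
            if not node.children:
                blocks[id(node)] = ([f"-{node.name}"], 0)
                continue
            lines: list[str] = []
            anchors: list[int] = []
            for child in node.children:
                clines, canchor = blocks.pop(id(child))
                anchors.append(len(lines) + canchor)
                lines.extend(clines)
            top, bot = anchors[0], anchors[-1]
            mid = (top + bot) // 2
            aset = set(anchors)
            out = []
            for r, line in enumerate(lines):
                lead = "-" if r == mid else " "
                if r == top:
                    corner = "/"
                elif r == bot:
                    corner = "\\"
                elif top < r < bot:
                    corner = "|"
                else:
                    corner = " "
                tick = "-" if r in aset else " "
                out.append(lead + corner + tick + line)
            if show_internal and node.name:
                out[mid] += f" [{node.name}]"
            blocks[id(node)] = (out, mid)
        lines, _ = blocks[id(self)]
        return "\n".join(lines)

    # ------------------------------------------------------------- serializing
    def write(self, dialect=None, include_features: Iterable[str] = ()) -> str:
        from .newick import write_newick
        return write_newick(self, dialect=dialect,
                            include_features=include_features)


def populate_random(n: int, names: Sequence[str] | None = None, seed: int = 0,
                    node_class: Callable[..., TreeNode] = TreeNode) -> TreeNode:
    """Random binary tree with ``n`` leaves by Yule-like leaf splitting.

    At every step a uniformly random current leaf is split into two
    daughters, so the result has exactly ``2n - 1`` nodes.  Branch lengths
    and supports take the default constants.  Leaf names come from
    ``names`` (must supply at least ``n``) or are auto-generated
    ``t1..tn``; the same seed always yields the same tree.
    """
    if n < 1:
        raise TreeError("need at least one leaf")
    if names is not None and len(names) < n:
        raise TreeError(f"need at least {n} names, got {len(names)}")
    rng = random.Random(seed)
    root = node_class()
    leaves = [root]
    for _ in range(n - 1):
        i = rng.randrange(len(leaves))
        node = leaves[i]
        c1, c2 = node_class(), node_class()
        node.children = [c1, c2]
        c1.up = node
        c2.up = node
        leaves[i] = c1
        leaves.append(c2)
    for idx, leaf in enumerate(root.iter_leaves()):
        leaf.name = names[idx] if names is not None else f"t{idx + 1}"
    return root
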