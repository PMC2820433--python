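"""Phylogenetic semantics on top of the generic tree.

Leaves are OTUs carrying a species code and, optionally, an aligned
sequence; internal nodes are their ancestors.  Two methods label internal
nodes as duplication or speciation events:

* the species-overlap algorithm, which needs no species tree: a node is a
  duplication when its child subtrees share species (overlap score above a
  threshold, default 0);
* strict gene-tree/species-tree reconciliation via the LCA mapping, which
  additionally infers gene losses and inserts them as ghost leaves.

Duplication nodes can be dated by rank against a nested species ladder
(topology scanning): the rank is the index of the smallest ladder level
containing every species under the node, giving a relative (not absolute)
age ordering.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Iterable, Sequence

from .tree import TreeError, TreeNode, populate_random

DUPLICATION = "duplication"
SPECIATION = "speciation"
#: feature marking an inserted loss leaf in a reconciled tree
LOSS_FEATURE = "evoltype"
LOSS_VALUE = "L"


class PhyloNode(TreeNode):
    """Tree node with species, sequence and inferred-event slots."""

    def __init__(self, name: str = "", dist: float | None = None,
                 support: float | None = None, species: str = "",
                 sequence: str | None = None):
        super().__init__(name, dist, support)
        self.species = species
        self.sequence = sequence
        self.event: str | None = None

    def __repr__(self):
        return f"PhyloNode({self.name!r})"


def default_species_rule(name: str) -> str:
    """Default naming rule: species code = first three characters."""
    return name[:3]


def assign_species(tree: TreeNode,
                   rule: Callable[[str], str] | None = None) -> None:
    """Set each leaf's species from its name via ``rule``.

    The default rule takes the first three characters of the leaf name; any
    name→code callable may be supplied instead.
    """
    rule = rule or default_species_rule
    for leaf in tree.iter_leaves():
        if not leaf.name:
            raise TreeError("cannot assign a species to an unnamed leaf")
        code = rule(leaf.name)
        if not code:
            raise TreeError(f"species rule returned an empty code "
                            f"for leaf {leaf.name!r}")
        leaf.species = code


def get_species(node: TreeNode) -> set[str]:
    """Union of species codes over the leaves of the subtree."""
    out = set()
    for leaf in node.iter_leaves():
        sp = getattr(leaf, "species", "")
        if not sp:
            raise TreeError(f"leaf {leaf.name!r} has no species assigned")
        out.add(sp)
    return out


@dataclass
class EvolEvent:
    """One inferred evolutionary event at an internal node.

    ``in_group``/``out_group`` are the leaf-name sets separated by the node
    (first child vs the rest); ``overlap_score`` is set by the
    species-overlap method only.
    """
    node: TreeNode
    etype: str
    overlap_score: float | None = None
    in_group: frozenset = frozenset()
    out_group: frozenset = frozenset()


def species_overlap_events(tree: TreeNode,
                           threshold: float = 0.0) -> list[EvolEvent]:
    """Label internal nodes by the species-overlap algorithm.

    For each node with >= 2 children the overlap score is
    ``|intersection| / |union|`` of the children's species sets (global
    intersection over global union for multifurcations); the node is a
    duplication when the score is strictly greater than ``threshold``
    (default 0: any shared species), else a speciation.  Events are
    returned in postorder and ``node.event`` is set.  No species tree is
    consulted.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    spsets: dict[int, set[str]] = {}
    events: list[EvolEvent] = []
    for node in tree.traverse("postorder"):
        if not node.children:
            sp = getattr(node, "species", "")
            if not sp:
                raise TreeError(f"leaf {node.name!r} has no species assigned")
            spsets[id(node)] = {sp}
            continue
        child_sets = [spsets.pop(id(c)) for c in node.children]
        union = set().union(*child_sets)
        spsets[id(node)] = union
        if len(node.children) < 2:
            continue
        inter = set(child_sets[0]).intersection(*child_sets[1:])
        score = len(inter) / len(union)
        etype = DUPLICATION if score > threshold else SPECIATION
        node.event = etype
        in_group = frozenset(l.name for l in node.children[0].iter_leaves())
        out_group = frozenset(l.name for c in node.children[1:]
                              for l in c.iter_leaves())
        events.append(EvolEvent(node, etype, score, in_group, out_group))
    return events


@dataclass
class ReconciliationResult:
    """Outcome of strict reconciliation.

    ``reconciled_tree`` is a copy of the gene tree with loss leaves
    inserted (feature ``evoltype == "L"``); ``mapping`` is the LCA map from
    original gene-tree nodes to species-tree nodes.
    """
    reconciled_tree: TreeNode
    events: list[EvolEvent]
    n_duplications: int
    n_losses: int
    mapping: dict


def _check_binary(tree: TreeNode, label: str) -> None:
    for node in tree.traverse("preorder"):
        if node.children and len(node.children) != 2:
            raise TreeError(
                f"{label} contains a polytomy at {node.name!r}: strict "
                "reconciliation is defined on binary trees; resolve the "
                "polytomy first")


def _sp_label(node: TreeNode) -> str:
    if node.name:
        return node.name
    return "+".join(sorted(node.get_leaf_names()))


def reconcile(gene_tree: TreeNode, species_tree: TreeNode) -> ReconciliationResult:
    """Strict gene-tree/species-tree reconciliation (LCA mapping).

    Postorder: every gene leaf maps to the species-tree leaf of its
    species; every internal node maps to the species-tree LCA of its
    children's images.  A node is a duplication iff it maps to the image of
    at least one child.  For each child edge, every species-tree branch
    skipped between the node's image (exclusive for speciations, inclusive
    for duplications) and the child's image contributes one loss leaf,
    inserted in the returned copy of the gene tree.
    """
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")

    sp_leaf: dict[str, TreeNode] = {}
    for leaf in species_tree.iter_leaves():
        if leaf.name in sp_leaf:
            raise TreeError(f"duplicated species code {leaf.name!r} "
                            "in the species tree")
        sp_leaf[leaf.name] = leaf
    depth: dict[int, int] = {}
    for node in species_tree.traverse("preorder"):
        depth[id(node)] = 0 if node.up is None else depth[id(node.up)] + 1

    def sp_lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while depth[id(a)] > depth[id(b)]:
            a = a.up
        while depth[id(b)] > depth[id(a)]:
            b = b.up
        while a is not b:
            a, b = a.up, b.up
        return a

    mapping: dict[TreeNode, TreeNode] = {}
    events: list[EvolEvent] = []
    for node in gene_tree.traverse("postorder"):
        if not node.children:
            sp = getattr(node, "species", "")
            if not sp:
                raise TreeError(f"leaf {node.name!r} has no species assigned")
            if sp not in sp_leaf:
                raise TreeError(f"species {sp!r} (leaf {node.name!r}) is "
                                "missing from the species tree")
            mapping[node] = sp_leaf[sp]
            continue
        c1, c2 = node.children
        m = sp_lca(mapping[c1], mapping[c2])
        mapping[node] = m
        etype = DUPLICATION if (m is mapping[c1] or m is mapping[c2]) \
            else SPECIATION
        node.event = etype
        events.append(EvolEvent(
            node, etype, None,
            frozenset(l.name for l in c1.iter_leaves()),
            frozenset(l.name for l in c2.iter_leaves())))

    copy_root, node_map = gene_tree.copy(return_map=True)
    n_losses = 0
    for node in gene_tree.traverse("preorder"):
        if not node.children:
            continue
        is_dup = node.event == DUPLICATION
        for child in node.children:
            # species-tree path from mapping[node] down to mapping[child]
            path = []
            s = mapping[child]
            while s is not mapping[node]:
                path.append(s)
                s = s.up
                if s is None:  # pragma: no cover - mapping guarantees an LCA
                    raise TreeError("inconsistent LCA mapping")
            path.append(mapping[node])
            path.reverse()
            start = 0 if is_dup else 1
            lost: list[TreeNode] = []
            for k in range(start, len(path) - 1):
                nxt = path[k + 1]
                lost.extend(c for c in path[k].children if c is not nxt)
            if not lost:
                continue
            cchild = node_map[child]
            cparent = cchild.up
            idx = cparent.children.index(cchild)
            cparent.children.remove(cchild)
            holder = cparent
            for lineage in lost:
                joint = copy_root.__class__()
                joint.dist = 0.0
                if holder is cparent:
                    holder.children.insert(idx, joint)
                else:
                    holder.children.append(joint)
                joint.up = holder
                ghost = copy_root.__class__(name=_sp_label(lineage))
                ghost.dist = 0.0
                ghost.features[LOSS_FEATURE] = LOSS_VALUE
                joint.children.append(ghost)
                ghost.up = joint
                holder = joint
            holder.children.append(cchild)
            cchild.up = holder
            n_losses += len(lost)

    # mirror events on the reconciled copy for rendering
    for node in gene_tree.traverse("preorder"):
        if node.children:
            node_map[node].event = node.event
    n_dup = sum(1 for ev in events if ev.etype == DUPLICATION)
    return ReconciliationResult(copy_root, events, n_dup, n_losses, mapping)


# ------------------------------------------------------------------- dating
def build_species_ladder(species_tree: TreeNode,
                         seed_species: str) -> list[frozenset]:
    """Nested species sets along the seed species' path to the root.

    Level 0 is the seed species alone; each following level is the leaf set
    of the next ancestor (duplicate consecutive levels collapsed).
    """
    hits = [l for l in species_tree.iter_leaves() if l.name == seed_species]
    if not hits:
        raise TreeError(f"seed species {seed_species!r} not in species tree")
    ladder: list[frozenset] = []
    n = hits[0]
    while n is not None:
        level = frozenset(n.get_leaf_names())
        if not ladder or level != ladder[-1]:
            ladder.append(level)
        n = n.up
    return ladder


def date_duplication(node: TreeNode,
                     reference_ladder: Sequence[Iterable[str]]) -> int:
    """Relative age rank of a duplication against a nested species ladder.

    Returns the smallest ladder index whose species set contains every
    species under the node; larger ranks are older duplications.
    """
    if getattr(node, "event", None) != DUPLICATION:
        raise TreeError("node is not labelled as a duplication event")
    levels = [frozenset(level) for level in reference_ladder]
    for prev, cur in zip(levels, levels[1:]):
        if not prev < cur:
            raise ValueError("reference ladder levels must be strictly nested")
    species = get_species(node)
    for rank, level in enumerate(levels):
        if species <= level:
            return rank
    raise TreeError(f"species {sorted(species)} not covered by the last "
                    "ladder level")


# --------------------------------------------------------------- monophyly
def check_monophyly(tree: TreeNode, target_values: Iterable,
                    attribute: str = "species"):
    """Classify the grouping of leaves whose ``attribute`` is in targets.

    Returns ``(verdict, intruders)`` where verdict is ``"monophyletic"``
    (no foreign leaves under the common ancestor), ``"paraphyletic"`` (the
    foreign leaves form a single clade) or ``"polyphyletic"``; intruders is
    the set of foreign leaf nodes.
    """
    targets = set(target_values)

    def value_of(leaf):
        v = getattr(leaf, attribute, _SENTINEL)
        if v is _SENTINEL or v is None or v == "":
            v = leaf.features.get(attribute, _SENTINEL)
        if v is _SENTINEL:
            raise TreeError(f"leaf {leaf.name!r} lacks attribute {attribute!r}")
        return v

    matched = [l for l in tree.iter_leaves() if value_of(l) in targets]
    if not matched:
        raise TreeError("no leaf matches the target values")
    ancestor = tree.get_common_ancestor(matched)
    under = ancestor.get_leaves()
    intruders = {l for l in under if value_of(l) not in targets}
    if not intruders:
        return "monophyletic", set()
    block = tree.get_common_ancestor(list(intruders))
    if set(block.get_leaves()) == intruders:
        return "paraphyletic", intruders
    return "polyphyletic", intruders


_SENTINEL = object()


# ---------------------------------------------------------------- alignments
def link_alignment(tree: TreeNode, alignment: str, strict: bool = True):
    """Attach aligned FASTA sequences to the leaves by exact id match.

    ``alignment`` is FASTA text (or a path to a FASTA file).  All sequences
    must have equal aligned length and unique ids.  Leaves without a
    matching record raise in strict mode; in lenient mode the list of
    unmatched leaf names is returned.
    """
    from Bio import SeqIO

    if "\n" not in alignment and ">" not in alignment:
        with open(alignment) as fh:
            alignment = fh.read()
    records = {}
    for rec in SeqIO.parse(StringIO(alignment), "fasta"):
        if rec.id in records:
            raise TreeError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise TreeError("aligned sequences have unequal lengths: "
                        f"{sorted(lengths)}")
    unmatched = []
    for leaf in tree.iter_leaves():
        if leaf.name in records:
            leaf.sequence = records[leaf.name]
        else:
            unmatched.append(leaf.name)
    if unmatched and strict:
        raise TreeError("no aligned sequence for leaves: "
                        + ", ".join(sorted(unmatched)))
    return unmatched


# ----------------------------------------------------------- ortholog pairs
def ortholog_pairs(events: Sequence[EvolEvent]) -> dict[tuple[str, str], str]:
    """Label every leaf pair separated by an event node.

    Pairs whose last common ancestor is a speciation are orthologs; pairs
    under a duplication are paralogs.  Because each unordered leaf pair has
    exactly one LCA, the labels partition all pairs when every internal
    node carries an event.
    """
    labels: dict[tuple[str, str], str] = {}
    for ev in events:
        lab = "ortholog" if ev.etype == SPECIATION else "paralog"
        groups = [[l.name for l in c.iter_leaves()] for c in ev.node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        labels[tuple(sorted((a, b)))] = lab
    return labels


# ------------------------------------------------------------- simulation
def simulate_gene_tree(species_tree: TreeNode, n_duplications: int = 0,
                       seed: int = 0) -> PhyloNode:
    """Loss-free simulated gene tree over a species tree.

    Starts from a copy of the species tree (one gene per species, leaf
    names ``<code>_1``); each duplication step grafts a copy of a random
    non-root node's subtree as its sibling under a fresh parent, which is
    marked with the ground-truth feature ``sim_duplication``.  Copied
    leaves get fresh per-species counters, so leaf names stay unique.  No
    losses are introduced, so the ground-truth duplication nodes are
    recoverable by both the species-overlap and reconciliation methods.
    """
    if n_duplications < 0:
        raise ValueError("n_duplications must be >= 0")
    rng = random.Random(seed)
    counters: dict[str, int] = {}

    def fresh(species: str) -> str:
        counters[species] = counters.get(species, 0) + 1
        return f"{species}_{counters[species]}"

    mapping: dict[int, PhyloNode] = {}
    gene: PhyloNode | None = None
    for node in species_tree.traverse("preorder"):
        g = PhyloNode(dist=node.dist)
        if not node.children:
            g.species = node.name
            g.name = fresh(node.name)
        mapping[id(node)] = g
        if node.up is None:
            gene = g
        else:
            parent = mapping[id(node.up)]
            parent.children.append(g)
            g.up = parent

    for _ in range(n_duplications):
        candidates = [n for n in gene.traverse("preorder") if n.up is not None]
        target = rng.choice(candidates)
        twin = target.copy()
        for leaf in twin.iter_leaves():
            leaf.name = fresh(leaf.species)
        parent = target.up
        idx = parent.children.index(target)
        joint = PhyloNode(dist=target.dist)
        parent.children[idx] = joint
        joint.up = parent
        target.up = joint
        target.dist = 1.0
        twin.up = joint
        twin.dist = 1.0
        joint.children = [target, twin]
        joint.features["sim_duplication"] = True
    return gene


def random_species_tree(codes: Sequence[str], seed: int = 0) -> PhyloNode:
    """Random binary species tree over unique species codes."""
    if len(set(codes)) != len(codes):
        raise TreeError("species codes must be unique")
    return populate_random(len(codes), names=list(codes), seed=seed,
                           node_class=PhyloNode)


def species_guided_outgroup(tree: TreeNode,
                            ingroup_species: Iterable[str]) -> TreeNode:
    """Experimental species-guided outgroup choice.

    Returns the non-root node whose species set is taxonomically farthest
    (Jaccard distance) from the designated ingroup species set; ties go to
    the first candidate in preorder.
    """
    ingroup = set(ingroup_species)
    if not ingroup:
        raise TreeError("ingroup species set is empty")
    best, best_score = None, -1.0
    for node in tree.iter_descendants("preorder"):
        sp = get_species(node)
        score = 1.0 - len(sp & ingroup) / len(sp | ingroup)
        if score > best_score:
            best, best_score = node, score
    return best
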