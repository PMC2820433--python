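# Methods notes

This note records the models, conventions and numerical choices behind
treescope, including the places where the design space was genuinely
open and what was decided.

## Tree model and defaults

A tree is a set of nodes with mutually consistent parent/child links;
exactly one node has no parent. Each node carries a name, a branch
length `dist` (to its parent, in the input's units), a `support` value
and an open-ended feature dictionary that must not shadow the
structural fields. Absent branch lengths and supports default to 1.0,
both at node creation and when parsing newick without those fields;
tests reference these as `DEFAULT_DIST` / `DEFAULT_SUPPORT` rather than
literals.

All traversals, the parser, the writer, copying and the distance
machinery are iterative. This is a hard requirement, not a style
choice: the intended workloads include taxonomy-scale trees (hundreds
of thousands of nodes, possibly fully unbalanced), where any recursive
formulation hits the interpreter stack limit.

## Newick dialects

Five dialects are registered (FULL, LEAF_NAMES_LENGTHS,
INTERNAL_SUPPORT, TOPOLOGY_ONLY, FLEXIBLE). The registry ids are this
package's own numbering and make no claim of matching any other tool's
format numbers. Conventions worth knowing:

- The internal-name slot is ambiguous between names and supports. The
  rule: under a dialect that declares support writing, a *bare number*
  in that slot is a support; anything else is a name. A numeric internal
  node name therefore cannot round-trip under such dialects — rename
  the node or use a dialect without supports.
- FULL writes both internal names and supports; since both cannot share
  the name slot, supports are serialized as an NHX `support=` entry and
  folded back into the structural field on parsing (they never appear in
  the feature map, preserving the no-shadowing invariant).
- Duplicate NHX keys: the last occurrence wins and a warning is logged.
- Names containing `(),:;[]` raise on writing. Auto-quoting was
  deliberately rejected: silently quoted names break downstream
  consumers that do exact string matching. Quoted labels are accepted on
  input.
- Strict dialects reject malformed numeric fields with the character
  offset; non-strict dialects substitute the defaults.
- The root's own `dist` is serialized like any other node's (it is
  meaningless for path lengths but keeps round trips field-exact).

## Rooting conventions

`set_outgroup` reverses the parent chain above the outgroup and places
a fresh binary root on the outgroup's parent edge. *Any* split of that
edge preserves all pairwise leaf distances (every path through the edge
keeps its total), so the split position is a free parameter. The
default places the root at the point that equalizes the maximal leaf
depth of the two sides, clamped to the edge. This choice makes
`set_outgroup(get_midpoint_outgroup(t))` an exact midpoint rooting:
when the diameter midpoint is interior to the chosen edge, the two
deepest leaves end up equidistant from the root (checked to 1e-6). An
explicit `split` distance overrides the default. A trifurcating
(unrooted-style) root is handled by grouping the non-outgroup children;
a unary old root left behind by the reversal is collapsed with its
branch length merged.

`get_midpoint_outgroup` computes the diameter by exhaustive leaf-pair
scanning (quadratic; fine for the intended tree sizes) with ties broken
by the lexicographically first leaf-name pair for reproducibility. A
midpoint falling exactly on an internal node returns that node; on the
root, the path node toward the first endpoint.

`prune` keeps exactly the requested leaves, collapsing unary nodes with
branch-length merging so kept pairwise distances are preserved. A unary
chain left at the root lies *above* the kept-leaf common ancestor; it
is collapsed without merging, since no kept path crosses it.

`get_farthest` searches the whole tree by default (walking through the
parent as well as the children); `descendants_only=True` restricts it
to the subtree — both variants are needed because the farthest node
from an internal node frequently lies outside its own subtree. Whether
to use branch lengths or edge counts is left to the caller via
`topology_only`; branch lengths are the default.

Random trees use seeded Yule-like growth (split a uniformly chosen
current leaf), which is simple, reproducible and produces enough
topological variety for property testing; no claim is made about
matching a particular speciation prior.

## Orthology inference

Species-overlap: score = |global intersection| / |global union| of the
children's species sets. The global (rather than pairwise) rule for
multifurcations reduces to the standard two-child case and stays in
[0, 1]. Duplication requires score **strictly greater** than the
threshold; the default threshold 0 reproduces "any shared species means
duplication". The method never consults a species tree.

Reconciliation is the strict LCA-mapping algorithm and requires binary
trees; polytomies raise with a message suggesting prior resolution.
Loss counting per child edge: walk the species-tree path from `M(v)`
down to `M(child)`; each off-path child of a traversed node is one lost
lineage, starting at `M(v)` itself when `v` is a duplication and just
below it otherwise. Equivalently, losses per edge =
`depth(M(child)) - depth(M(v)) - 1 + [v is a duplication]`, clamped at
zero. The normative fixture is the 3-leaf hidden-paralogy case
`(HSA_a,(HSA_b,MMU_b))` against `(HSA,MMU)`: one duplication at the
root and one mouse loss beside `HSA_a`. Loss leaves are inserted into a
*copy* of the gene tree (the input is only annotated with events), get
branch length 0, are named after the lost species-tree node (joined
leaf names for an unnamed internal lineage) and carry the feature
`evoltype = "L"`; removing them and collapsing unary nodes recovers the
input topology.

Duplication dating uses an explicit nested species ladder (level 0 ⊂
level 1 ⊂ ...) as the contract; `build_species_ladder` derives one from
a seed species' path to the species-tree root. The rank of a
duplication is the smallest level containing all species under it —
a relative ordering only, monotone from leaves to root along any
duplication path.

The species-guided outgroup chooser (maximize Jaccard distance between
a node's species set and a designated ingroup set, first-in-preorder on
ties) is a pragmatic heuristic and is flagged experimental in its
docstring.

## Synthetic gene trees

`simulate_gene_tree` copies the species tree (one gene per species) and
repeatedly grafts a copy of a random non-root subtree as its sibling,
marking the created parent with `sim_duplication`. Because entire
subtrees are copied, no losses arise, every unmarked internal node keeps
species-disjoint children, and each marked node has identical child
species sets — so ground truth, species overlap at threshold 0 and
reconciliation must mark exactly the same duplication set. This is the
designed cross-validation regime; it deliberately does *not* exercise
losses, incomplete lineage sorting or transfer, so agreement here says
nothing about methods' behaviour when those processes operate.

## Cluster validation

Profile distances (euclidean, Pearson and Spearman dissimilarity
= 1 − correlation) use pairwise-complete columns; a row pair sharing no
observed column, or a zero-variance row under a correlation metric, is
an error naming the rows rather than a silent NaN.

Silhouette: `b(i)` is the mean distance to **all linked leaves outside
the node's subtree**, not to the nearest other cluster. A dendrogram
node has no canonical sibling partition, while the subtree/complement
split is well defined for every internal partition; this is a
documented divergence from the flat-clustering textbook definition (the
two coincide for a two-cluster partition). Singletons score 0 by
convention; values always lie in [−1, 1]; the root has no outside set
and is rejected. Dunn uses single-linkage inter-cluster distances over
the maximum diameter and raises when all diameters are zero instead of
returning an infinity — a degenerate fixture should fail loudly.

The synthetic generator places cluster centres `separation` apart along
the first coordinate and adds i.i.d. Gaussian noise (`noise_sd`,
default 1.0 — noise at the scale of one expression unit with centres
several units apart, a regime comparable to well-separated co-expression
modules). It emulates compact spherical clusters with a known
partition; it does not emulate correlated conditions, heavy-tailed
noise or nested cluster structure, so passing validation here
demonstrates correctness of the indexes, not robustness on messy real
matrices. With `noise_sd = 0` and positive separation every
ground-truth silhouette equals exactly 1 (a = 0, b > 0), which the
tests assert without tolerance.

## Rendering

The SVG writer assembles elements as strings with fixed two-decimal
coordinate formatting, making output byte-deterministic for a fixed
tree and layout; it never mutates the tree (all geometry lives in local
maps). Horizontal position is root-path length times `scale`
(auto-fitted to half the canvas when unset); leaves stack in traversal
order; `align_leaves` right-aligns leaves, the usual display for
ultrametric clustering trees, while phylogenies default to
branch-proportional tips. Aligned faces (heatmap rows, sequence strips)
form a column block to the right of the deepest leaf. Categorical
encodings live in a single `THEME` table: duplication nodes blue
circles, speciation red, loss leaves dashed grey branches, silhouette
bubbles green above zero / red below with radius proportional to the
absolute value (hidden at exactly zero). Exact pixel proportions are
not contractual; the categorical encodings are. PDF/PNG export and any
interactive GUI are out of scope — SVG is the vector output, and
external tools can rasterize it.

## Problem sizes used in the checks

The test suite and the acceptance script use 200 random trees (≤ 50
leaves) for round trips, 100 trees for the distance/ancestor, rooting
and pruning invariants, 100 simulated gene trees (3–8 species, ≤ 5
duplications) for cross-method agreement, 50 synthetic matrices (≤ 100
rows × 10 columns) for the index oracles, and one 450,001-node
caterpillar for the scalability check — sizes chosen to exercise every
code path thoroughly while keeping a full run in the tens of seconds.

## Known limitations

- No Nexus/phyloXML I/O; one newick statement per tree.
- No tree-comparison metrics (e.g. Robinson–Foulds) and no
  branch-length inference.
- Reconciliation is parsimony-style and binary-only; no probabilistic
  reconciliation, transfer events or polytomy resolution.
- The quadratic diameter scan makes midpoint rooting impractical above
  a few thousand leaves.
- Correlation metrics need at least two shared observed columns per row
  pair.
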