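"""Reading and writing trees in New Hampshire (newick) and NHX formats.

Several newick dialects are supported through a small registry: a dialect
declares which fields it serializes (leaf names, internal names, branch
lengths, supports) and where support values live (the internal-name slot,
an NHX-style bracket annotation, or nowhere).  Absent fields are filled
with the package defaults (:data:`~treescope.tree.DEFAULT_DIST`,
:data:`~treescope.tree.DEFAULT_SUPPORT`).

NHX annotations (``[&&NHX:key=value:...]``) attach to the preceding node's
feature map; the special key ``support`` maps onto the structural support
field instead, so FULL-dialect output can carry both internal names and
supports.  The parser and writer are both iterative and therefore safe on
fully unbalanced trees with hundreds of thousands of nodes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .tree import DEFAULT_DIST, TreeNode

logger = logging.getLogger("treescope.newick")

#: support value occupies the internal-name slot (RAxML style)
SUPPORT_IN_NAME = "internal_name"
#: support value is written as an NHX ``support=`` entry
SUPPORT_IN_BRACKET = "bracket"
#: support values are not serialized
SUPPORT_NONE = "none"


class NewickError(Exception):
    """Base error for newick reading/writing."""


class NewickParseError(NewickError):
    """Malformed newick input; carries the character offset."""

    def __init__(self, message: str, pos: int | None = None):
        self.pos = pos
        if pos is not None:
            message = f"{message} (at character {pos})"
        super().__init__(message)


@dataclass(frozen=True)
class NewickDialect:
    """A registered newick flavour.

    ``strict`` dialects reject malformed numeric fields; non-strict ones
    fall back to the default values.
    """
    id: int
    name: str
    writes_leaf_names: bool = True
    writes_internal_names: bool = False
    writes_branch_lengths: bool = True
    writes_support: bool = False
    support_position: str = SUPPORT_NONE
    strict: bool = True


_REGISTRY: dict[int, NewickDialect] = {}
_BY_NAME: dict[str, NewickDialect] = {}


def register_dialect(dialect: NewickDialect) -> NewickDialect:
    if not (dialect.writes_leaf_names or dialect.writes_branch_lengths):
        raise NewickError("a dialect must write leaf names or branch lengths")
    if dialect.id in _REGISTRY:
        raise NewickError(f"dialect id {dialect.id} already registered")
    if dialect.name in _BY_NAME:
        raise NewickError(f"dialect name {dialect.name!r} already registered")
    _REGISTRY[dialect.id] = dialect
    _BY_NAME[dialect.name] = dialect
    return dialect


#: maximal fidelity: leaf+internal names, lengths, supports (as NHX entries)
FULL = register_dialect(NewickDialect(
    0, "FULL", writes_leaf_names=True, writes_internal_names=True,
    writes_branch_lengths=True, writes_support=True,
    support_position=SUPPORT_IN_BRACKET, strict=True))
#: plain leaf names + branch lengths
LEAF_NAMES_LENGTHS = register_dialect(NewickDialect(
    1, "LEAF_NAMES_LENGTHS", writes_leaf_names=True,
    writes_internal_names=False, writes_branch_lengths=True,
    writes_support=False, support_position=SUPPORT_NONE, strict=True))
#: supports in the internal-name slot, no internal names
INTERNAL_SUPPORT = register_dialect(NewickDialect(
    2, "INTERNAL_SUPPORT", writes_leaf_names=True,
    writes_internal_names=False, writes_branch_lengths=True,
    writes_support=True, support_position=SUPPORT_IN_NAME, strict=True))
#: bare topology with leaf names only
TOPOLOGY_ONLY = register_dialect(NewickDialect(
    3, "TOPOLOGY_ONLY", writes_leaf_names=True,
    writes_internal_names=False, writes_branch_lengths=False,
    writes_support=False, support_position=SUPPORT_NONE, strict=True))
#: accept anything, fill defaults; numeric internal labels become supports
FLEXIBLE = register_dialect(NewickDialect(
    100, "FLEXIBLE", writes_leaf_names=True, writes_internal_names=True,
    writes_branch_lengths=True, writes_support=True,
    support_position=SUPPORT_IN_NAME, strict=False))


def get_dialect(key) -> NewickDialect:
    """Resolve a dialect instance, registry id or registry name."""
    if isinstance(key, NewickDialect):
        return key
    if isinstance(key, int):
        try:
            return _REGISTRY[key]
        except KeyError:
            raise NewickError(f"no dialect with id {key}") from None
    try:
        return _BY_NAME[str(key).upper()]
    except KeyError:
        raise NewickError(f"no dialect named {key!r}") from None


# --------------------------------------------------------------------- NHX
_NHX_KEY_BAD = set(":=[]")
_NHX_VAL_BAD = set(":[]")


def decode_nhx(comment: str) -> dict[str, str]:
    """Decode an ``&&NHX`` comment body into ordered key→value entries.

    Duplicate keys: the last occurrence wins and a warning is logged.
    """
    if not comment.startswith("&&NHX"):
        raise NewickParseError(f"not an NHX comment: {comment!r}")
    rest = comment[len("&&NHX"):]
    entries: dict[str, str] = {}
    if not rest:
        return entries
    if not rest.startswith(":"):
        raise NewickParseError(f"malformed NHX comment: {comment!r}")
    for fragment in rest[1:].split(":"):
        if "=" not in fragment:
            raise NewickParseError(f"malformed NHX pair {fragment!r}")
        key, value = fragment.split("=", 1)
        if key in entries:
            logger.warning("duplicate NHX key %r: last occurrence wins", key)
        entries[key] = value
    return entries


def encode_nhx(entries: dict[str, str]) -> str:
    """Serialize entries as ``[&&NHX:k=v:...]``; empty input gives ''."""
    if not entries:
        return ""
    parts = []
    for key, value in entries.items():
        key, value = str(key), str(value)
        if not key or _NHX_KEY_BAD & set(key):
            raise NewickError(f"illegal NHX key {key!r}")
        if _NHX_VAL_BAD & set(value):
            raise NewickError(f"illegal NHX value {value!r} for key {key!r}")
        parts.append(f"{key}={value}")
    return "[&&NHX:" + ":".join(parts) + "]"


# ------------------------------------------------------------------- parsing
_NAME_STOP = set("():,;[]")


def parse_newick(text: str, dialect=None, node_class=TreeNode) -> TreeNode:
    """Parse one ';'-terminated newick statement into a tree.

    Multifurcations are preserved; NHX blocks attach to the feature map of
    the node they follow.  Errors report the character offset.  The walker
    is a flat loop over the input, so arbitrarily deep (caterpillar) trees
    parse without recursion-depth failures.
    """
    d = get_dialect(dialect) if dialect is not None else FLEXIBLE
    s = text
    n = len(s)
    root = node_class()
    cur = root
    depth = 0
    i = 0
    ended = False
    while i < n:
        c = s[i]
        if c.isspace():
            i += 1
        elif c == "(":
            if cur.children:
                raise NewickParseError("unexpected '('", i)
            child = node_class()
            cur.children.append(child)
            child.up = cur
            cur = child
            depth += 1
            i += 1
        elif c == ",":
            if cur.up is None:
                raise NewickParseError("dangling comma outside parentheses", i)
            sib = node_class()
            cur.up.children.append(sib)
            sib.up = cur.up
            cur = sib
            i += 1
        elif c == ")":
            if depth == 0:
                raise NewickParseError("unbalanced parentheses", i)
            depth -= 1
            cur = cur.up
            i = _read_label(s, i + 1, cur, d, internal=True)
        elif c == ";":
            ended = True
            i += 1
            break
        else:
            i = _read_label(s, i, cur, d, internal=False)
    if depth != 0:
        raise NewickParseError("unbalanced parentheses", i)
    if not ended:
        raise NewickParseError("missing ';' terminator", n)
    trailing = s[i:].strip()
    if trailing:
        raise NewickParseError(f"trailing data after ';': {trailing[:20]!r}", i)
    return root


def _read_label(s: str, i: int, node: TreeNode, d: NewickDialect,
                internal: bool) -> int:
    n = len(s)
    # --- name (optionally quoted)
    if i < n and s[i] == "'":
        j = i + 1
        buf = []
        while True:
            if j >= n:
                raise NewickParseError("unterminated quoted label", i)
            if s[j] == "'":
                if j + 1 < n and s[j + 1] == "'":  # doubled quote escape
                    buf.append("'")
                    j += 2
                    continue
                j += 1
                break
            buf.append(s[j])
            j += 1
        name = "".join(buf)
        i = j
    else:
        buf = []
        while i < n and s[i] not in _NAME_STOP and s[i] != ";":
            if not s[i].isspace():
                buf.append(s[i])
            i += 1
        name = "".join(buf)
    if name:
        if internal and d.writes_support:
            # a bare number in the internal-name slot is a support value
            try:
                node.support = float(name)
            except ValueError:
                node.name = name
        else:
            node.name = name
    # --- branch length and bracket comments, in any order
    while i < n:
        c = s[i]
        if c.isspace():
            i += 1
        elif c == ":":
            i += 1
            while i < n and s[i].isspace():
                i += 1
            j = i
            while j < n and (s[j].isdigit() or s[j] in "+-.eE"):
                j += 1
            token = s[i:j]
            try:
                node.dist = float(token)
            except ValueError:
                if d.strict:
                    raise NewickParseError(
                        f"non-numeric branch length {token!r}", i) from None
                node.dist = DEFAULT_DIST
            i = j
        elif c == "[":
            j = s.find("]", i)
            if j == -1:
                raise NewickParseError("unterminated comment", i)
            content = s[i + 1:j]
            if content.startswith("&&NHX"):
                for key, value in decode_nhx(content).items():
                    if key == "support":
                        try:
                            node.support = float(value)
                        except ValueError:
                            if d.strict:
                                raise NewickParseError(
                                    f"non-numeric support {value!r}", i
                                ) from None
                    else:
                        node.features[key] = value
            # non-NHX comments are ignored
            i = j + 1
        else:
            break
    return i


def parse_forest(text: str, dialect=None, node_class=TreeNode) -> list[TreeNode]:
    """Parse a file body holding one newick statement per ';'."""
    trees = []
    statement = []
    for ch in text:
        statement.append(ch)
        if ch == ";":
            chunk = "".join(statement).strip()
            if chunk:
                trees.append(parse_newick(chunk, dialect, node_class))
            statement = []
    leftover = "".join(statement).strip()
    if leftover:
        raise NewickParseError("trailing unterminated statement", len(text))
    return trees


# ------------------------------------------------------------------- writing
_RESERVED = set("():,;[]")


def _fmt_name(name: str) -> str:
    if _RESERVED & set(name):
        raise NewickError(
            f"node name {name!r} contains newick-reserved characters; "
            "rename it (names are not auto-quoted)")
    return name


def _fmt_num(x: float) -> str:
    return repr(float(x))


def write_newick(root: TreeNode, dialect=None,
                 include_features: Iterable[str] = ()) -> str:
    """Serialize a tree under a dialect; returns a ';'-terminated string.

    Nodes carrying any feature listed in ``include_features`` gain an NHX
    block (feature order in the block is sorted for determinism).  Writing
    is iterative, safe for very deep trees.
    """
    d = get_dialect(dialect) if dialect is not None else FULL
    feats = sorted(set(include_features))
    out: list[str] = []
    stack: list = [root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            out.append(item)
            continue
        if not item.children:
            out.append(_label(item, d, feats, internal=False))
        else:
            out.append("(")
            tail: list = []
            for k, child in enumerate(item.children):
                if k:
                    tail.append(",")
                tail.append(child)
            tail.append(")" + _label(item, d, feats, internal=True))
            stack.extend(reversed(tail))
    out.append(";")
    return "".join(out)


def _label(node: TreeNode, d: NewickDialect, feats: list[str],
           internal: bool) -> str:
    if internal:
        slot = ""
        if d.writes_internal_names and node.name:
            slot = _fmt_name(node.name)
        elif d.writes_support and d.support_position == SUPPORT_IN_NAME:
            slot = _fmt_num(node.support)
    else:
        slot = _fmt_name(node.name) if d.writes_leaf_names else ""
    s = slot
    if d.writes_branch_lengths:
        s += ":" + _fmt_num(node.dist)
    entries: dict[str, str] = {}
    if d.writes_support and d.support_position == SUPPORT_IN_BRACKET:
        entries["support"] = _fmt_num(node.support)
    for f in feats:
        if f in node.features:
            entries[f] = str(node.features[f])
    s += encode_nhx(entries)
    return s


def read_tree(path, dialect=None, node_class=TreeNode) -> TreeNode:
    """Read the first newick statement of a file."""
    with open(path) as fh:
        return parse_forest(fh.read(), dialect, node_class)[0]


def write_tree(root: TreeNode, path, dialect=None,
               include_features: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(root, dialect, include_features) + "\n")
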