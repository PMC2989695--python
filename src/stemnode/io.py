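"""Newick reading/writing under two interpretations, and annotation TSV I/O.

One Newick grammar serves both tree models; the *mode* flag, never the
string's content, decides the interpretation:

* ``node`` mode — every token in label position names a vertex (taxon).
  Every vertex, internal ones and the root included, must be labeled.
* ``stem`` mode — every token in label position names the edge above it
  (the parent edge of that syntactic node), and the topmost junction of the
  tree is implicit and unlabeled.  The string's outermost label becomes the
  planted root edge, so a string whose outermost group is unlabeled
  describes more than one child under the implicit root and is rejected as
  not planted.

The same string therefore encodes a node tree and, read the other way, its
stem counterpart — the model equivalence made concrete.  The dialect is
deliberately strict: branch lengths and any other ``:``-suffixed payload
are errors, not ignored, because a bare number in label position would be
ambiguous between a taxon name and a support value; here it is always a
label.  Serialization is canonical (children ordered lexicographically by
their subtree label multiset) so that reading back a written string is the
identity and corresponding node/stem trees serialize to identical text.

Annotations travel as two-column TSV: taxon label, then a comma-separated
list of character identifiers.  Duplicate taxon rows merge as multisets.
"""

from __future__ import annotations

import re
from typing import TextIO

from .conversion import AnnotationMap
from .tree_core import (
    DuplicateLabelError,
    NodeTree,
    NotPlantedError,
    StemTree,
    TreeError,
    _label_multiset_key,
)

__all__ = [
    "NewickSyntaxError",
    "read_newick",
    "write_newick",
    "read_annotations",
    "write_annotations",
]

_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,']+$")


class NewickSyntaxError(TreeError):
    """Malformed Newick input; ``position`` is the 0-based character offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _tokenize(text: str):
    """Yield (kind, value, position) tokens; kinds: punct, label."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),;":
            yield ("punct", c, i)
            i += 1
        elif c == ":":
            raise NewickSyntaxError(
                "branch lengths are not accepted in this dialect", i
            )
        elif c == "'":
            start = i
            i += 1
            chars = []
            while True:
                if i >= n:
                    raise NewickSyntaxError("unterminated quoted label", start)
                if text[i] == "'":
                    if i + 1 < n and text[i + 1] == "'":  # doubled quote escape
                        chars.append("'")
                        i += 2
                    else:
                        i += 1
                        break
                else:
                    chars.append(text[i])
                    i += 1
            yield ("label", "".join(chars), start)
        else:
            start = i
            while i < n and not text[i].isspace() and text[i] not in "(),;:'":
                i += 1
            yield ("label", text[start:i], start)


def _parse(text: str):
    """Parse to nested ``(label_or_None, children_list, position)`` triples."""
    tokens = list(_tokenize(text))
    if not tokens:
        raise NewickSyntaxError("empty input", 0)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else ("punct", "<end>", len(text))

    def parse_subtree():
        nonlocal pos
        kind, value, at = peek()
        if kind == "punct" and value == "(":
            pos += 1
            children = [parse_subtree()]
            while True:
                kind, value, at = peek()
                if kind == "punct" and value == ",":
                    pos += 1
                    children.append(parse_subtree())
                elif kind == "punct" and value == ")":
                    pos += 1
                    break
                else:
                    raise NewickSyntaxError(
                        f"expected ',' or ')', got {value!r}", at
                    )
            kind, value, at = peek()
            label = None
            if kind == "label":
                label = value
                pos += 1
            return (label, children, at)
        if kind == "label":
            pos += 1
            return (value, [], at)
        raise NewickSyntaxError(f"expected a label or '(', got {value!r}", at)

    root = parse_subtree()
    kind, value, at = peek()
    if not (kind == "punct" and value == ";"):
        raise NewickSyntaxError("expected trailing ';'", at)
    if pos + 1 != len(tokens):
        raise NewickSyntaxError("trailing content after ';'", tokens[pos + 1][2])
    return root


def read_newick(text: str, mode: str) -> NodeTree | StemTree:
    """Parse a Newick string as a node-based or stem-based tree.

    The mode is explicit and never guessed from the content.  Labels must
    be unique and present on every vertex (node mode) / every edge (stem
    mode); in stem mode a missing outermost label means several children
    hang under the implicit unlabeled root, which is not a planted tree.
    """
    if mode not in ("node", "stem"):
        raise TreeError(f"mode must be 'node' or 'stem', got {mode!r}")
    root = _parse(text)
    seen: set[str] = set()

    def check_label(node, what: str) -> str:
        label, _, at = node
        if label is None or label == "":
            raise NewickSyntaxError(f"missing {what} label in {mode} mode", at)
        if label in seen:
            raise DuplicateLabelError(f"duplicate label {label!r}")
        seen.add(label)
        return label

    if mode == "node":
        parent: dict[str, str] = {}

        def walk(node, parent_label):
            label = check_label(node, "vertex")
            if parent_label is not None:
                parent[label] = parent_label
            for child in node[1]:
                walk(child, label)
            return label

        root_label = walk(root, None)
        return NodeTree(root_label, parent)

    # stem mode: each syntactic node's label names its parent edge
    if root[0] is None or root[0] == "":
        raise NotPlantedError(
            "stem-mode input has no outermost label: more than one edge hangs "
            "under the implicit root junction, so the tree is not planted"
        )
    edges: dict[str, tuple] = {}
    counter = iter(range(10**9))

    def walk_stem(node, tail):
        label = check_label(node, "edge")
        head = next(counter)
        edges[label] = (tail, head)
        for child in node[1]:
            walk_stem(child, head)

    planted_root = next(counter)
    walk_stem(root, planted_root)
    return StemTree(planted_root, edges)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _render_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _canonical_node(tree: NodeTree, v: str) -> tuple:
    kids = sorted(
        (_canonical_node(tree, c) for c in tree.children(v)),
        key=_label_multiset_key,
    )
    return (v, tuple(kids))


def _render(canon: tuple) -> str:
    label, kids = canon
    if not kids:
        return _render_label(label)
    return "(" + ",".join(_render(k) for k in kids) + ")" + _render_label(label)


def write_newick(tree: NodeTree | StemTree, mode: str | None = None) -> str:
    """Serialize a tree to canonical Newick.

    The mode defaults to the tree's own model and must match it.
    Corresponding node and stem trees serialize to character-identical
    strings: the vertex names of one are the edge names of the other.
    """
    inferred = "node" if isinstance(tree, NodeTree) else "stem"
    if mode is None:
        mode = inferred
    if mode != inferred:
        raise TreeError(
            f"cannot write a {inferred}-model tree in {mode!r} mode; convert first"
        )
    if isinstance(tree, NodeTree):
        canon = _canonical_node(tree, tree.root)
    else:
        canon = tree.canonical_form()
    return _render(canon) + ";"


# ---------------------------------------------------------------------------
# annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(source: str | TextIO) -> AnnotationMap:
    """Read a two-column TSV (taxon, comma-separated character ids).

    Blank lines and ``#`` comments are skipped; duplicate taxon rows merge
    their characters as a multiset.  Malformed lines report their number.
    """
    text = source if isinstance(source, str) else source.read()
    ann = AnnotationMap()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip():
            raise TreeError(
                f"malformed annotation line {lineno}: expected "
                f"'taxon<TAB>id1,id2,...', got {line!r}"
            )
        taxon = parts[0].strip()
        chars = [c.strip() for c in parts[1].split(",") if c.strip()]
        ann.add(taxon, chars)
    return ann


def write_annotations(ann: AnnotationMap) -> str:
    """Serialize an annotation map to the two-column TSV format."""
    lines = []
    for taxon in sorted(ann):
        chars = sorted(ann[taxon].elements())
        lines.append(f"{taxon}\t{','.join(chars)}")
    return "\n".join(lines) + ("\n" if lines else "")
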