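"""Core rooted-tree data model shared by both phylogeny representations.

Two graphical models of the same phylogeny are implemented:

* :class:`NodeTree` — taxa are *vertices*; edges are ancestry relations
  between taxa ("is-parent-of").  Internal vertices are ancestral taxa,
  unsampled but inferred, and carry names just like terminal taxa.
* :class:`StemTree` — taxa are *edges* (lineages); vertices are unnamed
  speciation events ("junctions").  Every stem tree is *planted*: its root
  junction has exactly one child, so there is a unique root edge
  representing the common ancestor of all sampled taxa.

Both models support polytomies and carry no branch lengths: an edge states
an ancestry hypothesis, not a duration.  Junction identifiers in a
:class:`StemTree` are internal bookkeeping with no biological meaning;
two stem trees are equal when they differ only by junction renaming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "TreeError",
    "LabelNotFoundError",
    "DuplicateLabelError",
    "NotAnAncestorError",
    "EmptyQueryError",
    "NotPlantedError",
    "InvalidSubtreeError",
    "SizeGuardError",
    "SubtreeRef",
    "NodeTree",
    "StemTree",
]


class TreeError(ValueError):
    """Base class for all structural and query errors raised by this package."""


class LabelNotFoundError(TreeError, KeyError):
    """A queried taxon label does not occur in the tree."""

    def __init__(self, label: str):
        super().__init__(f"taxon label not found in tree: {label!r}")
        self.label = label


class DuplicateLabelError(TreeError):
    """A taxon label occurs more than once."""


class NotAnAncestorError(TreeError):
    """The designated endpoint of a lineage query is not an ancestor."""


class EmptyQueryError(TreeError):
    """A taxon-set query was made with an empty set."""


class NotPlantedError(TreeError):
    """A stem-based tree was expected but the root has more than one child."""


class InvalidSubtreeError(TreeError):
    """A :class:`SubtreeRef` does not describe a subtree of its host."""


class SizeGuardError(TreeError):
    """An exhaustive enumeration was requested beyond the supported size."""


def _check_label(label: object) -> str:
    if not isinstance(label, str) or not label:
        raise TreeError(f"taxon labels must be non-empty strings, got {label!r}")
    return label


@dataclass(frozen=True)
class SubtreeRef:
    """Reference to a subtree of a host tree.

    ``model`` is ``"node"`` (``elements`` are vertex labels) or ``"stem"``
    (``elements`` are edge labels).  ``planted`` is meaningful only for stem
    subtrees: a planted subtree hangs from a single topmost edge, which is
    what makes it the stem-model image of a proper subtree.
    """

    model: str
    elements: frozenset[str]
    planted: bool | None = None

    def __post_init__(self):
        if self.model not in ("node", "stem"):
            raise TreeError(f"model must be 'node' or 'stem', got {self.model!r}")
        object.__setattr__(self, "elements", frozenset(self.elements))


class NodeTree:
    """Rooted tree whose vertices are uniquely labeled taxa.

    Parameters
    ----------
    root:
        Label of the root taxon (the taxon with no parent).
    parent_of:
        Mapping from each non-root label to its parent's label.  The root
        must not appear as a key.

    The constructor validates connectivity and acyclicity: following
    ``parent_of`` from any vertex must terminate at ``root``, and the edge
    count is therefore always the vertex count minus one.
    """

    __slots__ = ("root", "_parent", "_children", "labels")

    def __init__(self, root: str, parent_of: Mapping[str, str] = ()):  # type: ignore[assignment]
        _check_label(root)
        parent = {(_check_label(c)): _check_label(p) for c, p in dict(parent_of).items()}
        if root in parent:
            raise TreeError(f"root {root!r} must not have a parent")
        labels = set(parent) | {root}
        for p in parent.values():
            if p not in labels:
                raise TreeError(f"parent label {p!r} is not a vertex of the tree")
        # acyclicity / connectivity: every chain must reach the root
        for v in parent:
            seen = {v}
            cur = v
            while cur != root:
                cur = parent[cur]
                if cur in seen:
                    raise TreeError(f"cycle detected through vertex {cur!r}")
                seen.add(cur)
        self.root = root
        self._parent = parent
        self.labels = frozenset(labels)
        children: dict[str, list[str]] = {v: [] for v in labels}
        for c, p in parent.items():
            children[p].append(c)
        self._children = {v: tuple(sorted(cs)) for v, cs in children.items()}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_children(cls, root: str, children: Mapping[str, Iterable[str]]) -> "NodeTree":
        """Build from a ``parent -> children`` mapping (duplicates rejected)."""
        parent: dict[str, str] = {}
        for p, cs in children.items():
            for c in cs:
                if c in parent:
                    raise DuplicateLabelError(f"vertex {c!r} listed under two parents")
                parent[c] = p
        return cls(root, parent)

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self._parent)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def _require(self, label: str) -> str:
        if label not in self.labels:
            raise LabelNotFoundError(label)
        return label

    def children(self, v: str) -> tuple[str, ...]:
        """Children of ``v``, in sorted order."""
        return self._children[self._require(v)]

    def parent(self, v: str) -> str | None:
        """The unique parent of ``v``, or ``None`` iff ``v`` is the root."""
        return self._parent.get(self._require(v))

    def ancestors(self, v: str) -> list[str]:
        """Ancestors of ``v`` from its parent up to the root; ``[]`` for the root."""
        self._require(v)
        out = []
        cur = self._parent.get(v)
        while cur is not None:
            out.append(cur)
            cur = self._parent.get(cur)
        return out

    def lineage(self, x: str, y: str) -> list[str]:
        """Ancestors of ``x`` that are descendants of, or equal to, ``y``.

        With ``y`` the root this is the *total lineage* of ``x``.  ``x``
        itself is excluded and ``y`` is included.  Raises
        :class:`NotAnAncestorError` if ``y`` is not on ``x``'s ancestor chain.
        """
        self._require(y)
        chain = self.ancestors(x)
        if y not in chain:
            raise NotAnAncestorError(f"{y!r} is not an ancestor of {x!r}")
        return chain[: chain.index(y) + 1]

    def is_ancestor(self, x: str, y: str) -> bool:
        """True iff ``x`` is a strict ancestor of ``y``."""
        return x in self.ancestors(y)

    def youngest_common_ancestor(self, taxa: Iterable[str]) -> str:
        """The unique minimal vertex that is ancestor-or-equal of every member.

        Known in common usage as the MRCA.  May itself belong to the query
        set.  Raises :class:`EmptyQueryError` on an empty set.
        """
        members = list(taxa)
        if not members:
            raise EmptyQueryError("youngest common ancestor of an empty set is undefined")
        # ancestor-or-self chains, root first, share a prefix; the YCA is the
        # deepest vertex common to all of them.
        chains = []
        for v in members:
            chain = self.ancestors(self._require(v))[::-1] + [v]
            chains.append(chain)
        yca = self.root
        for level in zip(*chains):
            if len(set(level)) == 1:
                yca = level[0]
            else:
                break
        return yca

    def descendants(self, v: str) -> frozenset[str]:
        """All vertices having ``v`` on their ancestor chain; excludes ``v``."""
        self._require(v)
        out: set[str] = set()
        stack = list(self._children[v])
        while stack:
            w = stack.pop()
            out.add(w)
            stack.extend(self._children[w])
        return frozenset(out)

    # -- subtrees -------------------------------------------------------------

    def proper_subtree(self, v: str) -> SubtreeRef:
        """The subtree consisting of ``v`` and all its descendants."""
        return SubtreeRef("node", self.descendants(v) | {v})

    def is_subtree(self, taxa: Iterable[str]) -> bool:
        """True iff the induced subgraph on the given vertices is connected.

        The induced subgraph takes every tree edge with both ends in the set;
        being a subgraph of a tree, it is a tree exactly when connected.
        """
        members = {self._require(v) for v in taxa}
        if not members:
            raise EmptyQueryError("empty vertex set is not a subtree")
        # connected iff exactly one member has no parent inside the set
        tops = [v for v in members if self._parent.get(v) not in members]
        return len(tops) == 1

    def is_proper_subtree(self, taxa: Iterable[str]) -> bool:
        """True iff the set equals some vertex together with all its descendants."""
        members = frozenset(taxa)
        if not members:
            return False
        if not self.is_subtree(members):
            return False
        top = next(v for v in members if self._parent.get(v) not in members)
        return members == self.descendants(top) | {top}

    # -- equality / hashing ---------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeTree):
            return NotImplemented
        return self.root == other.root and self._parent == other._parent

    def __hash__(self) -> int:
        return hash((self.root, frozenset(self._parent.items())))

    def __repr__(self) -> str:
        return f"NodeTree(root={self.root!r}, n={len(self)})"


class StemTree:
    """Planted rooted tree whose edges are uniquely labeled taxa.

    Parameters
    ----------
    root:
        Junction identifier of the planted root.
    edges:
        Mapping ``label -> (tail, head)`` giving, for each taxon, the
        speciation events at the old (tail) and young (head) end of its
        lineage.  Junction identifiers may be any hashable values; they are
        never serialized and equality ignores them.

    Invariants enforced: the underlying graph is a tree, the root junction
    has exactly one child (planted), and junction count = edge count + 1.
    """

    __slots__ = ("root", "_edges", "_junctions", "labels", "_out", "_in")

    def __init__(self, root, edges: Mapping[str, tuple]):
        edict = {(_check_label(lb)): (t, h) for lb, (t, h) in dict(edges).items()}
        if not edict:
            raise TreeError("a stem tree must have at least one edge (taxon)")
        junctions = {root}
        for t, h in edict.values():
            junctions.add(t)
            junctions.add(h)
        if len(junctions) != len(edict) + 1:
            raise TreeError(
                f"junction count ({len(junctions)}) must be edge count + 1 ({len(edict) + 1})"
            )
        incoming: dict = {}
        outgoing: dict = {j: [] for j in junctions}
        for lb, (t, h) in edict.items():
            if h in incoming:
                raise TreeError(f"junction {h!r} has two parent edges")
            if h == root:
                raise TreeError("the root junction cannot be the head of an edge")
            incoming[h] = lb
            outgoing[t].append(lb)
        # connectivity: every junction's parent chain must reach the root
        for j in junctions:
            seen = {j}
            cur = j
            while cur != root:
                if cur not in incoming:
                    raise TreeError(f"junction {cur!r} is disconnected from the root")
                cur = edict[incoming[cur]][0]
                if cur in seen:
                    raise TreeError("cycle detected among junctions")
                seen.add(cur)
        if len(outgoing[root]) != 1:
            raise NotPlantedError(
                f"a stem tree must be planted: root junction has "
                f"{len(outgoing[root])} children, expected exactly 1"
            )
        self.root = root
        self._edges = edict
        self._junctions = frozenset(junctions)
        self.labels = frozenset(edict)
        self._out = {j: tuple(sorted(lbs)) for j, lbs in outgoing.items()}
        self._in = incoming

    # -- basic queries --------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def n_junctions(self) -> int:
        return len(self._junctions)

    @property
    def root_edge(self) -> str:
        """Label of the unique edge emanating from the planted root."""
        return self._out[self.root][0]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def _require(self, label: str) -> str:
        if label not in self.labels:
            raise LabelNotFoundError(label)
        return label

    def endpoints(self, e: str) -> tuple:
        """(tail, head) junctions of edge ``e`` — internal identifiers."""
        return self._edges[self._require(e)]

    def parent_edge(self, e: str) -> str | None:
        """The edge below ``e`` (its ancestor lineage), or None for the root edge."""
        tail = self._edges[self._require(e)][0]
        return self._in.get(tail)

    def child_edges(self, e: str) -> tuple[str, ...]:
        """Edges emanating from the head (young end) of ``e``, sorted."""
        head = self._edges[self._require(e)][1]
        return self._out[head]

    def descendant_edges(self, e: str) -> frozenset[str]:
        """All edges strictly descended from ``e``."""
        self._require(e)
        out: set[str] = set()
        stack = list(self.child_edges(e))
        while stack:
            w = stack.pop()
            out.add(w)
            stack.extend(self.child_edges(w))
        return frozenset(out)

    # -- subtrees -------------------------------------------------------------

    def planted_proper_subtree(self, e: str) -> SubtreeRef:
        """The subtree made of ``e`` and every edge descended from it.

        Its local root (the tail of ``e``) has exactly one child within the
        subtree, so the result is always planted.
        """
        return SubtreeRef("stem", self.descendant_edges(e) | {e}, planted=True)

    def is_subtree(self, edge_labels: Iterable[str]) -> tuple[bool, bool]:
        """Whether the edges (with their endpoints) form a subtree, and whether
        that subtree is planted.

        Returns ``(is_subtree, planted)``.  ``planted`` is ``True`` when the
        shallowest junction touched by the members has exactly one member
        edge above it; only then does the edge set correspond to a vertex
        subtree of the node-based model.
        """
        members = {self._require(e) for e in edge_labels}
        if not members:
            raise EmptyQueryError("empty edge set is not a subtree")
        touched = set()
        for e in members:
            t, h = self._edges[e]
            touched.add(t)
            touched.add(h)
        # member edges are acyclic (subgraph of a tree), so the subgraph is
        # connected iff it has exactly one more junction than edges
        if len(touched) != len(members) + 1:
            return (False, False)
        shallowest = self._shallowest(touched)
        planted = sum(1 for e in members if self._edges[e][0] == shallowest) == 1
        return (True, planted)

    def _shallowest(self, junctions) -> object:
        """The junction of the set closest to the planted root."""
        best, best_depth = None, None
        for j in junctions:
            d = 0
            cur = j
            while cur != self.root:
                cur = self._edges[self._in[cur]][0]
                d += 1
            if best_depth is None or d < best_depth:
                best, best_depth = j, d
        return best

    def is_planted_proper_subtree(self, edge_labels: Iterable[str]) -> bool:
        """True iff the set equals some edge together with all its descendant edges."""
        members = frozenset(edge_labels)
        ok, planted = self.is_subtree(members)
        if not (ok and planted):
            return False
        top = next(e for e in members if self.parent_edge(e) not in members)
        return members == self.descendant_edges(top) | {top}

    # -- canonical form / equality -------------------------------------------

    def _canonical(self, e: str) -> tuple:
        """Canonical nested form of the subtree planted at edge ``e``.

        Children are ordered lexicographically by their subtree label
        multiset, which is well defined because labels are unique.
        """
        kids = sorted(
            (self._canonical(c) for c in self.child_edges(e)),
            key=_label_multiset_key,
        )
        return (e, tuple(kids))

    def canonical_form(self) -> tuple:
        """Junction-renaming-invariant canonical form (basis of equality)."""
        return self._canonical(self.root_edge)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StemTree):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def __hash__(self) -> int:
        return hash(self.canonical_form())

    def __repr__(self) -> str:
        return f"StemTree(root_edge={self.root_edge!r}, n={len(self)})"


def _label_multiset_key(canon: tuple) -> tuple[str, ...]:
    """Sorted tuple of all labels in a canonical nested form."""
    label, kids = canon
    out = [label]
    stack = list(kids)
    while stack:
        lb, ks = stack.pop()
        out.append(lb)
        stack.extend(ks)
    return tuple(sorted(out))
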