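"""Conversion between the node-based and stem-based tree models.

The two models encode the same phylogeny.  Going node → stem, a new
unnamed planted root is created above the old root taxon, a new edge joins
them, and every edge is labeled by the taxon at its young end; the old
vertex names are then dropped.  Going stem → node, every non-root junction
takes the name of its parent edge, the planted root junction and root edge
are removed, and edge names are dropped.  The two procedures are mutually
inverse, which is what makes the two models interchangeable: there are
exactly as many rooted taxon-labeled node trees on n taxa as planted
edge-labeled stem trees.

The correspondence also maps subtrees: the proper subtree of the node tree
rooted at taxon v has the same label set as the planted proper subtree of
the stem tree hanging from edge v.  It does *not* extend to arbitrary
subtrees — a non-planted stem subtree has no node-model counterpart, and
:func:`corresponding_subtree` returns a diagnostic
:class:`CorrespondenceUndefined` in that case rather than raising, because
that failure mode is scientifically meaningful (it is the shape of the
node-name-on-stem-tree mistake).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .tree_core import (
    InvalidSubtreeError,
    LabelNotFoundError,
    NodeTree,
    NotPlantedError,
    StemTree,
    SubtreeRef,
    TreeError,
)

__all__ = [
    "node_to_stem",
    "stem_to_node",
    "corresponding_subtree",
    "CorrespondenceUndefined",
    "AnnotationMap",
    "translate_annotations",
]


def node_to_stem(tree: NodeTree) -> StemTree:
    """Convert a node-based tree to its stem-based counterpart.

    A fresh planted root junction is placed above the old root taxon and
    each edge takes the label of the taxon at its young end, so the output's
    edge-label set equals the input's vertex-label set.  The planted root is
    an unnamed sentinel junction: the ephemeral "0" of the construction is
    never exposed, so it can never collide with a real taxon name.
    """
    # junction k is the young end of the edge named by vertex k
    junction = {v: v for v in tree.labels}
    root_junction = object()  # unnamed sentinel, distinct from every label
    edges: dict[str, tuple] = {}
    for v in tree.labels:
        p = tree.parent(v)
        tail = root_junction if p is None else junction[p]
        edges[v] = (tail, junction[v])
    return StemTree(root_junction, edges)


def stem_to_node(tree: StemTree) -> NodeTree:
    """Convert a stem-based tree back to its node-based counterpart.

    Each non-root junction is named after its parent edge; the planted root
    junction disappears, and the root edge's label becomes the root taxon.
    Inverse of :func:`node_to_stem`.
    """
    if not isinstance(tree, StemTree):
        raise NotPlantedError("stem_to_node expects a (planted) stem tree")
    parent: dict[str, str] = {}
    for e in tree.labels:
        p = tree.parent_edge(e)
        if p is not None:
            parent[e] = p
    return NodeTree(tree.root_edge, parent)


@dataclass(frozen=True)
class CorrespondenceUndefined:
    """Marker returned when a stem subtree has no node-model counterpart.

    Carries the offending edge set and a diagnostic: the corresponding
    vertex set fails to be a subtree of the node tree because the stem
    subtree is not planted.
    """

    elements: frozenset[str]
    reason: str

    def __bool__(self) -> bool:  # truth-tests as "no correspondence"
        return False


def corresponding_subtree(
    tree: NodeTree | StemTree, ref: SubtreeRef
) -> SubtreeRef | CorrespondenceUndefined:
    """Map a subtree reference across the model correspondence.

    ``tree`` is the host of ``ref``.  A node subtree maps to the stem
    subtree on the same labels (always well defined, and planted exactly
    when the node subtree is a subtree).  A stem subtree maps to the node
    subtree on the same labels only when planted; otherwise a
    :class:`CorrespondenceUndefined` diagnostic is returned.
    """
    if ref.model == "node":
        if not isinstance(tree, NodeTree):
            raise TreeError("node-model ref requires a NodeTree host")
        if not tree.is_subtree(ref.elements):
            raise InvalidSubtreeError(
                f"vertex set {sorted(ref.elements)} is not a subtree of the host"
            )
        return SubtreeRef("stem", ref.elements, planted=True)
    if not isinstance(tree, StemTree):
        raise TreeError("stem-model ref requires a StemTree host")
    ok, planted = tree.is_subtree(ref.elements)
    if not ok:
        raise InvalidSubtreeError(
            f"edge set {sorted(ref.elements)} is not a subtree of the host"
        )
    if not planted:
        return CorrespondenceUndefined(
            frozenset(ref.elements),
            "the stem subtree is not planted, so the corresponding vertex set "
            "does not form a subtree of the node-based tree",
        )
    return SubtreeRef("node", ref.elements)


class AnnotationMap(dict):
    """Per-taxon multiset of character identifiers (apomorphies).

    Maps taxon label -> :class:`collections.Counter` of character ids.  A
    character marks the lineage in which it is hypothesized to have become
    fixed; its position along the lineage carries no meaning, so only
    multiplicity is stored.
    """

    def __init__(self, data: Mapping[str, object] = ()):  # type: ignore[assignment]
        super().__init__()
        for taxon, chars in dict(data).items():
            self.add(taxon, chars)

    def add(self, taxon: str, chars) -> None:
        """Merge character ids (any iterable, or a Counter) onto ``taxon``."""
        counter = chars if isinstance(chars, Counter) else Counter(chars)
        if taxon in self:
            self[taxon] = self[taxon] + counter
        else:
            self[taxon] = counter

    def validate(self, tree: NodeTree | StemTree) -> "AnnotationMap":
        """Check every annotated taxon occurs in ``tree``; returns self."""
        for taxon in self:
            if taxon not in tree.labels:
                raise LabelNotFoundError(taxon)
        return self


def translate_annotations(
    ann: AnnotationMap,
    source: NodeTree | StemTree,
    target: NodeTree | StemTree,
) -> AnnotationMap:
    """Carry character annotations from one model to the other.

    The model correspondence preserves taxon labels, so characters on the
    edge named v of a stem tree sit on the vertex named v of the node tree
    and vice versa: translation is label-identity, validated against both
    trees rather than transformed.
    """
    ann.validate(source)
    if source.labels != target.labels:
        raise TreeError(
            "source and target trees carry different taxon sets; "
            "they cannot represent the same phylogeny"
        )
    out = AnnotationMap()
    for taxon, chars in ann.items():
        out.add(taxon, Counter(chars))
    return out.validate(target)
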