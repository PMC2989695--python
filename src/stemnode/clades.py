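"""Clade extraction and monophyly classification on either tree model.

A monophyletic group is a common ancestor together with *all* of its
descendants — the ancestor itself included, following Hennig.  On a
node-based tree that is the proper subtree rooted at a vertex; on a
stem-based tree it is the proper subtree planted at an edge.  The two
notions name exactly the same taxon sets once the model correspondence is
applied, which is why a clade name only makes sense on the model it was
defined for.

Classification of an arbitrary taxon set S is decided by its youngest
common ancestor a = YCA(S):

* **monophyletic** — S is exactly a plus all of a's descendants;
* **paraphyletic** — a belongs to S but some descendants of a are missing;
* **polyphyletic** — a is not in S.

The paraphyly/polyphyly split via YCA membership reproduces the classical
verdicts (a group excluding its own common ancestor is poly-, one merely
missing some descendants is para-) and deliberately does not require the
induced subgraph to be connected for paraphyly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

from .conversion import stem_to_node
from .tree_core import (
    EmptyQueryError,
    LabelNotFoundError,
    NodeTree,
    StemTree,
    TreeError,
)

__all__ = [
    "CladeClassification",
    "node_clade",
    "stem_clade",
    "classify",
    "classify_on_stem",
    "MisapplicationReport",
    "diagnose_misapplication",
]


class CladeClassification(str, enum.Enum):
    MONOPHYLETIC = "monophyletic"
    PARAPHYLETIC = "paraphyletic"
    POLYPHYLETIC = "polyphyletic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def node_clade(tree: NodeTree, v: str) -> frozenset[str]:
    """The clade anchored at vertex ``v``: ``v`` plus all its descendants."""
    return frozenset(tree.proper_subtree(v).elements)


def stem_clade(tree: StemTree, e: str) -> frozenset[str]:
    """The clade anchored at edge ``e``: ``e`` plus all edges descended from it.

    Equals ``node_clade`` at the same label after converting models — the
    two anchoring schemes are synonymous, each on its own model.
    """
    return frozenset(tree.planted_proper_subtree(e).elements)


def classify(tree: NodeTree, taxa: Iterable[str]) -> CladeClassification:
    """Classify a taxon set as mono-, para- or polyphyletic on a node tree."""
    members = frozenset(taxa)
    if not members:
        raise EmptyQueryError("cannot classify an empty taxon set")
    a = tree.youngest_common_ancestor(members)
    if members == tree.descendants(a) | {a}:
        return CladeClassification.MONOPHYLETIC
    if a in members:
        return CladeClassification.PARAPHYLETIC
    return CladeClassification.POLYPHYLETIC


def classify_on_stem(tree: StemTree, taxa: Iterable[str]) -> CladeClassification:
    """Classify a taxon set on a stem tree.

    Classification is a property of the phylogeny, not of the model chosen
    to draw it, so this delegates through the model correspondence.
    """
    return classify(stem_to_node(tree), taxa)


@dataclass(frozen=True)
class MisapplicationReport:
    """Outcome of applying a clade definition to the wrong tree model.

    ``mismatch`` is False when definition and model agree (nothing to
    report).  Otherwise ``message`` explains why the definition cannot be
    instantiated on this model and, where a demonstration exists,
    ``selected`` holds the taxon set the misapplied anchor would pick out
    and ``classification`` its verdict.
    """

    model: str
    definition: str
    mismatch: bool
    message: str = ""
    selected: frozenset[str] | None = None
    classification: CladeClassification | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "definition": self.definition,
            "mismatch": self.mismatch,
            "message": self.message,
            "selected": sorted(self.selected) if self.selected is not None else None,
            "classification": self.classification.value if self.classification else None,
        }


def diagnose_misapplication(
    tree: NodeTree | StemTree, definition: str, anchor: str | None = None
) -> MisapplicationReport:
    """Demonstrate what goes wrong when a clade definition meets the wrong model.

    ``definition`` is ``"node"`` or ``"stem"``, naming the kind of clade
    definition being applied.  ``anchor`` identifies where:

    * stem tree + node definition — the anchor is the speciation event at
      the young end of edge ``anchor``.  The vertex-anchored "clade" is the
      set of edges above that junction, a proper but *non-planted* subtree;
      the report classifies it (typically poly- or paraphyletic, never the
      intended monophyletic group containing the anchor lineage).
    * node tree + stem definition — the anchor names the would-be "root
      edge" parent(anchor) → anchor.  An edge without both endpoints is not
      a graph, so the structure is undefined; omitting the root edge leaves
      the well-defined node clade at ``anchor``, which the report gives.

    When definition and model agree the report is empty (``mismatch=False``).
    """
    if definition not in ("node", "stem"):
        raise TreeError(f"definition must be 'node' or 'stem', got {definition!r}")
    model = "node" if isinstance(tree, NodeTree) else "stem"
    if definition == model:
        return MisapplicationReport(model=model, definition=definition, mismatch=False)

    if anchor is None:
        raise TreeError("an anchor label is required to demonstrate the misapplication")
    if anchor not in tree.labels:
        raise LabelNotFoundError(anchor)

    if model == "stem":
        # node-based anchor on a stem tree: the anchored vertex is the young
        # end of `anchor`; its proper subtree is the non-planted edge set above.
        selected = tree.descendant_edges(anchor)
        if not selected:
            return MisapplicationReport(
                model=model,
                definition=definition,
                mismatch=True,
                message=(
                    f"a node-based anchor names a speciation event, not a taxon; "
                    f"the junction at the young end of edge {anchor!r} is terminal, "
                    f"so the vertex-anchored subtree contains no taxon at all"
                ),
                selected=frozenset(),
            )
        verdict = classify_on_stem(tree, selected)
        return MisapplicationReport(
            model=model,
            definition=definition,
            mismatch=True,
            message=(
                "a node-based clade cannot exist on a stem-based tree: the anchor "
                "selects a proper but non-planted subtree, whose taxa all descend "
                f"from the excluded lineage {anchor!r}; the selected set is "
                f"{verdict.value}, not monophyletic"
            ),
            selected=selected,
            classification=verdict,
        )

    # stem-based anchor on a node tree: the "root edge" parent(anchor)->anchor
    # cannot stand alone (an edge needs both endpoints to be a graph).
    p = tree.parent(anchor)
    clade = frozenset(tree.descendants(anchor) | {anchor})
    if p is None:
        message = (
            f"a stem-based clade needs a root edge, but {anchor!r} is the root "
            "taxon and has no parent edge; no such structure exists on this tree"
        )
    else:
        message = (
            f"a stem-based clade anchored on the edge {p!r} -> {anchor!r} would "
            "require an edge without its parent vertex, which is not a graph; "
            f"omitting the root edge leaves the well-defined node clade at "
            f"{anchor!r}, which is monophyletic"
        )
    return MisapplicationReport(
        model=model,
        definition=definition,
        mismatch=True,
        message=message,
        selected=clade,
        classification=classify(tree, clade),
    )
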