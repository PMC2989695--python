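"""Reference trees and a seeded random-tree generator.

Two small reference phylogenies recur throughout the tests and docs:

* the *five-taxon* tree — sampled taxa A, B, C with inferred ancestral
  lineages y (ancestor of B and C) and z (ancestor of everything), plus a
  character table of seven apomorphies;
* the *nine-taxon* tree — taxa 1..9, on which the classic subtree and
  monophyly demonstrations run: edge set {4,5,8,9} is a subtree of the
  stem model but the same vertices are not a subtree of the node model
  (polyphyletic), {2,4,5,8,9} is a subtree of both (monophyletic), and
  {1,3,6,7} is a planted node subtree (paraphyletic).

The random generator draws uniformly from all rooted labeled trees on n
taxa (random Prüfer sequence for the free tree, then a uniform root) and
is fully determined by its seed.
"""

from __future__ import annotations

import random

from .conversion import AnnotationMap, node_to_stem
from .enumeration import _root_edges, prufer_to_edges
from .tree_core import NodeTree, StemTree, TreeError

__all__ = [
    "fig1_tree",
    "fig1_annotations",
    "fig3_tree",
    "random_tree",
]

#: parent -> children structure of the five-taxon reference tree
_FIVE_TAXON = {"z": ["A", "y"], "y": ["B", "C"]}

#: parent -> children structure of the nine-taxon reference tree
_NINE_TAXON = {"1": ["2", "3"], "2": ["4", "5"], "3": ["6", "7"], "4": ["8", "9"]}


def _build(root: str, children: dict, model: str) -> NodeTree | StemTree:
    if model not in ("node", "stem"):
        raise TreeError(f"model must be 'node' or 'stem', got {model!r}")
    tree = NodeTree.from_children(root, children)
    return tree if model == "node" else node_to_stem(tree)


def fig1_tree(model: str = "node") -> NodeTree | StemTree:
    """The five-taxon reference tree (A, B, C with ancestors y, z).

    Node model: root z with children A and y; y's children are B and C.
    Stem model: the converted counterpart — root edge z, internal edge y,
    terminal edges A, B, C.
    """
    return _build("z", _FIVE_TAXON, model)


def fig1_annotations() -> AnnotationMap:
    """Apomorphy table for the five-taxon tree: characters 1–7.

    Characters 1 and 2 mark the internal lineage y and characters 3–5 mark
    lineage B; the placement of the remaining marks (6 on A, 7 on C) is a
    reconstruction from the textual constraints, synthetic in that the
    original drawing pins them only to terminal lineages.
    """
    return AnnotationMap(
        {"y": ["1", "2"], "B": ["3", "4", "5"], "A": ["6"], "C": ["7"]}
    )


def fig3_tree(model: str = "node") -> NodeTree | StemTree:
    """The nine-taxon reference tree used in the subtree demonstrations.

    Node model: root 1; children(1) = {2, 3}; children(2) = {4, 5};
    children(3) = {6, 7}; children(4) = {8, 9}.  The topology is a
    reconstruction satisfying every textual claim made about it (which
    subsets form subtrees, which are planted, and the three monophyly
    verdicts); it is canonical for this package's tests.
    """
    return _build("1", _NINE_TAXON, model)


def random_tree(n: int, seed: int, model: str = "node") -> NodeTree | StemTree:
    """A uniform random rooted labeled tree on taxa ``1..n``.

    Uniformity over all n^(n-1) rooted labeled trees comes from drawing a
    uniform Prüfer sequence (free tree) and an independent uniform root.
    The same ``(n, seed, model)`` always returns the same tree.
    """
    if n < 1:
        raise TreeError(f"need at least one taxon, got n={n}")
    rng = random.Random(seed)
    labels = [str(i) for i in range(1, n + 1)]
    if n == 1:
        tree = NodeTree(labels[0])
    else:
        seq = [rng.choice(labels) for _ in range(n - 2)]
        edges = prufer_to_edges(seq, labels)
        root = rng.choice(labels)
        tree = NodeTree(root, _root_edges(edges, root))
    return tree if model == "node" else node_to_stem(tree)
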