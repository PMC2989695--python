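"""Exhaustive enumeration of small labeled trees, used as a counting oracle.

The equivalence of the two tree models is certified by brute force: for a
given label set, generate every rooted vertex-labeled node tree and,
*independently*, every planted edge-labeled stem tree, and check that the
node-to-stem conversion is a bijection between the two collections.  Both
counts equal Cayley's n^(n-1).

Independence matters: the stem enumerator never calls the conversion.  It
generates planted junction skeletons directly (free trees on n+1 junctions
in which the designated root junction is a leaf, via Prüfer sequences that
avoid it), crosses them with every assignment of the n labels to the n
edges, and deduplicates by canonical form — so agreement with the node
enumerator is evidence, not tautology.

All enumerators carry hard size guards; these trees grow super-
exponentially and the point of this module is certification at small n,
not production-scale generation.
"""

from __future__ import annotations

from itertools import permutations, product
from typing import Iterator, Sequence

from .conversion import node_to_stem, stem_to_node
from .tree_core import NodeTree, SizeGuardError, StemTree

__all__ = [
    "MAX_ENUM_N",
    "enumerate_node_trees",
    "enumerate_stem_trees",
    "prufer_to_edges",
    "certify_bijection",
    "certify_subtree_correspondence",
    "CertificationFailure",
]

MAX_ENUM_N = 7
_MAX_SUBSET_N = 12


class CertificationFailure(AssertionError):
    """A certification check found a violation; carries the offending tree."""


def _guard(n: int, limit: int = MAX_ENUM_N) -> None:
    if not 1 <= n <= limit:
        raise SizeGuardError(
            f"enumeration supports 1 <= n <= {limit} labels, got {n}"
        )


def prufer_to_edges(seq: Sequence, nodes: Sequence) -> list[tuple]:
    """Decode a Prüfer sequence into the edge list of a free labeled tree.

    ``nodes`` lists the tree's vertices; ``seq`` has length ``len(nodes)-2``
    with entries drawn from ``nodes``.  Standard bijective decoding: the
    sequences over n vertices are in one-to-one correspondence with the
    n^(n-2) free labeled trees.
    """
    nodes = list(nodes)
    if len(nodes) == 1:
        return []
    if len(nodes) == 2:
        return [(nodes[0], nodes[1])]
    degree = {v: 1 for v in nodes}
    for v in seq:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [v for v in nodes if degree[v] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, w = sorted(leaves)[:2]
    edges.append((u, w))
    return edges


def _root_edges(edges: list[tuple], root) -> dict:
    """Orient a free tree's edges away from ``root``; returns child->parent."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parent: dict = {}
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                stack.append(v)
    return parent


def enumerate_node_trees(labels: Sequence[str]) -> Iterator[NodeTree]:
    """Every rooted tree on the given vertex labels, each exactly once.

    Free labeled trees come from Prüfer sequences; each is then rooted at
    every vertex in turn.  Yields n^(n-1) trees.
    """
    labels = list(labels)
    n = len(labels)
    _guard(n)
    if n == 1:
        yield NodeTree(labels[0])
        return
    for seq in product(labels, repeat=n - 2):
        edges = prufer_to_edges(seq, labels)
        for root in labels:
            yield NodeTree(root, _root_edges(edges, root))


def enumerate_stem_trees(labels: Sequence[str]) -> Iterator[StemTree]:
    """Every planted tree with the given edge labels, up to junction renaming.

    Junction skeletons are free trees on n+1 junctions in which junction 0
    (the planted root) is a leaf — exactly the Prüfer sequences over the
    other n junctions.  Each skeleton is crossed with all n! assignments of
    labels to edges and duplicates (same tree, different junction
    numbering) are removed by canonical form.  Conversion code is never
    invoked, keeping this enumeration an independent oracle.
    """
    labels = list(labels)
    n = len(labels)
    _guard(n)
    junctions = list(range(n + 1))  # 0 is the planted root
    if n == 1:
        yield StemTree(0, {labels[0]: (0, 1)})
        return
    seen: set = set()
    for seq in product(junctions[1:], repeat=n - 1):
        free_edges = prufer_to_edges(seq, junctions)
        parent = _root_edges(free_edges, 0)  # child junction -> parent junction
        # orientations away from junction 0; 0 is a leaf since it is absent
        # from the Prüfer sequence, so the rooted skeleton is planted
        slots = sorted(parent)  # the n child junctions, one edge each
        for perm in permutations(labels):
            edges = {lb: (parent[j], j) for lb, j in zip(perm, slots)}
            tree = StemTree(0, edges)
            key = tree.canonical_form()
            if key not in seen:
                seen.add(key)
                yield tree


def certify_bijection(n: int, labels: Sequence[str] | None = None) -> dict:
    """Certify that node-to-stem conversion is a bijection at size ``n``.

    Runs both enumerations, checks that conversion is injective on the node
    enumeration, that its image is exactly the stem enumeration, and that
    both round-trips are identities.  Returns a report dict with both
    counts; raises :class:`CertificationFailure` (with the offending tree's
    serialization) on any violation.
    """
    from .io import write_newick

    _guard(n, limit=5)  # full double enumeration; factorial labelings beyond 5
    if labels is None:
        labels = [str(i) for i in range(1, n + 1)]
    node_trees = list(enumerate_node_trees(labels))
    stem_trees = list(enumerate_stem_trees(labels))
    images = {}
    for t in node_trees:
        u = node_to_stem(t)
        key = u.canonical_form()
        if key in images:
            raise CertificationFailure(
                f"conversion is not injective: {write_newick(t)} and "
                f"{write_newick(images[key])} map to the same stem tree"
            )
        images[key] = t
        if stem_to_node(u) != t:
            raise CertificationFailure(
                f"round trip node->stem->node altered {write_newick(t)}"
            )
    stem_keys = set()
    for u in stem_trees:
        key = u.canonical_form()
        if key in stem_keys:
            raise CertificationFailure(
                f"duplicate in stem enumeration: {write_newick(u)}"
            )
        stem_keys.add(key)
        if node_to_stem(stem_to_node(u)) != u:
            raise CertificationFailure(
                f"round trip stem->node->stem altered {write_newick(u)}"
            )
    if set(images) != stem_keys:
        raise CertificationFailure(
            "conversion image differs from the independent stem enumeration "
            f"({len(images)} vs {len(stem_keys)} trees)"
        )
    return {
        "n": n,
        "node_tree_count": len(node_trees),
        "stem_tree_count": len(stem_trees),
        "bijection": True,
        "expected_cayley": n ** (n - 1),
    }


def certify_subtree_correspondence(tree: NodeTree) -> dict:
    """Certify the subtree correspondence on one tree, over all label subsets.

    For every non-empty subset S of taxa: S is a subtree of the node tree
    exactly when, as an edge set, it is a *planted* subtree of the stem
    counterpart; and S is a proper subtree exactly when it is a planted
    proper subtree.  Also checks that the number of proper subtrees equals
    the number of vertices.  Returns a report dict with the counts.
    """
    n = len(tree.labels)
    if n > _MAX_SUBSET_N:
        raise SizeGuardError(
            f"subset certification supports trees with <= {_MAX_SUBSET_N} "
            f"vertices, got {n}"
        )
    from .io import write_newick

    u = node_to_stem(tree)
    labels = sorted(tree.labels)
    n_subtrees = n_planted = n_proper = 0
    for mask in range(1, 1 << n):
        subset = frozenset(lb for i, lb in enumerate(labels) if mask >> i & 1)
        is_node_sub = tree.is_subtree(subset)
        _, stem_planted = u.is_subtree(subset)
        if is_node_sub != stem_planted:
            raise CertificationFailure(
                f"subset {sorted(subset)} of {write_newick(tree)}: subtree of "
                f"node tree = {is_node_sub}, planted subtree of stem tree = "
                f"{stem_planted}"
            )
        is_proper = tree.is_proper_subtree(subset)
        if is_proper != u.is_planted_proper_subtree(subset):
            raise CertificationFailure(
                f"subset {sorted(subset)} breaks the proper-subtree "
                f"correspondence on {write_newick(tree)}"
            )
        n_subtrees += is_node_sub
        n_planted += stem_planted
        n_proper += is_proper
    if n_proper != n:
        raise CertificationFailure(
            f"{write_newick(tree)} has {n_proper} proper subtrees but "
            f"{n} vertices"
        )
    return {
        "n_vertices": n,
        "n_subtrees": n_subtrees,
        "n_planted_stem_subtrees": n_planted,
        "n_proper_subtrees": n_proper,
        "correspondence": True,
    }
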