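"""Ancestry queries and subtree checks on the core tree models."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemnode import (
    EmptyQueryError,
    LabelNotFoundError,
    NodeTree,
    NotAnAncestorError,
    NotPlantedError,
    StemTree,
    TreeError,
    random_tree,
)


class TestNodeTreeConstruction:
    def test_single_vertex_is_minimal(self):
        t = NodeTree("only")
        assert t.root == "only"
        assert t.n_vertices == 1 and t.n_edges == 0

    def test_vertex_edge_balance(self, fig3_node):
        assert fig3_node.n_vertices == fig3_node.n_edges + 1 == 9

    @pytest.mark.parametrize(
        "root,parent",
        [
            ("a", {"a": "b", "b": "a"}),  # root with a parent
            ("a", {"b": "c", "c": "b"}),  # cycle off the root
            ("a", {"b": "z"}),  # parent not a vertex
        ],
    )
    def test_malformed_rejected(self, root, parent):
        with pytest.raises(TreeError):
            NodeTree(root, parent)

    def test_empty_labels_rejected(self):
        with pytest.raises(TreeError):
            NodeTree("")

    def test_duplicate_children_listing_rejected(self):
        with pytest.raises(TreeError):
            NodeTree.from_children("r", {"r": ["a"], "x": ["a"]})


class TestAncestryQueries:
    @pytest.mark.parametrize(
        "v,expected", [("8", "4"), ("4", "2"), ("2", "1"), ("1", None), ("B", None)]
    )
    def test_parent(self, fig3_node, fig1_node, v, expected):
        tree = fig3_node if v.isdigit() else fig1_node
        if v == "B":
            assert fig1_node.parent("B") == "y"
        else:
            assert tree.parent(v) == expected

    def test_parent_unknown_label(self, fig3_node):
        with pytest.raises(LabelNotFoundError):
            fig3_node.parent("nope")

    @pytest.mark.parametrize(
        "v,expected",
        [("8", ["4", "2", "1"]), ("1", []), ("5", ["2", "1"]), ("3", ["1"])],
    )
    def test_ancestors(self, fig3_node, v, expected):
        assert fig3_node.ancestors(v) == expected

    def test_ancestors_on_five_taxon_tree(self, fig1_node):
        assert fig1_node.ancestors("C") == ["y", "z"]

    @pytest.mark.parametrize(
        "x,y,expected",
        [("8", "1", ["4", "2", "1"]), ("8", "4", ["4"]), ("2", "1", ["1"])],
    )
    def test_lineage(self, fig3_node, x, y, expected):
        assert fig3_node.lineage(x, y) == expected

    def test_lineage_requires_ancestor(self, fig3_node):
        with pytest.raises(NotAnAncestorError):
            fig3_node.lineage("8", "3")
        with pytest.raises(NotAnAncestorError):
            fig3_node.lineage("8", "8")  # a vertex is not its own ancestor

    @pytest.mark.parametrize(
        "taxa,expected",
        [
            ({"8", "9"}, "4"),
            ({"4", "5", "8", "9"}, "2"),
            ({"5"}, "5"),
            ({"8", "6"}, "1"),
            ({"2", "4"}, "2"),  # the YCA may belong to the query set
        ],
    )
    def test_youngest_common_ancestor(self, fig3_node, taxa, expected):
        assert fig3_node.youngest_common_ancestor(taxa) == expected

    def test_yca_empty_query(self, fig3_node):
        with pytest.raises(EmptyQueryError):
            fig3_node.youngest_common_ancestor([])

    @pytest.mark.parametrize(
        "v,expected",
        [
            ("2", {"4", "5", "8", "9"}),
            ("9", set()),
            ("1", {"2", "3", "4", "5", "6", "7", "8", "9"}),
        ],
    )
    def test_descendants(self, fig3_node, v, expected):
        assert fig3_node.descendants(v) == expected


class TestNodeSubtrees:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ("2", {"2", "4", "5", "8", "9"}),
            ("9", {"9"}),
            ("1", {"1", "2", "3", "4", "5", "6", "7", "8", "9"}),
        ],
    )
    def test_proper_subtree(self, fig3_node, v, expected):
        ref = fig3_node.proper_subtree(v)
        assert ref.model == "node" and ref.elements == frozenset(expected)

    @pytest.mark.parametrize(
        "taxa,expected",
        [
            ({"4", "5", "8", "9"}, False),
            ({"2", "4", "5", "8", "9"}, True),
            ({"7"}, True),
            ({"1", "3", "6", "7"}, True),
            ({"8", "6"}, False),
        ],
    )
    def test_is_subtree(self, fig3_node, taxa, expected):
        assert fig3_node.is_subtree(taxa) is expected

    def test_is_subtree_matches_graph_connectivity_oracle(self):
        """Induced-subgraph connectivity on all subsets of small random trees."""
        for seed in range(5):
            tree = random_tree(7, seed)
            g = nx.Graph(
                (v, tree.parent(v)) for v in tree.labels if tree.parent(v)
            )
            g.add_nodes_from(tree.labels)
            labels = sorted(tree.labels)
            for r in range(1, len(labels) + 1):
                for subset in itertools.combinations(labels, r):
                    expected = nx.is_connected(g.subgraph(subset))
                    assert tree.is_subtree(subset) is expected

    def test_proper_subtree_count_equals_vertex_count(self):
        """Each vertex determines one proper subtree, and they are distinct."""
        for seed in range(100):
            tree = random_tree(1 + seed % 12, seed)
            refs = {tree.proper_subtree(v).elements for v in tree.labels}
            assert len(refs) == tree.n_vertices


class TestStemTree:
    def test_planted_enforced(self):
        with pytest.raises(NotPlantedError):
            StemTree(0, {"a": (0, 1), "b": (0, 2)})

    def test_junction_edge_balance(self, fig3_stem):
        assert fig3_stem.n_junctions == fig3_stem.n_edges + 1 == 10

    def test_root_edge(self, fig3_stem, fig1_stem):
        assert fig3_stem.root_edge == "1"
        assert fig1_stem.root_edge == "z"

    def test_equality_ignores_junction_names(self):
        a = StemTree(0, {"r": (0, 1), "x": (1, 2), "y": (1, 3)})
        b = StemTree("top", {"r": ("top", "s"), "y": ("s", "u"), "x": ("s", "v")})
        assert a == b and hash(a) == hash(b)

    @pytest.mark.parametrize(
        "e,expected",
        [
            ("2", {"2", "4", "5", "8", "9"}),
            ("9", {"9"}),
            ("1", {"1", "2", "3", "4", "5", "6", "7", "8", "9"}),
        ],
    )
    def test_planted_proper_subtree(self, fig3_stem, e, expected):
        ref = fig3_stem.planted_proper_subtree(e)
        assert ref.elements == frozenset(expected)
        assert ref.planted is True

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({"4", "5", "8", "9"}, (True, False)),  # proper but non-planted
            ({"2", "4", "5", "8", "9"}, (True, True)),
            ({"8", "9"}, (True, False)),  # sibling terminal edges share a junction
            ({"8", "6"}, (False, False)),
            ({"7"}, (True, True)),
        ],
    )
    def test_is_subtree(self, fig3_stem, edges, expected):
        assert fig3_stem.is_subtree(edges) == expected

    def test_unknown_edge_label(self, fig3_stem):
        with pytest.raises(LabelNotFoundError):
            fig3_stem.planted_proper_subtree("zzz")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(n=st.integers(1, 20), seed=st.integers(0, 2**31 - 1))
def test_vertex_edge_balance_property(n, seed):
    """Every constructed rooted tree has one more vertex than edges."""
    tree = random_tree(n, seed)
    assert tree.n_vertices == tree.n_edges + 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(n=st.integers(2, 20), seed=st.integers(0, 2**31 - 1), data=st.data())
def test_ancestor_and_yca_properties(n, seed, data):
    """A vertex never lists itself as an ancestor; the YCA of a pair sits on
    both ancestor-or-self chains."""
    tree = random_tree(n, seed)
    labels = sorted(tree.labels)
    v = data.draw(st.sampled_from(labels))
    w = data.draw(st.sampled_from(labels))
    assert v not in tree.ancestors(v)
    yca = tree.youngest_common_ancestor({v, w})
    assert yca in tree.ancestors(v) + [v]
    assert yca in tree.ancestors(w) + [w]
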