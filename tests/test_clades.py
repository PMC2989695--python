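"""Clade extraction and mono-/para-/polyphyly classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemnode import (
    CladeClassification,
    classify,
    classify_on_stem,
    diagnose_misapplication,
    node_clade,
    node_to_stem,
    random_tree,
    stem_clade,
)

MONO = CladeClassification.MONOPHYLETIC
PARA = CladeClassification.PARAPHYLETIC
POLY = CladeClassification.POLYPHYLETIC


class TestCladeExtraction:
    @pytest.mark.parametrize(
        "v,expected",
        [("2", set("24589")), ("9", {"9"}), ("1", set("123456789"))],
    )
    def test_node_clade(self, fig3_node, v, expected):
        assert node_clade(fig3_node, v) == frozenset(expected)

    @pytest.mark.parametrize("e,expected", [("2", set("24589")), ("7", {"7"})])
    def test_stem_clade(self, fig3_stem, e, expected):
        assert stem_clade(fig3_stem, e) == frozenset(expected)

    def test_every_clade_is_monophyletic(self, fig3_node, fig3_stem):
        for v in fig3_node.labels:
            assert classify(fig3_node, node_clade(fig3_node, v)) is MONO
            assert classify_on_stem(fig3_stem, stem_clade(fig3_stem, v)) is MONO


class TestClassification:
    @pytest.mark.parametrize(
        "taxa,expected",
        [
            (set("4589"), POLY),  # excludes its own common ancestor 2
            (set("1367"), PARA),  # includes root 1 but only one child lineage
            (set("24589"), MONO),  # vertex 2 plus all its descendants
            (set("123456789"), MONO),
            ({"6"}, MONO),  # a terminal taxon is its own one-taxon clade
            ({"3"}, PARA),  # an ancestral taxon alone excludes its descendants
            ({"8", "6"}, POLY),
        ],
    )
    def test_verdicts(self, fig3_node, fig3_stem, taxa, expected):
        assert classify(fig3_node, taxa) is expected
        assert classify_on_stem(fig3_stem, taxa) is expected

    def test_polyphyly_iff_yca_excluded_all_subsets(self, fig3_node):
        """Brute force over all 511 subsets of the nine-taxon tree."""
        labels = sorted(fig3_node.labels)
        for r in range(1, 10):
            for subset in itertools.combinations(labels, r):
                s = set(subset)
                verdict = classify(fig3_node, s)
                yca = fig3_node.youngest_common_ancestor(s)
                assert (verdict is POLY) == (yca not in s)
                if verdict is MONO:
                    assert s == fig3_node.descendants(yca) | {yca}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(n=st.integers(1, 16), seed=st.integers(0, 2**31 - 1), data=st.data())
def test_classification_is_model_independent(n, seed, data):
    """The verdict depends on the phylogeny, not the model drawn."""
    t = random_tree(n, seed)
    u = node_to_stem(t)
    labels = sorted(t.labels)
    subset = data.draw(
        st.sets(st.sampled_from(labels), min_size=1, max_size=len(labels))
    )
    assert classify(t, subset) is classify_on_stem(u, subset)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(n=st.integers(1, 16), seed=st.integers(0, 2**31 - 1))
def test_clade_name_synonymy(n, seed):
    """Vertex-anchored and edge-anchored clades name the same taxon sets."""
    t = random_tree(n, seed)
    u = node_to_stem(t)
    node_names = {node_clade(t, v) for v in t.labels}
    stem_names = {stem_clade(u, e) for e in u.labels}
    assert node_names == stem_names


class TestMisapplication:
    def test_node_definition_on_stem_tree(self, fig3_stem):
        """Anchoring at the speciation event atop edge 2 selects the
        non-planted edge set {4,5,8,9}, which is polyphyletic."""
        report = diagnose_misapplication(fig3_stem, "node", anchor="2")
        assert report.mismatch
        assert report.selected == frozenset("4589")
        assert report.classification is POLY

    def test_stem_definition_on_node_tree(self, fig3_node):
        """The would-be root edge 1->3 is not a graph without vertex 1;
        omitting it leaves the well-defined monophyletic node clade at 3."""
        report = diagnose_misapplication(fig3_node, "stem", anchor="3")
        assert report.mismatch
        assert "not a graph" in report.message
        assert report.selected == frozenset("367")
        assert report.classification is MONO

    def test_matching_model_is_empty_report(self, fig3_node, fig3_stem):
        assert not diagnose_misapplication(fig3_node, "node").mismatch
        assert not diagnose_misapplication(fig3_stem, "stem").mismatch

    def test_terminal_anchor_on_stem_tree(self, fig3_stem):
        report = diagnose_misapplication(fig3_stem, "node", anchor="9")
        assert report.mismatch and report.selected == frozenset()

    def test_report_serializes(self, fig3_stem):
        d = diagnose_misapplication(fig3_stem, "node", anchor="2").to_dict()
        assert d["classification"] == "polyphyletic"
        assert d["selected"] == ["4", "5", "8", "9"]
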