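# stemnode

Rooted phylogenies are drawn in two superficially similar but mathematically
distinct ways. In a **node-based** tree, taxa sit on the vertices and each
edge asserts an ancestry relation between two taxa: internal vertices are
ancestral taxa — unsampled, but inferred. In a **stem-based** (branch-based)
tree, taxa are the *edges* — lineages extended in time — and the vertices are
speciation events; every stem-based tree is *planted*, meaning its root
vertex has exactly one child edge, the common ancestor of everything sampled.

The two models carry identical information. `stemnode` makes that equivalence
operational for systematists and for anyone teaching or testing clade
semantics:

* first-class `NodeTree` and `StemTree` types with ancestry queries
  (parent, ancestors, lineage, youngest common ancestor, descendants) and
  subtree predicates, polytomies included;
* the explicit conversion in both directions: a rooted tree *T* on *n*
  labeled vertices corresponds to the planted tree *U* on *n*+1 vertices
  whose *n* edges carry the same labels (add an unnamed planted root above
  root(*T*), label each edge by its child vertex, forget vertex names — and
  the exact reverse);
* clade extraction and **mono-/para-/polyphyly** classification on either
  model: for a taxon set *S* with youngest common ancestor *a*, *S* is
  monophyletic iff *S* = {*a*} ∪ descendants(*a*), paraphyletic iff *a* ∈ *S*
  but some descendants are missing, polyphyletic iff *a* ∉ *S*;
* diagnostics for the characteristic mistake of applying a node-based clade
  definition to a stem-based tree (or vice versa): the vertex-anchored
  subtree of a stem tree is proper but *non-planted*, and the taxon set it
  selects is not monophyletic;
* an exhaustive enumerator of small labeled trees that certifies the model
  equivalence by independent counting: for every *n*, both collections have
  exactly *n*^(*n*−1) members (Cayley), and the conversion is a verified
  bijection;
* strict two-mode Newick I/O — one grammar, two interpretations chosen by an
  explicit flag, canonical deterministic output, branch lengths rejected
  rather than ignored.

## Worked example

```python
>>> import stemnode as sn
>>> t = sn.read_newick("(((8,9)4,5)2,(6,7)3)1;", "node")   # nine taxa, 1 = root
>>> u = sn.node_to_stem(t)
>>> sn.write_newick(u, "stem")                # same string, other model
'(((8,9)4,5)2,(6,7)3)1;'
>>> u.is_subtree({"4", "5", "8", "9"})        # a subtree of U, but not planted
(True, False)
>>> t.is_subtree({"4", "5", "8", "9"})        # ... and not a subtree of T at all
False
>>> sn.classify(t, {"4", "5", "8", "9"}).value  # excludes its own YCA (taxon 2)
'polyphyletic'
>>> sn.classify(t, {"2", "4", "5", "8", "9"}).value
'monophyletic'
>>> sn.classify(t, {"1", "3", "6", "7"}).value  # keeps the YCA, drops lineage 2
'paraphyletic'
>>> sn.certify_bijection(3)
{'n': 3, 'node_tree_count': 9, 'stem_tree_count': 9, 'bijection': True, 'expected_cayley': 9}
```

The edge set {4,5,8,9} hangs together in the stem model (the four lineages
share speciation events) yet the same labels are disconnected as vertices of
the node model — the shape of the error made when a node-based name is
applied to a stem-based tree. Adding the common-ancestor lineage 2 restores
a planted subtree, and with it monophyly.

The same operations are available from a shell:

```sh
$ stemnode classify --in tests/data/fig3.nwk --model node --taxa 4,5,8,9
polyphyletic (youngest common ancestor: 2)
$ stemnode certify --n 4
{
  "bijection": true,
  "expected_cayley": 64,
  "n": 4,
  "node_tree_count": 64,
  "stem_tree_count": 64
}
```

(`convert`, `clade`, `check` and `diagnose` complete the command set; see
`stemnode --help`.)

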