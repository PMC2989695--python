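# Methods

## The two tree models

A rooted tree with `n` edges has `n + 1` vertices; every non-root vertex has
exactly one parent, and the root, none. On this shared skeleton the package
builds two interpretations of a phylogeny:

* **Node-based** (`NodeTree`): taxa are vertices, edges are is-parent-of
  hypotheses. Stored as a root label plus a child → parent map; the
  constructor verifies acyclicity and connectivity by walking every parent
  chain to the root, so the vertex/edge balance holds for every instance by
  construction.
* **Stem-based** (`StemTree`): taxa are edges, vertices ("junctions") are
  speciation events. Stored as a root junction plus a
  `label → (tail, head)` edge map. Junction identifiers are arbitrary
  hashable values with no biological meaning and are never serialized;
  equality and hashing go through a canonical nested form that forgets
  them. Every stem tree is *planted* — root junction with exactly one child
  edge — and this is enforced at construction, so no downstream operation
  needs to re-check it.

Taxon labels are arbitrary non-empty strings, not integers: the `1..n`
numbering used in worked examples is a mathematical convenience, while real
trees carry taxon names. Polytomies are supported everywhere; nothing in the
package assumes or checks binarity. Child order is semantically ignored; a
canonical order (children sorted lexicographically by the sorted tuple of
their subtree's labels) is imposed only for serialization and equality.
Branch lengths, unrooted trees and reticulate networks are out of scope — a
tree in this sense cannot model reticulation.

## Conversion

Node → stem: create a fresh planted root junction above the old root taxon,
join them with a new edge, label every edge by the taxon at its young end,
and drop vertex names. The ephemeral label a textbook construction would put
on the new root is represented here by an unnamed sentinel junction, so it
can never collide with user data. Stem → node reverses this exactly: each
non-root junction takes its parent edge's name, the planted root and root
edge are deleted, the root edge's label becomes the root taxon. Both
compositions are identities, and the edge-label set of one model always
equals the vertex-label set of the other.

The correspondence extends to subtrees with one asymmetry that is the
package's central teaching point: the proper subtree of `T` rooted at taxon
`v` and the planted proper subtree of `U` hanging from edge `v` have the
same label set, but a *non-planted* stem subtree has no node-model
counterpart — its labels do not induce a connected subgraph of `T`.
`corresponding_subtree` therefore returns a `CorrespondenceUndefined`
diagnostic value for that case rather than raising: callers (the clades
module and the `diagnose` command) need to report the failure, not crash on
it.

Character annotations (apomorphies) are per-taxon multisets; position along
a lineage is deliberately not representable because it carries no meaning in
the model. Translation between models is label-identity, validated against
both trees rather than transformed.

## Clade classification

For a non-empty taxon set `S` on a node tree with `a = YCA(S)`:

* monophyletic ⇔ `S = {a} ∪ descendants(a)` (the ancestor is a member,
  following Hennig);
* paraphyletic ⇔ `a ∈ S` but some descendants of `a` are missing;
* polyphyletic ⇔ `a ∉ S`.

The para/poly split by YCA membership is a design choice where usage in the
literature is loose: it reproduces the classical verdicts on the reference
tree (a group of four cousins excluding their common ancestor is
polyphyletic; a group keeping the root but dropping a whole child lineage is
paraphyletic) and it does **not** require a paraphyletic set to induce a
connected subgraph — paraphyly is about missing descendants, not about
drawing. Ancestral (internal, unsampled) taxa are first-class members of
query sets. Classification on a stem tree delegates through the conversion,
since the verdict is a property of the phylogeny rather than of the model
chosen to draw it; a property test checks model-independence on random
trees.

`lineage(x, y)` returns the ancestors of `x` down to and including `y`,
excluding `x` itself — the definition leaves the inclusion of `x` ambiguous,
and excluding it keeps `lineage(x, root)` equal to `ancestors(x)`.

## Enumeration as an oracle

The model equivalence is certified by counting rather than trusted. Node
trees on `n` labels are generated bijectively: Prüfer sequences give each
free labeled tree exactly once (`n^(n-2)`), and each is rooted at every
vertex, totalling `n^(n-1)`. Stem trees are generated *independently of the
conversion code*: junction skeletons are the free trees on `n + 1` junctions
in which the designated planted root is a leaf (Prüfer sequences avoiding
it), each skeleton is crossed with all `n!` assignments of labels to edges,
and duplicates — the same tree under a different junction numbering — are
removed by canonical form. Agreement of the two counts, injectivity of the
conversion, exactness of its image and both round-trip identities are then
checked tree by tree.

Hard size guards raise explicit errors instead of silently truncating:
enumeration accepts `n ≤ 7`, the double-enumeration certificate `n ≤ 5`
(the factorial labeling sweep dominates beyond that), and the all-subsets
subtree certificate trees of ≤ 12 vertices. Certification at `n ≤ 5`
(1, 2, 9, 64, 625 trees per collection) runs in about a second; the point
is exhaustiveness at small sizes, where a counterexample to the claimed
bijection would have to appear if the algebra were wrong.

## Newick dialect

One grammar, two interpretations, selected by an explicit `mode` flag and
never guessed from content — silent guessing would recreate exactly the
model confusion the package exists to dispel. Node mode requires a label on
every vertex, internal and root included, because internal vertices are
taxa. Stem mode reads each token in label position as the name of the edge
above that syntactic node; the topmost junction is implicit and unlabeled,
so a string whose outermost group carries no label describes several edges
hanging under the implicit root and is rejected as not planted.

Anything following `:` (branch lengths, and with them support-value
notation) is a hard error rather than being consumed: a bare number in
label position is ambiguous between a taxon name and a support value, and
in this dialect it is always a label — which also lets the `1..9` reference
tree round-trip. Labels containing structural characters or whitespace are
single-quoted with `''` escaping. Output is canonical (children in the
label-multiset order above), so read∘write is bit-exact and corresponding
node and stem trees serialize to character-identical strings. Syntax errors
report a 0-based character offset.

Annotation tables are two-column TSV (`taxon<TAB>id1,id2,...`); duplicate
taxon rows merge as multisets, malformed lines report their line number,
`#` lines are comments.

## Random-tree generator

`random_tree(n, seed)` draws uniformly over all `n^(n-1)` rooted labeled
trees — a uniform Prüfer sequence for the free tree and an independent
uniform root — and is a pure function of `(n, seed, model)`. It emulates
topology only: labels are synthetic integers, there are no branch lengths,
and no model of diversification shapes the distribution (a uniform labeled
tree is not a Yule or coalescent tree). Tests passing on it therefore
establish combinatorial correctness of the structural claims on arbitrary
shapes, including heavy polytomies and linear chains; they say nothing
about inference from data, which is out of scope throughout. A chi-square
test at `n = 3` (10⁴ draws over the 9 shapes) guards the uniformity claim.

## Problem sizes

Defaults used by the test suite and the reproduction script, chosen to make
the certificates exhaustive where exhaustiveness is the argument and broad
where sampling is: bijection certificates at `n = 1..5`; 500 random trees up
to 64 taxa for conversion round trips; all `2^n − 1` subsets on the 9-taxon
reference tree and 200 random trees of up to 10 vertices for the subtree
correspondence; 200 random trees each for synonymy and Newick determinism.
The whole suite runs in a few seconds on one CPU.

## Known limitations

* No branch lengths or divergence times; an edge is a hypothesis, not a
  duration.
* No reticulations, and no unrooted trees — rootedness is what defines the
  ancestry relations both models depend on.
* Apomorphy-based clade definitions, crown-clade machinery and nomenclatural
  registration are not modeled; annotations attach characters to lineages
  but no inference is performed on them.
* The reference figures are reconstructions from their textual descriptions
  (the drawings themselves are not machine-readable); tests assert only the
  documented structural claims, and the character placements not pinned by
  text are labeled as reconstructed in the fixture docstrings.
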