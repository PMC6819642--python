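# Methods

## Data model

A dendrogram is a rooted tree with branch lengths, read from a single
`;`-terminated Newick statement. Every node carries a *height*: its
distance down to the leaves, computed as the maximum over descendant leaves
of the summed branch lengths on the way down. For ultrametric trees — the
normal output of agglomerative clustering, where all root-to-leaf path
lengths agree — height is exactly the merge distance. Non-ultrametric
input is accepted; the max-over-descendants rule keeps heights monotone
from leaves to root, so the distance-threshold semantics degrade gracefully
rather than failing. Negative branch lengths are rejected; missing ones
default to 0, and the root's branch length is always treated as 0.

Newick parsing is delegated to Biopython's reader, which satisfies the
strictness this application needs: unquoted underscores are kept verbatim,
quoted labels are taken as-is (replicate suffixes must survive exactly),
duplicate full leaf names are tolerated (with a warning — matching operates
on sample types, not full names), and internal-node names or numeric
support values are preserved but ignored by every algorithm. A light
pre-scan of parenthesis/quote balance reports the character offset of
structural errors. Serialization emits children in stored order with
12 significant digits, giving byte-deterministic output and round-trip
error far below the 1e-9 tolerance the tests assert.

Leaf names decompose at the **last** occurrence of the delimiter (default
`.`) into sample type and replicate indicator, so dotted type names like
`iris.setosa.5` work. A name without the delimiter is a bare type with no
replicate indicator; two equal bare names count as two replicates of that
type. Replicate indicators are display-only — no algorithm reads them.

## Canonical labels and the three relaxation levels

Cluster equivalence is decided by equality of canonical text labels built
in one post-order pass. Two boolean knobs select the level:
keep_structure ∧ keep_duplicates → bio-isomorphic;
¬keep_structure ∧ keep_duplicates → re-arranged;
neither → contained. The fourth combination (structure kept, duplicates
dropped) is representable in the grammar but not a defined level; the mode
constructor rejects it.

The bio-isomorphic label is `"(" + ",".join(sorted(child labels)) + ")"`
with leaves labelled by sample type. Sorting the children makes the string
a canonical form of the replicate-blind topology: equality is invariant to
sibling order and replicate placement but sensitive to any true topology
change. The re-arranged and contained labels are the sorted type multiset
and type set respectively. The exact string grammar is this package's own
realization; equivalence is defined semantically, and the test suite checks
label equality against independent brute-force predicates (recursive
isomorphism over child permutations; direct multiset/set comparison) on all
subtree pairs of random fixtures.

The distance threshold applies to a node's **own** height: nodes above it
get no label and are excluded from matching, but their descendants at or
below the threshold remain matchable — the threshold excludes nodes, not
subtrees. Leaves are labelled for composition but never returned as match
candidates (the minimum cluster size of ≥ 2 excludes them anyway). Each
node is processed exactly once; an instrumentation counter exposes this and
the tests assert it.

## Matching

For each pair of consecutive dendrograms (strictly pairwise, no transitive
multi-way matching), the source tree is walked top-down. An eligible
cluster — internal, at or below the source threshold, with at least the
minimum cluster size of leaves — searches the target and, on success,
recursion stops below it: reported source nodes are mutually non-nested and
as high as possible. On failure the children are searched and results
concatenated.

The target search scans breadth-first from the target root and returns the
minimum-depth eligible node with an equal label. Among equally-shallow
candidates the tie breaks on the lexicographically smallest sorted
leaf-name list rather than sibling position. This choice matters: a
left-to-right tie-break would make the reported match depend on child
order, and the package guarantees that display operations (flips, sorting)
never change match results. The scan stops one level below the first hit,
so the work stays within the n×m comparison bound that a second counter
exposes.

Each source cluster searches the target independently; a target node may
serve several source clusters. The alternative — consuming each matched
target so links are one-to-one — was implemented and rejected: it breaks
the relaxation hierarchy, because an earlier source cluster can consume the
only equally-labelled target and leave a stricter-mode match with nowhere
to persist under relaxation. Without consumption the hierarchy is
unconditional: a cluster matched bio-isomorphically is matched (at the same
node or an ancestor) under re-arranged, and likewise re-arranged →
contained, since relaxing only coarsens labels and the recursion reaches
the same source node unless an ancestor matched first.

### Parameters

* **Minimum cluster size** (global): leaves a cluster needs to be a match
  candidate. Floor 2 (enforced); default 3, a typical replicate count in
  small designed panels.
* **Distance threshold** (per dendrogram): height, measured from the
  leaves, above which nodes are excluded. Default: half the root height.
  The CLI accepts absolute distances (`1.25`) or fractions of each root
  height (`0.4f`).
* **Replicate delimiter**: default `.`, configurable
  (`--replicate-delimiter`).

### Branch highlighting

Inside a match the two subtrees are descended in parallel. At each paired
node, children are first paired greedily by equal bio-isomorphic canonical
label (regardless of the match's own mode); such a pair is bio-isomorphic
throughout, so both subtrees are marked *equal* wholesale. Leftover
children are paired greedily by largest sample-type overlap (ties by
position) and descended with their top edges marked *different*; wholly
unpaired children contribute all their edges as different. The result is a
disjoint partition of both subtrees' edges, and a bio-isomorphic match
comes out all-equal. The overlap-based leftover pairing is this package's
concretization (no published criterion exists); it was chosen over
positional pairing so that identical substructure buried inside differing
contexts — e.g. the same two-replicate cherry wired elsewhere — is still
reported equal.

## Display operations

Horizontal flip toggles an orientation flag; subtree flip reverses one
node's child order; neither touches heights or labels. Sorting orders each
node's children to minimize the number of leaf pairs left out of
alphabetical order across sibling blocks. Because cross-block inversions
depend only on the blocks' leaf sets, this per-node choice is globally
optimal for binary trees (verified exhaustively in tests on ≤ 8-leaf
trees); ties break on each block's smallest leaf name, which makes the sort
idempotent. A simpler smallest-leaf-name keying was considered and
rejected because it is not always inversion-minimal (e.g. blocks
{A, Z, Z′} vs {B}). Only sibling order changes, so the cluster set is
preserved and no line crossings can appear. All three operations leave
label maps and match results invariant; the tie-break design above is what
makes the match-invariance exact.

## Rendering

The SVG renderer is deliberately primitive-deterministic: plain text
assembly with fixed two-decimal coordinates, so identical inputs give
byte-identical files. Panels are laid out left to right in input order;
the tallest dendrogram fixes the panel height at a fixed per-leaf spacing
(default 18 px). Each panel shows a title, rectangular-elbow branches
(x proportional to height), leaf labels with a small replicate-indicator
glyph, a 5-tick distance axis and a dashed threshold marker. Matches are
translucent connectors between the two cluster roots, one color per match
from a fixed 10-color categorical palette (cycling beyond 10); equal or
different branches are restroked in the match color when highlighting is
on. Orientation flips mirror a panel's x-axis.

## Synthetic fixtures

The generator emulates clustering output for a replicated design: leaves
`type01.1 … typeNT.R`, merged pairwise at uniformly drawn heights sorted
ascending, giving a binary, ultrametric tree with strictly monotone merge
heights, byte-reproducible from one seed. Defaults are 4 types in
triplicate (12 leaves). The three perturbations return a partner tree in a
known relation at the perturbed cluster: swapping two same-type leaves
(bio-isomorphic; labels untouched), regrafting a leaf within its cluster
multiset-preservingly with retries until the canonical form actually
changes (re-arranged, not bio-isomorphic), and deleting a replicate of a
type with multiplicity ≥ 2, suppressing the unary node (contained, not
re-arranged).

What the fixtures do **not** emulate: noise in branch lengths shared
between the two trees of a pair (independent random pairs have unrelated
heights), non-binary merges, bootstrap support values, and the scale of
real expression matrices. Passing tests therefore demonstrate correctness
of the combinatorial machinery on clustering-shaped trees, not robustness
of any upstream clustering.

## Problem sizes and determinism

Randomized tests and the acceptance script use 200 tree pairs of 4–15
leaves (types × replicates drawn from {2..5} × {2,3}), where brute-force
oracles — exhaustive enumeration over all subtree pairs, isomorphism by
child permutations — are exact and fast; on binary trees this size already
exercises every code path (ties, duplicate labels, threshold exclusion).
All randomness flows from explicit integer seeds; the acceptance script
derives all of its streams from `--seed`.

## Known limitations

* One tree per Newick file; NEXUS/PhyloXML, rerooting and multifurcation
  resolution are out of scope (multifurcations are handled where they
  occur, but never created or resolved).
* Matching is pairwise-consecutive only; there is no globally optimal
  bipartite assignment, no similarity score between whole dendrograms, and
  no significance statistics for matches.
* Labels compare exactly; there is no fuzzy matching and branch lengths
  inside a cluster never enter the labels.
* The report's equal/different edge counts depend on the highlight
  alignment heuristic described above for non-bio-isomorphic matches.
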