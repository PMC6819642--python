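# dendromatch

Replicate-aware comparison of hierarchical-clustering dendrograms.

## The problem

Hierarchical clustering of replicated biological samples — triplicate
toxicogenomics assays, repeated flower measurements, any design where each
*sample type* is measured several times — yields dendrograms whose leaves
carry names like `versicolor.1`, `versicolor.2`: a type plus a replicate
indicator. Two clustering runs (different linkage, different feature sets,
different normalizations) rarely produce identical trees, yet many of their
differences carry no biological meaning: two replicates of the same type
trade places, a subcluster is wired differently, one replicate is missing.
Classical tree-comparison tools treat leaves as uniquely identifiable and
flag all of these as differences.

`dendromatch` compares an ordered series of rooted, leaf-labelled Newick
trees pairwise and reports clusters that are equivalent under three
progressively relaxed notions of similarity:

| mode | topology | per-type counts | type set |
|---|---|---|---|
| **bio-isomorphic** | equal | equal | equal |
| **re-arranged** | free | equal | equal |
| **contained** | free | free | equal |

## Method

Leaf names are split at the last delimiter (default `.`) into
(sample type, replicate id); only the types enter the comparison. Each
internal node of height ≤ *t* (the per-dendrogram distance threshold,
measured from the leaves; default half the root height) receives a
canonical label in a single post-order pass:

* bio-isomorphic: `"(" + sorted(child labels) + ")"`, leaves labelled by
  type — sorting makes the label invariant to child order and replicate
  placement, so label equality is exactly bio-isomorphism;
* re-arranged: the sorted multiset of descendant-leaf types;
* contained: the sorted set of descendant-leaf types.

Matching then walks the source dendrogram top-down; an eligible cluster
(≥ *s* leaves, default *s* = 3, minimum 2) searches the target breadth-first
and links to the shallowest equally-labelled eligible cluster. Recursion
stops below a matched node, so matches are reported at the highest possible
level. Labeling is O(n) for binary trees and the whole search is O(n·m) in
the worst case. Within a match, branches that agree between the two
subtrees can be highlighted via a parallel descent that aligns children by
canonical label.

The library also provides display operations (horizontal flip, subtree
flip, best-fit alphabetical leaf sorting that never changes the clustering),
a deterministic SVG renderer with match connectors and per-match colors, and
a generator of synthetic ultrametric fixture trees with controlled
bio-isomorphic / re-arranged / contained perturbations.

## Worked example

Two 5-leaf clusterings of the same iris-style samples that disagree only in
how the versicolor/virginica subcluster is wired:

```sh
cat > average.nwk <<'EOF'
(((versicolor.1:0.3,(versicolor.3:0.1,versicolor.4:0.1):0.2):0.2,virginica.2:0.5):0.3,versicolor.2:0.8);
EOF
cat > complete.nwk <<'EOF'
((((versicolor.3:0.15,versicolor.4:0.15):0.2,virginica.2:0.35):0.15,versicolor.2:0.5):0.3,versicolor.1:0.8);
EOF
dendromatch compare --input average.nwk --input complete.nwk \
    --mode rearranged --threshold 1.0f --threshold 1.0f \
    --highlight equal --out-svg comparison.svg
```

prints

```
# dendromatch report
# mode=rearranged min_cluster_size=3
# dendrogram title=average leaves=5 root_height=0.8 threshold=0.8
# dendrogram title=complete leaves=5 root_height=0.8 threshold=0.8
pair=0->1	mode=rearranged	color=0	source=versicolor.1,versicolor.3,versicolor.4,virginica.2,versicolor.2	target=versicolor.3,versicolor.4,virginica.2,versicolor.2,versicolor.1	equal_edges=8	different_edges=8
# total_matches=1
```

One match: the full 5-leaf cluster (4 versicolor + 1 virginica replicates)
is re-arranged-equivalent between the two trees — same members, different
wiring — so it would *not* match in `--mode bio-isomorphic` (try it: the
report shows `total_matches=0`). Of the 16 branches inside the two matched
subtrees, 8 are equal (among them the identical
`versicolor.3`/`versicolor.4` cherry, highlighted in the match color in
`comparison.svg`) and 8 differ — the point where the two linkage choices
disagree. Thresholds are given as fractions of each root height (`1.0f`
opens the whole tree; bare numbers are absolute distances).

Synthetic trees for experimentation:

```sh
dendromatch fixtures --n-types 4 --replicates 3 --seed 7 --pair rearranged --out-dir demo/
```

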