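"""Independent brute-force oracles used to cross-check the implementation.

Nothing here uses the canonical-label machinery: cluster equivalence is
decided by direct structural/multiset comparison, and matching by exhaustive
scans over all node pairs with explicitly computed traversal orders.
"""

from __future__ import annotations

from itertools import permutations

from dendromatch import Dendrogram, DendroNode, MatchMode, MatchParams
from dendromatch.replicate_model import leaf_type, type_multiset


def bio_isomorphic(a: DendroNode, b: DendroNode, delimiter: str = ".") -> bool:
    """Recursive multiset comparison of subtrees over all child pairings."""
    if a.is_leaf or b.is_leaf:
        return (a.is_leaf and b.is_leaf
                and leaf_type(a, delimiter) == leaf_type(b, delimiter))
    if len(a.children) != len(b.children):
        return False
    return any(
        all(bio_isomorphic(ca, cb, delimiter)
            for ca, cb in zip(a.children, perm))
        for perm in permutations(b.children)
    )


def clusters_equal(mode: MatchMode, a: DendroNode, b: DendroNode,
                   delimiter: str = ".") -> bool:
    if mode is MatchMode.BIO_ISOMORPHIC:
        return bio_isomorphic(a, b, delimiter)
    if mode is MatchMode.REARRANGED:
        return type_multiset(a, delimiter) == type_multiset(b, delimiter)
    return set(type_multiset(a, delimiter)) == set(type_multiset(b, delimiter))


def bfs_order(d: Dendrogram) -> list[DendroNode]:
    """Target scan order: by depth, ties by sorted leaf-name list.

    The depth part realizes the highest-level (shallowest) preference; the
    name part makes the tie-break independent of sibling order.
    """
    depth: dict[DendroNode, int] = {d.root: 0}
    for node in d.root.walk_preorder():
        for c in node.children:
            depth[c] = depth[node] + 1
    return sorted(d.root.walk_preorder(),
                  key=lambda n: (depth[n], sorted(n.leaf_names())))


def eligible(node: DendroNode, threshold: float, min_size: int) -> bool:
    return (not node.is_leaf
            and len(node.leaves()) >= min_size
            and node.height <= threshold)


def oracle_matches(source: Dendrogram, target: Dendrogram,
                   params: MatchParams) -> list[tuple[DendroNode, DendroNode]]:
    """Source-maximal equal-cluster pairs by exhaustive enumeration.

    Source nodes are taken top-down, stopping below a matched node; for each
    one every target node is tested with the direct predicate and the first
    hit in breadth-first order is taken.
    """
    src_thr = params.threshold_for(source)
    tgt_thr = params.threshold_for(target)
    tgt_nodes = bfs_order(target)
    out: list[tuple[DendroNode, DendroNode]] = []

    def visit(s: DendroNode) -> None:
        if eligible(s, src_thr, params.min_cluster_size):
            hits = [t for t in tgt_nodes
                    if eligible(t, tgt_thr, params.min_cluster_size)
                    and clusters_equal(params.mode, s, t, params.delimiter)]
            if hits:
                out.append((s, hits[0]))
                return
        for c in s.children:
            visit(c)

    visit(source.root)
    return out
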