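"""Display-only manipulations: horizontal flip, subtree flip, best-fit sort.

None of these change the clustering itself — labels and match results are
invariant under all three — they only change how the tree is drawn.
"""

from __future__ import annotations

import warnings

from .newick_io import Dendrogram, DendroNode


def flip_horizontal(d: Dendrogram) -> Dendrogram:
    """Swap the sides of root and leaves by toggling the orientation flag."""
    d.orientation = "root-right" if d.orientation == "root-left" else "root-left"
    return d


def flip_subtree(node: DendroNode) -> DendroNode:
    """Reverse the child order of ``node`` (vertical flip of its span)."""
    if node.is_leaf:
        warnings.warn(f"flip_subtree on leaf {node.name!r} is a no-op",
                      stacklevel=2)
        return node
    node.children.reverse()
    return node


def _inversions_between(left: list[int], right: list[int]) -> int:
    """Pairs (x in left, y in right) with rank(x) > rank(y) when left precedes right."""
    sorted_right = sorted(right)
    import bisect

    return sum(bisect.bisect_left(sorted_right, x) for x in left)


def sort_dendrogram(d: Dendrogram) -> Dendrogram:
    """Alphabetically sort the leaves by child reordering only (best fit).

    The set of clusters is untouched — only sibling order changes, so no
    line crossings can appear.  At every internal node the children are
    ordered to minimize the number of leaf pairs that end up out of
    alphabetical order across sibling blocks; because cross-block inversions
    depend only on the blocks' leaf sets, this per-node choice is globally
    optimal for binary trees.  Ties break on the smallest leaf name in each
    block, which also makes the operation idempotent.
    """
    rank = {name: i for i, name in
            enumerate(sorted(d.root.leaf_names()))}

    ranks: dict[DendroNode, list[int]] = {}
    min_name: dict[DendroNode, str] = {}
    for node in d.root.walk_postorder():
        if node.is_leaf:
            ranks[node] = [rank[node.name]]  # type: ignore[index]
            min_name[node] = node.name  # type: ignore[assignment]
        else:
            import functools

            def cmp(a: DendroNode, b: DendroNode) -> int:
                ab = _inversions_between(ranks[a], ranks[b])
                ba = _inversions_between(ranks[b], ranks[a])
                if ab != ba:
                    return -1 if ab < ba else 1
                return -1 if min_name[a] <= min_name[b] else 1

            node.children.sort(key=functools.cmp_to_key(cmp))
            ranks[node] = [r for c in node.children for r in ranks[c]]
            min_name[node] = min(min_name[c] for c in node.children)
    return d
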