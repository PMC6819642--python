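"""Highest-level cluster matching between consecutive dendrograms.

Given two labeled dendrograms, the matcher reports, for each eligible
cluster in the source, the shallowest equally-labeled eligible cluster in
the target.  The source is walked top-down and recursion stops at the first
(i.e. highest) matched node; the target is scanned breadth-first from its
root so the returned node is the shallowest available hit.  Two parameters
restrict the search: a per-dendrogram distance threshold (nodes whose
height, measured from the leaves, exceeds it are excluded) and a global
minimum cluster size (leaf count a cluster needs to be a candidate).

Each source cluster searches the target independently, so two source
clusters with equal labels may link to the same target node.  This keeps
the relaxation hierarchy intact: a cluster matched under a strict mode is
always still matched — at the same node or an ancestor — under a more
relaxed one, because its target cannot be taken away by a competitor.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

from .errors import ParameterError
from .labeling import ClusterLabel, MatchMode, label_nodes
from .newick_io import Dendrogram, DendroNode
from .replicate_model import DEFAULT_DELIMITER

#: minimum admissible cluster size; clusters are groups, so 2 is the floor
MIN_CLUSTER_SIZE_FLOOR = 2
#: default minimum cluster size (a typical replicate count)
DEFAULT_MIN_CLUSTER_SIZE = 3
#: default distance threshold, as a fraction of each dendrogram's root
#: height: half-way between the leaves and the root
DEFAULT_THRESHOLD_FRACTION = 0.5


@dataclass
class MatchParams:
    """Global matching parameters.

    ``thresholds`` maps a dendrogram title to an absolute distance; any
    dendrogram without an entry uses half its own root height.
    """

    mode: MatchMode = MatchMode.BIO_ISOMORPHIC
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    thresholds: dict[str, float] = field(default_factory=dict)
    delimiter: str = DEFAULT_DELIMITER

    def __post_init__(self) -> None:
        if self.min_cluster_size < MIN_CLUSTER_SIZE_FLOOR:
            raise ParameterError(
                f"minimum cluster size must be >= {MIN_CLUSTER_SIZE_FLOOR}, "
                f"got {self.min_cluster_size}")

    def threshold_for(self, d: Dendrogram) -> float:
        if d.title in self.thresholds:
            return self.thresholds[d.title]
        return d.root_height * DEFAULT_THRESHOLD_FRACTION


@dataclass(eq=False)
class ClusterMatch:
    """A matched (source cluster, target cluster) pair.

    ``equal_branches`` / ``different_branches`` partition the edges of both
    matched subtrees once :func:`highlight_branches` has run; each edge is
    identified as ``(role, child_node_id)`` with role "source" or "target".
    """

    source_node: DendroNode
    target_node: DendroNode
    mode: MatchMode
    color_index: int = 0
    equal_branches: frozenset[tuple[str, int]] = frozenset()
    different_branches: frozenset[tuple[str, int]] = frozenset()


@dataclass
class MatchStats:
    """Instrumentation for the O(n×m) complexity contract."""

    label_comparisons: int = 0
    source_nodes_visited: int = 0


def _leaf_counts(d: Dendrogram) -> dict[DendroNode, int]:
    counts: dict[DendroNode, int] = {}
    for node in d.root.walk_postorder():
        counts[node] = 1 if node.is_leaf else sum(counts[c] for c in node.children)
    return counts


def find_match(
    label: ClusterLabel,
    target: Dendrogram,
    params: MatchParams,
    consumed: set[DendroNode] | None = None,
    target_labels: dict[DendroNode, ClusterLabel] | None = None,
    leaf_counts: dict[DendroNode, int] | None = None,
    stats: MatchStats | None = None,
) -> DendroNode | None:
    """Breadth-first scan of the target for the shallowest equal label.

    Level order from the root; the returned node is the minimum-depth node
    (depth in edges from the target root) that is not in ``consumed`` (an
    optional caller-supplied exclusion set), carries an equal label (which
    already implies it is internal and at or below the target's threshold)
    and has enough leaves.  Among equally-shallow candidates the one with
    the lexicographically smallest sorted leaf-name list wins, so the choice
    does not depend on sibling order and survives display flips and sorts.
    """
    if consumed is None:
        consumed = set()
    if target_labels is None:
        target_labels = label_nodes(target, params.mode,
                                    params.threshold_for(target), params.delimiter)
    if leaf_counts is None:
        leaf_counts = _leaf_counts(target)
    queue: deque[tuple[DendroNode, int]] = deque([(target.root, 0)])
    best: tuple[int, list[str]] | None = None
    best_node: DendroNode | None = None
    while queue:
        node, depth = queue.popleft()
        if best is not None and depth > best[0]:
            break  # deeper levels cannot beat an existing hit
        lab = target_labels.get(node)
        if lab is not None:
            if stats is not None:
                stats.label_comparisons += 1
            if (node not in consumed
                    and lab.text == label.text
                    and leaf_counts[node] >= params.min_cluster_size):
                key = (depth, sorted(node.leaf_names()))
                if best is None or key < best:
                    best = key
                    best_node = node
        queue.extend((c, depth + 1) for c in node.children)
    return best_node


def find_matching_clusters(
    source: Dendrogram,
    target: Dendrogram,
    params: MatchParams,
    stats: MatchStats | None = None,
) -> list[ClusterMatch]:
    """All highest-level matches from ``source`` clusters into ``target``.

    The source is processed top-down from its root: when an eligible node
    finds a match the subtree below it is not searched further, so reported
    source nodes are mutually non-nested and as shallow as possible; when it
    does not, its children are searched recursively and the results
    concatenated.  Every source cluster searches the whole target, so a
    target node may serve several matches.
    """
    src_threshold = params.threshold_for(source)
    src_labels = label_nodes(source, params.mode, src_threshold, params.delimiter)
    tgt_labels = label_nodes(target, params.mode, params.threshold_for(target),
                             params.delimiter)
    src_counts = _leaf_counts(source)
    tgt_counts = _leaf_counts(target)
    matches: list[ClusterMatch] = []

    def visit(node: DendroNode) -> None:
        if stats is not None:
            stats.source_nodes_visited += 1
        label = src_labels.get(node)
        eligible = (label is not None
                    and src_counts[node] >= params.min_cluster_size)
        if eligible:
            hit = find_match(label, target, params,
                             target_labels=tgt_labels, leaf_counts=tgt_counts,
                             stats=stats)
            if hit is not None:
                matches.append(ClusterMatch(
                    source_node=node, target_node=hit, mode=params.mode,
                    color_index=len(matches)))
                return
        for child in node.children:
            visit(child)

    visit(source.root)
    return matches


def match_sequence(
    dendrograms: list[Dendrogram],
    params: MatchParams,
) -> list[list[ClusterMatch]]:
    """Compare consecutive pairs: k dendrograms give k−1 match lists.

    Pair (i, i+1) is compared with dendrogram i as source; color indices are
    assigned sequentially within each pair.  Matching is strictly pairwise —
    there is no transitive multi-way matching.
    """
    if len(dendrograms) < 2:
        warnings.warn("need at least two dendrograms to compare; "
                      "no matches computed", stacklevel=2)
        return []
    return [find_matching_clusters(a, b, params)
            for a, b in zip(dendrograms, dendrograms[1:])]


# ---------------------------------------------------------------------------
# branch highlighting inside a match
# ---------------------------------------------------------------------------

def _canonical(node: DendroNode, delimiter: str) -> dict[DendroNode, str]:
    """Full-subtree bio-isomorphic canonical text for every node under ``node``."""
    from .replicate_model import leaf_type

    out: dict[DendroNode, str] = {}
    for n in node.walk_postorder():
        if n.is_leaf:
            out[n] = leaf_type(n, delimiter)
        else:
            out[n] = "(" + ",".join(sorted(out[c] for c in n.children)) + ")"
    return out


def _subtree_edges(node: DendroNode, role: str,
                   include_own: bool) -> set[tuple[str, int]]:
    edges = {(role, n.id) for n in node.walk_preorder() if n is not node}
    if include_own:
        edges.add((role, node.id))
    return edges


def highlight_branches(
    match: ClusterMatch,
    delimiter: str = DEFAULT_DELIMITER,
) -> tuple[frozenset[tuple[str, int]], frozenset[tuple[str, int]]]:
    """Partition the edges of both matched subtrees into equal / different.

    The two subtrees are descended in parallel from their matched roots.  At
    each paired node the children are greedily paired by equal bio-isomorphic
    canonical label (each child consumed once); a label-equal pair is
    bio-isomorphic throughout, so its entire two subtrees (including the
    edges above the paired children) are marked equal.  Leftover children are
    paired greedily by largest sample-type overlap (ties broken by position)
    and descended further with their top edges marked different, so shared
    substructure buried inside differing contexts is still found; children
    with no partner at all contribute all their edges as different.  Bio-isomorphic labels are used for this within-match
    alignment regardless of the match's own mode; for a bio-isomorphic match
    every edge therefore comes out equal.

    The result is stored on ``match`` and returned.
    """
    from .replicate_model import type_multiset

    canon_s = _canonical(match.source_node, delimiter)
    canon_t = _canonical(match.target_node, delimiter)
    equal: set[tuple[str, int]] = set()
    diff: set[tuple[str, int]] = set()

    def walk(a: DendroNode, b: DendroNode) -> None:
        unused_b = list(b.children)
        leftovers_a: list[DendroNode] = []
        for ca in a.children:
            partner = next((cb for cb in unused_b
                            if canon_s[ca] == canon_t[cb]), None)
            if partner is not None:
                unused_b.remove(partner)
                equal.update(_subtree_edges(ca, "source", include_own=True))
                equal.update(_subtree_edges(partner, "target", include_own=True))
            else:
                leftovers_a.append(ca)
        # pair leftovers by descending sample-type overlap, position on ties
        scored = sorted(
            ((-sum((type_multiset(ca, delimiter)
                    & type_multiset(cb, delimiter)).values()), ia, ib)
             for ia, ca in enumerate(leftovers_a)
             for ib, cb in enumerate(unused_b)),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, ia, ib in scored:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            ca, cb = leftovers_a[ia], unused_b[ib]
            diff.add(("source", ca.id))
            diff.add(("target", cb.id))
            walk(ca, cb)
        for ia, extra in enumerate(leftovers_a):
            if ia not in used_a:
                diff.update(_subtree_edges(extra, "source", include_own=True))
        for ib, extra in enumerate(unused_b):
            if ib not in used_b:
                diff.update(_subtree_edges(extra, "target", include_own=True))

    walk(match.source_node, match.target_node)
    match.equal_branches = frozenset(equal)
    match.different_branches = frozenset(diff)
    return match.equal_branches, match.different_branches


# ---------------------------------------------------------------------------
# match report serialization
# ---------------------------------------------------------------------------

def format_report(
    dendrograms: list[Dendrogram],
    pair_matches: list[list[ClusterMatch]],
    params: MatchParams,
) -> str:
    """Line-oriented report: one record per match.

    Fields: pair index, mode, source/target cluster as leaf-name lists,
    color index, equal/different edge counts.
    """
    lines = [
        "# dendromatch report",
        f"# mode={params.mode.value} min_cluster_size={params.min_cluster_size}",
    ]
    for d in dendrograms:
        lines.append(f"# dendrogram title={d.title} leaves={d.leaf_count} "
                     f"root_height={d.root_height:.6g} "
                     f"threshold={params.threshold_for(d):.6g}")
    total = 0
    for i, matches in enumerate(pair_matches):
        for m in matches:
            if not m.equal_branches and not m.different_branches:
                highlight_branches(m, params.delimiter)
            total += 1
            lines.append(
                f"pair={i}->{i + 1}\tmode={m.mode.value}\tcolor={m.color_index}\t"
                f"source={','.join(m.source_node.leaf_names())}\t"
                f"target={','.join(m.target_node.leaf_names())}\t"
                f"equal_edges={len(m.equal_branches)}\t"
                f"different_edges={len(m.different_branches)}")
    lines.append(f"# total_matches={total}")
    return "\n".join(lines) + "\n"
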