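"""Synthetic dendrogram generation and controlled perturbations.

The generator emulates hierarchical-clustering output on a replicated
experimental design: a binary, ultrametric tree whose leaves are ``n_types``
sample types with ``replicates_per_type`` replicates each (names like
``type02.3``).  The defaults — 4 types in triplicate, 12 leaves — mirror a
typical small replicated panel.

The three ``make_*_pair`` perturbations produce a second tree standing in a
known relation to the first at the perturbed cluster:

* swap of two same-type leaves  → bio-isomorphic (labels untouched);
* multiset-preserving regraft   → re-arranged but not bio-isomorphic;
* deletion of a duplicate replicate → contained but not re-arranged.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import FixtureError
from .labeling import MatchMode, label_nodes
from .newick_io import Dendrogram, DendroNode, compute_heights
from .replicate_model import leaf_type

DEFAULT_N_TYPES = 4
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic clustering result."""

    n_types: int = DEFAULT_N_TYPES
    replicates_per_type: int = DEFAULT_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.replicates_per_type < 1:
            raise FixtureError("n_types and replicates_per_type must be >= 1")


def generate(spec: FixtureSpec, title: str | None = None) -> Dendrogram:
    """Random agglomerative construction, reproducible from ``spec.seed``.

    Leaves start at height 0; n−1 merge heights are drawn uniformly from
    (0, 1] and sorted ascending, so each merge sits strictly above both of
    the (uniformly chosen) roots it joins — the tree is ultrametric with
    monotone heights by construction.
    """
    rng = random.Random(spec.seed)
    leaves = [DendroNode(name=f"type{t:02d}.{r}")
              for t in range(1, spec.n_types + 1)
              for r in range(1, spec.replicates_per_type + 1)]
    active: list[tuple[DendroNode, float]] = [(leaf, 0.0) for leaf in leaves]
    merge_heights = sorted(rng.uniform(1e-6, 1.0) for _ in range(len(leaves) - 1))
    for h in merge_heights:
        i, j = sorted(rng.sample(range(len(active)), 2))
        (b, hb) = active.pop(j)
        (a, ha) = active.pop(i)
        a.branch_length = h - ha
        b.branch_length = h - hb
        parent = DendroNode(children=[a, b])
        a.parent = parent
        b.parent = parent
        active.append((parent, h))
    root = active[0][0]
    root.branch_length = 0.0
    d = Dendrogram(root=root,
                   title=title or f"fixture-{spec.seed}")
    return compute_heights(d)


def _swap_names(a: DendroNode, b: DendroNode) -> None:
    a.name, b.name = b.name, a.name


def make_bio_isomorphic_pair(d: Dendrogram, rng: random.Random) -> Dendrogram:
    """Swap the positions of two replicates of one type."""
    out = d.copy()
    by_type: dict[str, list[DendroNode]] = {}
    for leaf in out.root.leaves():
        by_type.setdefault(leaf_type(leaf), []).append(leaf)
    candidates = sorted(t for t, ls in by_type.items() if len(ls) >= 2)
    if not candidates:
        raise FixtureError("no sample type with >= 2 replicates to swap")
    t = rng.choice(candidates)
    a, b = rng.sample(by_type[t], 2)
    _swap_names(a, b)
    out.title = d.title + "-bioiso"
    return out


def _delete_leaf(out: Dendrogram, victim: DendroNode) -> None:
    """Remove ``victim`` and suppress the resulting unary node."""
    parent = victim.parent
    if parent is None:
        raise FixtureError("cannot delete the only leaf")
    parent.children.remove(victim)
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        if grand is None:
            only.branch_length = 0.0
            only.parent = None
            out.root = only
        else:
            only.branch_length += parent.branch_length
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand
    compute_heights(out)


def _bio_text(node: DendroNode) -> str:
    if node.is_leaf:
        return leaf_type(node)
    return "(" + ",".join(sorted(_bio_text(c) for c in node.children)) + ")"


def make_rearranged_pair(d: Dendrogram, rng: random.Random,
                         max_tries: int = 100) -> Dendrogram:
    """Regraft a leaf within its cluster, preserving the type multiset.

    The leaf is detached and re-attached onto another edge of the same
    cluster at an intermediate height, so the cluster keeps its leaves but
    changes topology.  Retries until the cluster's bio-isomorphic canonical
    form actually changes (a regraft can reproduce the original shape).
    """
    for _ in range(max_tries):
        out = d.copy()
        internal = [n for n in out.root.walk_postorder()
                    if not n.is_leaf and len(n.leaves()) >= 3]
        if not internal:
            raise FixtureError("no cluster with >= 3 leaves to rearrange")
        cluster = rng.choice(internal)
        before = _bio_text(cluster)
        movable = [leaf for leaf in cluster.leaves() if leaf.parent is not cluster
                   or len(cluster.children) > 2]
        if not movable:
            continue
        victim = rng.choice(movable)
        # detach victim, suppressing its parent
        parent = victim.parent
        assert parent is not None
        parent.children.remove(victim)
        if len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            only.branch_length += parent.branch_length
            assert grand is not None  # parent is not the cluster root's parent
            grand.children[grand.children.index(parent)] = only
            only.parent = grand
            if parent is cluster:
                cluster = only
        # re-attach onto an edge strictly inside the cluster
        compute_heights(out)
        sites = [n for n in cluster.walk_postorder()
                 if n is not cluster and n is not victim]
        if not sites:
            continue
        site = rng.choice(sites)
        assert site.parent is not None
        top = site.height + site.branch_length
        h = rng.uniform(site.height + 1e-9, top - 1e-9) if top - site.height > 2e-9 \
            else (site.height + top) / 2
        holder = DendroNode(children=[site, victim],
                            branch_length=top - h)
        grand = site.parent
        grand.children[grand.children.index(site)] = holder
        holder.parent = grand
        site.parent = holder
        site.branch_length = h - site.height
        victim.parent = holder
        victim.branch_length = h
        compute_heights(out)
        if _bio_text(cluster) != before:
            out.title = d.title + "-rearranged"
            return out
    raise FixtureError("could not produce a topology-changing regraft")


def make_contained_pair(d: Dendrogram, rng: random.Random) -> Dendrogram:
    """Delete one replicate of a type that occurs at least twice."""
    out = d.copy()
    by_type: dict[str, list[DendroNode]] = {}
    for leaf in out.root.leaves():
        by_type.setdefault(leaf_type(leaf), []).append(leaf)
    candidates = sorted(t for t, ls in by_type.items() if len(ls) >= 2)
    if not candidates:
        raise FixtureError("no sample type with >= 2 replicates to prune")
    t = rng.choice(candidates)
    victim = rng.choice(by_type[t])
    _delete_leaf(out, victim)
    out.title = d.title + "-contained"
    return out
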