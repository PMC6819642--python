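import random

import pytest

from dendromatch import (Dendrogram, FixtureSpec, MatchParams, generate,
                         parse_newick)

# Hand-built 5-leaf iris-style trees: a base clustering and three
# perturbations standing in known relations to it.
BASE_NWK = ("(((versicolor.1:0.3,(versicolor.3:0.1,versicolor.4:0.1):0.2):0.2,"
            "virginica.2:0.5):0.3,versicolor.2:0.8);")
# replicates 1 and 2 switch positions: bio-isomorphic
SWAPPED_NWK = ("(((versicolor.2:0.3,(versicolor.3:0.1,versicolor.4:0.1):0.2):0.2,"
               "virginica.2:0.5):0.3,versicolor.1:0.8);")
# same members, subcluster rewired (virginica joins the cherry): re-arranged
REWIRED_NWK = ("((((versicolor.3:0.15,versicolor.4:0.15):0.2,virginica.2:0.35)"
               ":0.15,versicolor.2:0.5):0.3,versicolor.1:0.8);")
# versicolor.3 and versicolor.4 deleted: contained
PRUNED_NWK = ("((versicolor.1:0.5,virginica.2:0.5):0.3,versicolor.2:0.8);")


@pytest.fixture
def base_tree() -> Dendrogram:
    return parse_newick(BASE_NWK, title="base")


@pytest.fixture
def swapped_tree() -> Dendrogram:
    return parse_newick(SWAPPED_NWK, title="swapped")


@pytest.fixture
def rewired_tree() -> Dendrogram:
    return parse_newick(REWIRED_NWK, title="rewired")


@pytest.fixture
def pruned_tree() -> Dendrogram:
    return parse_newick(PRUNED_NWK, title="pruned")


def full_params(mode, *trees, min_cluster_size=3) -> MatchParams:
    """Params with the threshold opened to each tree's full root height."""
    return MatchParams(mode=mode, min_cluster_size=min_cluster_size,
                       thresholds={t.title: t.root_height for t in trees})


def random_tree(seed: int, n_types: int | None = None,
                replicates: int | None = None) -> Dendrogram:
    """A random ultrametric fixture; shape varied deterministically by seed."""
    rng = random.Random(seed)
    spec = FixtureSpec(
        n_types=n_types if n_types is not None else rng.choice([2, 3, 4, 5]),
        replicates_per_type=(replicates if replicates is not None
                             else rng.choice([2, 3])),
        seed=seed,
    )
    return generate(spec, title=f"t{seed}")


def random_pair(seed: int) -> tuple[Dendrogram, Dendrogram]:
    """Two independent trees over the same leaf set (≤ 15 leaves)."""
    rng = random.Random(seed * 2 + 1)
    n_types = rng.choice([2, 3, 4, 5])
    reps = rng.choice([2, 3])
    a = generate(FixtureSpec(n_types, reps, seed=seed * 2 + 1), title=f"a{seed}")
    b = generate(FixtureSpec(n_types, reps, seed=seed * 2 + 2), title=f"b{seed}")
    return a, b
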