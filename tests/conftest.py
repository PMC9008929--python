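import numpy as np
import pytest

from phylosum import (
    PseudoPosteriorConfig,
    TreeSample,
    generate_pseudo_posterior,
    parse_newick,
    random_time_tree,
)


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_five():
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


@pytest.fixture
def small_sample():
    """Hand-built 4-tree sample on {A,B,C,D}: clade {A,B} in 3 of 4 trees."""
    newicks = [
        "((A:1,B:1):1,(C:1,D:1):1);",
        "((A:1,B:1):2,(C:2,D:2):1);",
        "(((A:1,B:1):1,C:2):1,D:3);",
        "(((A:1,C:1):1,B:2):1,D:3);",
    ]
    return TreeSample(trees=[parse_newick(s) for s in newicks])


@pytest.fixture
def wildcard_sample():
    """Pseudo-posterior with one uniform wildcard among 11 stable taxa."""
    backbone = random_time_tree(12, seed=11)
    wc = sorted(backbone.taxa)[0]
    config = PseudoPosteriorConfig(
        backbone=backbone,
        wildcards=frozenset({wc}),
        locality=0.0,
        n_trees=100,
        seed=12,
    )
    sample, truth = generate_pseudo_posterior(config)
    return sample, truth, backbone


def random_tree_pairs(n_pairs, n_taxa, seed):
    rng = np.random.default_rng(seed)
    labels = [f"T{i}" for i in range(n_taxa)]
    for _ in range(n_pairs):
        yield (
            random_time_tree(n_taxa, seed=rng, labels=labels),
            random_time_tree(n_taxa, seed=rng, labels=labels),
        )
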