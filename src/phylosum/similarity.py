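"""Normalized bipartition and quartet similarities between trees.

Both metrics are *similarities*: 1.0 means identically resolved, and the
normalization divides by the maximum attainable count so that trees with
different taxon counts are comparable.  Two independent random trees have
an expected bipartition similarity of 0.0 and an expected quartet
similarity of 1/3 (each of the three possible resolutions of a quartet is
equally likely under any label-exchangeable tree distribution), so a
rescaled quartet similarity ``(s - 1/3) / (2/3)`` is also provided, with
random-pair expectation 0.0.

Quartet resolutions in a rooted time tree are decided from pairwise MRCA
ages: among the six pairs of a quartet, the pair with the strictly
youngest MRCA is the cherry of the induced unrooted quartet.  Age ties
across different pairings leave the quartet unresolved; an unresolved
quartet counts as shared only when unresolved in both trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .clade_support import extract_clades, prune_tree
from .trees import PhylosumError, TimeTree, TreeSample

__all__ = [
    "SimilarityRecord",
    "mrca_age_matrix",
    "bipartition_similarity",
    "quartet_similarity_exact",
    "quartet_similarity_mc",
    "quartet_similarity",
    "rescale_quartet",
    "similarity_to_sample",
    "DEFAULT_EXACT_LIMIT",
    "DEFAULT_MC_SAMPLES",
]

#: above this many shared taxa the exact quartet enumeration (C(n,4) terms)
#: is refused in favour of the seeded Monte Carlo estimator
DEFAULT_EXACT_LIMIT = 30
DEFAULT_MC_SAMPLES = 100_000

# pair order (i,j),(k,l),(i,k),(j,l),(i,l),(j,k); pairing labels:
# 0 = ij|kl, 1 = ik|jl, 2 = il|jk
_PAIR_LABELS = np.array([0, 0, 1, 1, 2, 2])


def mrca_age_matrix(tree: TimeTree, taxa: Sequence[str]) -> np.ndarray:
    """Dense matrix of pairwise MRCA ages for the given taxon ordering.

    Computed in one postorder sweep: at each internal node, every pair of
    tips drawn from two different child subtrees has that node as MRCA.
    """
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    M = np.zeros((n, n))
    tip_lists: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tip_lists[id(node)] = (
                [index[node.label]] if node.label in index else []
            )
            continue
        child_lists = [tip_lists.pop(id(c)) for c in node.children]
        for a_i in range(len(child_lists)):
            for b_i in range(a_i + 1, len(child_lists)):
                for x in child_lists[a_i]:
                    for y in child_lists[b_i]:
                        M[x, y] = M[y, x] = node.age
        merged: list[int] = []
        for cl in child_lists:
            merged.extend(cl)
        tip_lists[id(node)] = merged
    return M


def _restrict_pair(a: TimeTree, b: TimeTree, min_shared: int = 4):
    shared = sorted(a.taxa & b.taxa)
    if len(shared) < min_shared:
        raise PhylosumError(
            f"only {len(shared)} shared taxa; need at least {min_shared}"
        )
    ra = a if a.taxa == frozenset(shared) else prune_tree(a, shared)
    rb = b if b.taxa == frozenset(shared) else prune_tree(b, shared)
    return ra, rb, shared


def bipartition_similarity(a: TimeTree, b: TimeTree) -> float:
    """Fraction of shared nontrivial clades, normalized by ``n_shared - 2``.

    Trees are restricted to their shared taxa first.  ``n - 2`` is the
    number of nontrivial clades of a fully resolved rooted tree, i.e. the
    maximum number of matches, so identical topologies score 1.0.
    """
    ra, rb, shared = _restrict_pair(a, b)
    ca = extract_clades(ra)
    cb = extract_clades(rb)
    return len(ca & cb) / (len(shared) - 2)


@lru_cache(maxsize=8)
def _quartet_index_arrays(n: int):
    q = np.array(list(combinations(range(n), 4)), dtype=np.intp)
    i, j, k, l = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rows = np.stack([i, k, i, j, i, j])
    cols = np.stack([j, l, k, l, l, k])
    return rows, cols


def _resolve_quartets(M: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pairing label (0/1/2) per quartet, or -1 where ages tie (unresolved)."""
    ages = M[rows, cols].T  # (n_quartets, 6)
    mins = ages.min(axis=1, keepdims=True)
    at_min = ages == mins
    g = np.stack(
        [
            at_min[:, 0] | at_min[:, 1],
            at_min[:, 2] | at_min[:, 3],
            at_min[:, 4] | at_min[:, 5],
        ],
        axis=1,
    )
    n_groups = g.sum(axis=1)
    labels = np.argmax(g, axis=1)
    labels[n_groups != 1] = -1
    return labels


def quartet_similarity_exact(
    a: TimeTree, b: TimeTree, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> float:
    """Exact quartet similarity: agreeing quartets / C(n_shared, 4).

    Enumerates every quartet of the shared taxa; refuses when the shared
    taxon count exceeds ``exact_limit`` (use :func:`quartet_similarity_mc`).
    """
    ra, rb, shared = _restrict_pair(a, b)
    n = len(shared)
    if n > exact_limit:
        raise PhylosumError(
            f"{n} shared taxa exceeds exact limit {exact_limit}; "
            "use quartet_similarity_mc"
        )
    Ma = mrca_age_matrix(ra, shared)
    Mb = mrca_age_matrix(rb, shared)
    rows, cols = _quartet_index_arrays(n)
    la = _resolve_quartets(Ma, rows, cols)
    lb = _resolve_quartets(Mb, rows, cols)
    return float(np.mean(la == lb))


def quartet_similarity_mc(
    a: TimeTree,
    b: TimeTree,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte Carlo quartet similarity: uniform quartet sampling.

    Returns ``(estimate, standard_error)`` with the binomial standard
    error ``sqrt(p(1-p)/m)``.  Deterministic for a fixed seed.
    """
    if n_samples < 100:
        raise PhylosumError("n_samples must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ra, rb, shared = _restrict_pair(a, b)
    n = len(shared)
    Ma = mrca_age_matrix(ra, shared)
    Mb = mrca_age_matrix(rb, shared)
    # uniform 4-subsets via per-row argpartition of random keys
    keys = rng.random((n_samples, n))
    q = np.argpartition(keys, 4, axis=1)[:, :4]
    q.sort(axis=1)
    i, j, k, l = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rows = np.stack([i, k, i, j, i, j])
    cols = np.stack([j, l, k, l, l, k])
    la = _resolve_quartets(Ma, rows, cols)
    lb = _resolve_quartets(Mb, rows, cols)
    p = float(np.mean(la == lb))
    se = float(np.sqrt(p * (1.0 - p) / n_samples))
    return p, se


def quartet_similarity(
    a: TimeTree,
    b: TimeTree,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, str, int]:
    """Dispatch to the exact or Monte Carlo estimator by shared-taxon count.

    Returns ``(similarity, standard_error, estimator, mc_samples)``.
    """
    n_shared = len(a.taxa & b.taxa)
    if n_shared <= exact_limit:
        return quartet_similarity_exact(a, b, exact_limit), 0.0, "exact", 0
    est, se = quartet_similarity_mc(a, b, n_samples, seed)
    return est, se, "montecarlo", n_samples


def rescale_quartet(s: float) -> float:
    """Map quartet similarity so two random trees expect 0.0: (s - 1/3)/(2/3)."""
    if not 0.0 <= s <= 1.0:
        raise PhylosumError("quartet similarity must be in [0, 1]")
    return (s - 1.0 / 3.0) / (2.0 / 3.0)


@dataclass
class SimilarityRecord:
    """One tree-vs-tree comparison row."""

    tree_a: str
    tree_b: str
    shared_taxa: int
    bipartition_similarity: float
    quartet_similarity: float
    rescaled_quartet: float
    estimator: str = "exact"
    mc_samples: int = 0


def similarity_to_sample(
    reference: TimeTree,
    sample: TreeSample,
    reference_id: str = "reference",
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
) -> list[SimilarityRecord]:
    """Compare a summary tree against every tree of a posterior sample.

    Comparisons are restricted to the intersection of tip sets, so a
    pruned reference can be compared against an unpruned sample.  Returns
    one record per posterior tree, in sample order.
    """
    rng = np.random.default_rng(seed)
    records: list[SimilarityRecord] = []
    for i, tree in enumerate(sample):
        shared = len(reference.taxa & tree.taxa)
        bip = bipartition_similarity(reference, tree)
        q, _se, estimator, m = quartet_similarity(
            reference, tree, exact_limit=exact_limit, n_samples=n_samples, seed=rng
        )
        records.append(
            SimilarityRecord(
                tree_a=reference_id,
                tree_b=f"{sample.source or 'sample'}[{i}]",
                shared_taxa=shared,
                bipartition_similarity=bip,
                quartet_similarity=q,
                rescaled_quartet=rescale_quartet(q),
                estimator=estimator,
                mc_samples=m,
            )
        )
    return records


def summarize_similarities(
    records: Iterable[SimilarityRecord],
) -> dict[str, float]:
    """Mean and quantiles of the similarity distributions over a sample."""
    recs = list(records)
    if not recs:
        raise PhylosumError("no similarity records")
    bip = np.array([r.bipartition_similarity for r in recs])
    quart = np.array([r.quartet_similarity for r in recs])
    return {
        "n": len(recs),
        "bipartition_mean": float(bip.mean()),
        "bipartition_q05": float(np.quantile(bip, 0.05)),
        "bipartition_q95": float(np.quantile(bip, 0.95)),
        "quartet_mean": float(quart.mean()),
        "quartet_q05": float(np.quantile(quart, 0.05)),
        "quartet_q95": float(np.quantile(quart, 0.95)),
        "rescaled_quartet_mean": float(rescale_quartet(float(quart.mean()))),
    }
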