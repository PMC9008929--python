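"""Rogue-taxon diagnostics: leaf stability indices and closest-tip
node-distance profiles over a posterior tree sample.

A *wildcard* (rogue) taxon attaches to many different branches across
the posterior, depressing clade support without the backbone topology
itself being uncertain.  Two complementary diagnostics are implemented:

* **Leaf stability** — for a focal taxon ``t`` and triplets ``{a,b,c}``
  of other taxa, the quartet ``{t,a,b,c}`` has three possible resolutions
  whose sample frequencies ``f1 >= f2 >= f3`` (unresolved quartets take up
  the remainder) yield three indices, averaged over triplets:

  - ``lsDif = mean(f1 - f2)`` (difference),
  - ``lsMax = mean(f1)`` (maximum),
  - ``lsEnt = mean(1 - H(f)/log 3)`` (entropy), with ``H`` the Shannon
    entropy of the resolved frequencies renormalized to sum to one.

  A taxon resolved identically in every tree scores 1.0 on all three.

* **Closest-tip node distances** — the number of internal nodes on the
  path between two tips (1 for sister tips, or for a tip and its
  zero-length sampled ancestor).  The three closest neighbours of each
  taxon are fixed on the summary (MCC) tree — three neighbours make the
  comparison a quartet statement — and the distances to those same
  neighbours are then tracked through every posterior tree.  Stable taxa
  keep small distances; wildcards show large means and extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .similarity import mrca_age_matrix
from .trees import PhylosumError, TimeTree, TreeSample

__all__ = [
    "StabilityRecord",
    "node_distance",
    "closest_tips",
    "instability_profile",
    "leaf_stability",
    "stability_report",
    "EXHAUSTIVE_TAXON_LIMIT",
    "DEFAULT_QUARTET_BUDGET",
]

#: at or below this many taxa all triplets are enumerated per focal taxon
EXHAUSTIVE_TAXON_LIMIT = 20
#: triplets sampled per focal taxon above the exhaustive limit
DEFAULT_QUARTET_BUDGET = 1000

_LOG3 = np.log(3.0)


def node_distance(tree: TimeTree, tip_a: str, tip_b: str) -> int:
    """Number of internal nodes on the path between two tips.

    Sister tips are 1 node apart — the minimum, which always indicates a
    monophyletic sister pairing (or a sampled-ancestor relationship under
    the zero-length-branch convention).
    """
    if tip_a == tip_b:
        raise PhylosumError("node distance requires two distinct tips")
    dists = tree.tip_adjacency_distances(tip_a)
    if tip_b not in dists:
        raise PhylosumError(f"tip {tip_b!r} not found in tree")
    return dists[tip_b] - 1  # edges on the path minus one = internal nodes


def closest_tips(tree: TimeTree, taxon: str, k: int = 3) -> list[str]:
    """The ``k`` tips nearest to ``taxon`` by node distance on ``tree``.

    Ties are broken lexicographically by label so the choice is
    deterministic.
    """
    if k >= tree.n_tips:
        raise PhylosumError("k must be smaller than the number of tips")
    dists = tree.tip_adjacency_distances(taxon)
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    return [label for label, _ in ranked[:k]]


def instability_profile(
    sample: TreeSample, mcc: TimeTree, taxon: str, k: int = 3
) -> dict:
    """Distance distributions from ``taxon`` to its MCC-closest neighbours.

    Neighbours are fixed on the MCC tree, then the node distance to each
    is measured in every posterior tree.  Returns per-rank mean, max and
    95th percentile (linear-interpolated empirical order statistic),
    together with the raw distance arrays.
    """
    neighbours = closest_tips(mcc, taxon, k)
    dist_rows = []
    for tree in sample:
        d = tree.tip_adjacency_distances(taxon)
        dist_rows.append([d[nb] - 1 for nb in neighbours])
    dists = np.asarray(dist_rows, dtype=float)  # (n_trees, k)
    return {
        "taxon": taxon,
        "neighbours": neighbours,
        "mcc_distances": [node_distance(mcc, taxon, nb) for nb in neighbours],
        "mean": dists.mean(axis=0).tolist(),
        "max": dists.max(axis=0).tolist(),
        "q95": np.quantile(dists, 0.95, axis=0).tolist(),
        "distances": dists,
    }


def _triplet_array(
    n_taxa: int,
    focal_index: int,
    quartet_budget: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    others = np.array([i for i in range(n_taxa) if i != focal_index], dtype=np.intp)
    if len(others) < 3:
        raise PhylosumError("leaf stability needs at least 3 other taxa")
    if quartet_budget is None or n_taxa <= EXHAUSTIVE_TAXON_LIMIT:
        return np.array(list(combinations(others, 3)), dtype=np.intp)
    # uniform triplets with replacement: unbiased for the triplet mean
    keys = rng.random((quartet_budget, len(others)))
    picks = np.argpartition(keys, 3, axis=1)[:, :3]
    return np.sort(others[picks], axis=1)


def _quartet_partner_counts(
    matrices: Sequence[np.ndarray], focal: int, triplets: np.ndarray
) -> np.ndarray:
    """Per-triplet counts of the three resolutions of {focal, a, b, c}.

    Resolution label = which of a, b, c is the focal taxon's quartet
    partner; decided by the youngest pairwise MRCA age (ties = unresolved,
    counted in none of the three).
    """
    a, b, c = triplets[:, 0], triplets[:, 1], triplets[:, 2]
    t = np.full_like(a, focal)
    # pairs (t,a),(b,c) -> partner a; (t,b),(a,c) -> b; (t,c),(a,b) -> c
    rows = np.stack([t, b, t, a, t, a])
    cols = np.stack([a, c, b, c, c, b])
    counts = np.zeros((len(triplets), 3), dtype=float)
    for M in matrices:
        ages = M[rows, cols].T
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
        resolved = g.sum(axis=1) == 1
        labels = np.argmax(g, axis=1)
        for r in range(3):
            counts[:, r] += resolved & (labels == r)
    return counts


def _indices_from_counts(counts: np.ndarray, n_trees: int) -> tuple[float, float, float]:
    freqs = np.sort(counts, axis=1)[:, ::-1] / n_trees  # f1 >= f2 >= f3
    ls_dif = float(np.mean(freqs[:, 0] - freqs[:, 1]))
    ls_max = float(np.mean(freqs[:, 0]))
    resolved = counts.sum(axis=1)
    ent_terms = np.zeros(len(counts))
    pos = resolved > 0
    if np.any(pos):
        p = counts[pos] / resolved[pos, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        ent_terms[pos] = 1.0 + plogp.sum(axis=1) / _LOG3
    ls_ent = float(np.mean(ent_terms))
    return ls_dif, ls_ent, ls_max


def leaf_stability(
    sample: TreeSample,
    taxon: str,
    quartet_budget: int | None = DEFAULT_QUARTET_BUDGET,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Leaf stability indices ``(lsDif, lsEnt, lsMax)`` for one taxon.

    Triplets of other taxa are enumerated exhaustively for small
    namespaces and sampled uniformly (seeded) above
    :data:`EXHAUSTIVE_TAXON_LIMIT` taxa; ``quartet_budget=None`` forces
    exhaustive enumeration.
    """
    if len(sample) == 0:
        raise PhylosumError("empty tree sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = sorted(sample.taxa)
    focal = taxa.index(taxon)
    triplets = _triplet_array(len(taxa), focal, quartet_budget, rng)
    matrices = [mrca_age_matrix(t, taxa) for t in sample]
    counts = _quartet_partner_counts(matrices, focal, triplets)
    return _indices_from_counts(counts, len(sample))


@dataclass
class StabilityRecord:
    """Per-taxon stability and node-distance report row."""

    taxon: str
    tip_age: float
    ls_dif: float
    ls_ent: float
    ls_max: float
    ct_mean: list[float]  # mean node distance to 1st..kth closest MCC tip
    ct_max: list[float]
    ct_q95: list[float]


def stability_report(
    sample: TreeSample,
    mcc: TimeTree,
    k: int = 3,
    quartet_budget: int | None = DEFAULT_QUARTET_BUDGET,
    seed: int | None = None,
) -> list[StabilityRecord]:
    """Leaf stability plus closest-tip distance profile for every taxon.

    One record per taxon, sorted by label; deterministic for a fixed seed.
    MRCA age matrices are shared across focal taxa, so the whole report
    costs little more than a single-taxon query.
    """
    if len(sample) == 0:
        raise PhylosumError("empty tree sample")
    rng = np.random.default_rng(seed)
    taxa = sorted(sample.taxa)
    matrices = [mrca_age_matrix(t, taxa) for t in sample]
    tip_ages = {t.label: float(t.age) for t in mcc.tips()}
    records: list[StabilityRecord] = []
    for focal, taxon in enumerate(taxa):
        triplets = _triplet_array(len(taxa), focal, quartet_budget, rng)
        counts = _quartet_partner_counts(matrices, focal, triplets)
        ls_dif, ls_ent, ls_max = _indices_from_counts(counts, len(sample))
        prof = instability_profile(sample, mcc, taxon, k)
        records.append(
            StabilityRecord(
                taxon=taxon,
                tip_age=tip_ages.get(taxon, float("nan")),
                ls_dif=ls_dif,
                ls_ent=ls_ent,
                ls_max=ls_max,
                ct_mean=prof["mean"],
                ct_max=prof["max"],
                ct_q95=prof["q95"],
            )
        )
    return records
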