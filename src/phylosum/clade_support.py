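"""Clade posterior probabilities, MCC trees, a-posteriori pruning and
equivalent-node comparison.

The posterior probability (PP) of a clade is the fraction of trees in the
posterior sample that contain it.  The maximum clade credibility (MCC)
tree is the *sampled* tree maximizing the product of its clades' PPs;
node heights are taken from that tree itself ("keep target heights"), so
no height re-estimation is performed.

A *pruned MCC tree* is the MCC tree of the sample after deleting all but
a retained taxon subset from every posterior tree — no new analysis, same
posterior.  Pruning removes wildcard taxa whose unstable placements
fragment the support of otherwise consistent groupings, so pruned clades
typically carry higher PPs than their *equivalent nodes* (smallest
containing clades) in the full MCC tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .trees import NamespaceError, PhylosumError, TimeTree, TreeNode, TreeSample

__all__ = [
    "CladeTable",
    "EquivalentNodeRecord",
    "SupportSummary",
    "extract_clades",
    "clade_posteriors",
    "mcc_tree",
    "mean_clade_pp",
    "prune_tree",
    "prune_sample",
    "pruned_mcc",
    "equivalent_nodes",
    "summarize_support",
]


def extract_clades(
    tree: TimeTree, include_trivial: bool = False
) -> set[frozenset[str]]:
    """Clades (tip-label sets) of all internal nodes of a rooted tree.

    Singletons are excluded.  The all-taxa root clade is trivial — present
    in every rooted tree — and is omitted unless ``include_trivial``.
    Sampled-ancestor tips participate as ordinary tips.
    """
    all_taxa = tree.taxa
    clades: set[frozenset[str]] = set()
    node_clades = tree.node_clades()
    for node in tree.internal_nodes():
        cl = node_clades[id(node)]
        if len(cl) < 2:
            continue
        if cl == all_taxa and not include_trivial:
            continue
        clades.add(cl)
    return clades


@dataclass
class CladeTable:
    """Occurrence counts of clades over a posterior sample."""

    counts: dict[frozenset[str], int]
    n_trees: int

    def pp(self, clade: Iterable[str]) -> float:
        """Posterior probability: occurrences / total trees (0 if never seen)."""
        return self.counts.get(frozenset(clade), 0) / self.n_trees

    def __len__(self) -> int:
        return len(self.counts)


def clade_posteriors(sample: TreeSample) -> CladeTable:
    """Count every nontrivial clade observed in the sample."""
    if len(sample) == 0:
        raise PhylosumError("empty tree sample")
    counts: dict[frozenset[str], int] = {}
    for tree in sample:
        for clade in extract_clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    return CladeTable(counts=counts, n_trees=len(sample))


def _log_clade_score(tree: TimeTree, table: CladeTable) -> float:
    score = 0.0
    for clade in extract_clades(tree):
        pp = table.pp(clade)
        # every clade of a sampled tree occurs at least once, so pp > 0
        score += math.log(pp)
    return score


def mcc_tree(sample: TreeSample, table: CladeTable | None = None) -> TimeTree:
    """Maximum clade credibility tree of a posterior sample.

    Returns (a copy of) the sampled tree with the highest sum of log
    clade PPs over its nontrivial clades; ties go to the earliest sampled
    tree.  Node heights are the selected tree's own heights.  Every
    internal node is annotated with ``posterior`` = PP of its clade (the
    root gets 1.0).
    """
    if len(sample) == 0:
        raise PhylosumError("empty tree sample")
    if table is None:
        table = clade_posteriors(sample)
    best_i = 0
    best_score = -math.inf
    for i, tree in enumerate(sample):
        score = _log_clade_score(tree, table)
        if score > best_score:
            best_score = score
            best_i = i
    mcc = sample[best_i].copy()
    all_taxa = mcc.taxa
    node_clades = mcc.node_clades()
    for node in mcc.internal_nodes():
        cl = node_clades[id(node)]
        node.annotations["posterior"] = 1.0 if cl == all_taxa else table.pp(cl)
    return mcc


def mean_clade_pp(mcc: TimeTree) -> float:
    """Arithmetic mean of the ``posterior`` annotation over nontrivial nodes."""
    all_taxa = mcc.taxa
    node_clades = mcc.node_clades()
    pps = []
    for node in mcc.internal_nodes():
        if node_clades[id(node)] == all_taxa:
            continue
        if "posterior" not in node.annotations:
            raise PhylosumError("MCC tree lacks posterior annotations")
        pps.append(float(node.annotations["posterior"]))
    if not pps:
        raise PhylosumError("no nontrivial internal nodes")
    return sum(pps) / len(pps)


def prune_tree(tree: TimeTree, retained: Iterable[str]) -> TimeTree:
    """Restrict a tree to a taxon subset.

    Non-retained tips are removed; the resulting degree-2 nodes are
    suppressed with branch lengths summed.  Ages of surviving nodes are
    unchanged, so the pruned tree keeps the original time calibration.
    """
    keep = frozenset(retained)
    missing = keep - tree.taxa
    if missing:
        raise NamespaceError(f"retained taxa absent from tree: {sorted(missing)}")

    def _build(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            if node.label in keep:
                return TreeNode(
                    label=node.label, age=node.age, annotations=dict(node.annotations)
                )
            return None
        kept_children = [c for c in (_build(ch) for ch in node.children) if c]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            # degree-2 node: suppress, child keeps its own age
            return kept_children[0]
        new = TreeNode(label=node.label, age=node.age, annotations=dict(node.annotations))
        for c in kept_children:
            new.add_child(c)
        return new

    root = _build(tree.root)
    if root is None or root.is_tip:
        raise PhylosumError("pruning left fewer than 2 taxa")
    pruned = TimeTree(root)
    pruned.compute_branch_lengths_from_ages()
    return pruned


def prune_sample(sample: TreeSample, retained: Iterable[str]) -> TreeSample:
    """A-posteriori pruning: restrict every posterior tree to ``retained``."""
    keep = frozenset(retained)
    if len(keep) < 3:
        raise PhylosumError("need at least 3 retained taxa")
    missing = keep - sample.taxa
    if missing:
        raise NamespaceError(f"retained taxa absent from sample: {sorted(missing)}")
    return TreeSample(
        trees=[prune_tree(t, keep) for t in sample],
        source=sample.source,
        burnin_fraction=sample.burnin_fraction,
    )


def pruned_mcc(sample: TreeSample, retained: Iterable[str]) -> TimeTree:
    """MCC tree of the a-posteriori pruned posterior sample.

    Clade PPs are computed on the pruned sample; the same posterior
    underlies the full and pruned summaries.
    """
    return mcc_tree(prune_sample(sample, retained))


@dataclass
class EquivalentNodeRecord:
    """A pruned-MCC clade matched to its equivalent node in the full MCC tree.

    The equivalent node is the smallest clade of the full MCC tree
    containing all taxa of the pruned clade (their MRCA clade).  The
    record is *contradicting* when the full tree places other retained
    taxa inside that clade, i.e. when restricting the full MCC tree to the
    retained taxa does not recover the pruned clade.
    """

    pruned_clade: frozenset[str]
    pp_pruned: float
    full_node_clade: frozenset[str]
    pp_full: float
    contradicting: bool


def equivalent_nodes(
    full_mcc: TimeTree,
    pruned: TimeTree,
    retained: Iterable[str] | None = None,
) -> list[EquivalentNodeRecord]:
    """Match each nontrivial pruned-MCC clade to its full-MCC equivalent node.

    Both trees must carry ``posterior`` annotations (as produced by
    :func:`mcc_tree`).  Records are ordered by decreasing pruned-clade
    size for reproducibility.
    """
    retained_set = frozenset(retained) if retained is not None else pruned.taxa
    if pruned.taxa != retained_set:
        raise NamespaceError("pruned tree tips do not match retained set")
    if not retained_set <= full_mcc.taxa:
        raise NamespaceError("retained taxa not a subset of full MCC tips")

    full_clades = full_mcc.node_clades()
    full_pp = {
        full_clades[id(n)]: float(n.annotations.get("posterior", float("nan")))
        for n in full_mcc.internal_nodes()
    }
    pruned_clades = pruned.node_clades()

    records: list[EquivalentNodeRecord] = []
    for node in pruned.internal_nodes():
        clade = pruned_clades[id(node)]
        if clade == retained_set:
            continue  # trivial root clade
        # smallest full-MCC clade containing all members
        candidates = [cl for cl in full_pp if clade <= cl]
        candidates.append(full_mcc.taxa)
        full_clade = min(candidates, key=len)
        pp_full = full_pp.get(full_clade, 1.0)  # root clade has PP 1 by convention
        contradicting = (full_clade & retained_set) != clade
        records.append(
            EquivalentNodeRecord(
                pruned_clade=clade,
                pp_pruned=float(node.annotations["posterior"]),
                full_node_clade=full_clade,
                pp_full=pp_full,
                contradicting=contradicting,
            )
        )
    records.sort(key=lambda r: (-len(r.pruned_clade), sorted(r.pruned_clade)))
    return records


@dataclass
class SupportSummary:
    n_records: int
    mean_pp_full: float
    mean_pp_pruned: float
    mean_difference: float
    n_contradicting: int


def summarize_support(records: Sequence[EquivalentNodeRecord]) -> SupportSummary:
    """Mean full/pruned PPs, mean PP gain from pruning, contradiction count."""
    if not records:
        raise PhylosumError("no equivalent-node records")
    n = len(records)
    mean_full = sum(r.pp_full for r in records) / n
    mean_pruned = sum(r.pp_pruned for r in records) / n
    return SupportSummary(
        n_records=n,
        mean_pp_full=mean_full,
        mean_pp_pruned=mean_pruned,
        mean_difference=mean_pruned - mean_full,
        n_contradicting=sum(r.contradicting for r in records),
    )
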