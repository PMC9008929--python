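"""Synthetic fossilized-birth-death trees and pseudo-posterior samples.

This module generates the study conditions for the downstream summaries:

* forward simulation of the fossilized birth-death (FBD) process —
  speciation rate λ, extinction rate μ and fossil-sampling rate ψ, all
  per lineage per million years — conditioned on a minimum number of
  fossil samples, with fossils on surviving lineages turned into
  sampled-ancestor tips (zero-length branches);
* stratigraphic machinery: equal-duration stage slices of a geologic
  stage, and tip ages drawn uniformly within per-tip stratigraphic
  intervals with fossil-site synchronization (tips from the same site
  share one age draw);
* the exponential origin-time prior used by tip-dating analyses of
  clades with an old, sparsely sampled stem (offset plus exponential
  excess);
* *pseudo-posteriors*: samples of trees in which a fixed backbone is
  (optionally) NNI-perturbed while designated wildcard taxa detach and
  reattach across branches with a controllable locality.  This is a
  stochastic stand-in for genuine MCMC output: most taxa keep stable
  placements, wildcards wander, and every downstream statistic (clade
  PPs, MCC selection, similarities, leaf stability) has known ground
  truth.

All randomness flows through ``numpy.random.Generator`` objects seeded
explicitly; a fixed seed reproduces every tree bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import PhylosumError, TimeTree, TreeNode, TreeSample

__all__ = [
    "FBDParams",
    "StageSliceScheme",
    "PseudoPosteriorConfig",
    "fbd_convert",
    "fbd_invert",
    "sample_origin_prior",
    "stage_slice_boundaries",
    "assign_tip_ages",
    "simulate_fbd_tree",
    "random_time_tree",
    "generate_pseudo_posterior",
]


# ----------------------------------------------------------------------
# FBD parametrization
# ----------------------------------------------------------------------
def fbd_convert(lam: float, mu: float, psi: float) -> tuple[float, float, float]:
    """(λ, μ, ψ) -> (d, r, s): net diversification, turnover, sampling proportion.

    ``d = λ - μ``, ``r = μ/λ``, ``s = ψ/(μ + ψ)`` (``s = 0`` when both μ
    and ψ are zero).
    """
    if lam <= 0:
        raise PhylosumError("speciation rate must be positive")
    if mu < 0 or psi < 0:
        raise PhylosumError("extinction and sampling rates must be non-negative")
    if mu >= lam:
        raise PhylosumError("extinction must be below speciation (d > 0)")
    d = lam - mu
    r = mu / lam
    s = psi / (mu + psi) if (mu + psi) > 0 else 0.0
    return d, r, s


def fbd_invert(d: float, r: float, s: float) -> tuple[float, float, float]:
    """(d, r, s) -> (λ, μ, ψ); inverse of :func:`fbd_convert`."""
    if d <= 0:
        raise PhylosumError("net diversification must be positive")
    if not 0.0 <= r < 1.0:
        raise PhylosumError("turnover must be in [0, 1)")
    if not 0.0 <= s < 1.0:
        raise PhylosumError("sampling proportion must be in [0, 1) for inversion")
    lam = d / (1.0 - r)
    mu = r * lam
    psi = s * mu / (1.0 - s) if s > 0 else 0.0
    if s > 0 and mu == 0.0:
        raise PhylosumError("s > 0 with zero turnover has no finite ψ")
    return lam, mu, psi


@dataclass(frozen=True)
class FBDParams:
    """Fossilized birth-death parameters with the derived parametrization."""

    lam: float
    mu: float
    psi: float
    origin: float  # mya

    def __post_init__(self) -> None:
        fbd_convert(self.lam, self.mu, self.psi)  # validates
        if self.origin <= 0:
            raise PhylosumError("origin must be positive (mya)")

    @property
    def d(self) -> float:
        return fbd_convert(self.lam, self.mu, self.psi)[0]

    @property
    def r(self) -> float:
        return fbd_convert(self.lam, self.mu, self.psi)[1]

    @property
    def s(self) -> float:
        return fbd_convert(self.lam, self.mu, self.psi)[2]

    @classmethod
    def from_drs(cls, d: float, r: float, s: float, origin: float) -> "FBDParams":
        lam, mu, psi = fbd_invert(d, r, s)
        return cls(lam=lam, mu=mu, psi=psi, origin=origin)


def sample_origin_prior(
    mean_excess: float,
    offset: float,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw origin ages from an offset exponential prior.

    The prior places the origin at ``offset`` (the upper age limit of the
    oldest unambiguous fossil) plus an exponential excess with the given
    mean — informative when the clade is vanishingly rare before its
    first certain occurrence, yet allowing older origins.
    """
    if mean_excess <= 0:
        raise PhylosumError("mean_excess must be positive")
    if n < 1:
        raise PhylosumError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return offset + rng.exponential(mean_excess, size=n)


# ----------------------------------------------------------------------
# stratigraphy
# ----------------------------------------------------------------------
def stage_slice_boundaries(start: float, end: float, n_slices: int) -> list[float]:
    """Internal boundaries of equal-duration slices of a stage.

    ``start`` and ``end`` are ages (mya) with ``start > end``; the stage
    is divided into ``n_slices`` time-equivalent bins and the
    ``n_slices - 1`` internal boundary ages are returned, oldest first.
    """
    if start <= end:
        raise PhylosumError("stage start must be older than its end")
    if n_slices < 1:
        raise PhylosumError("need at least one slice")
    width = (start - end) / n_slices
    return [start - i * width for i in range(1, n_slices)]


@dataclass(frozen=True)
class StageSliceScheme:
    """A geologic stage divided into equal-duration slices."""

    name: str
    start: float  # older bound, mya
    end: float  # younger bound, mya
    n_slices: int

    def __post_init__(self) -> None:
        stage_slice_boundaries(self.start, self.end, self.n_slices)  # validates

    @property
    def boundaries(self) -> list[float]:
        return stage_slice_boundaries(self.start, self.end, self.n_slices)

    def slice_interval(self, i: int) -> tuple[float, float]:
        """(older, younger) age bounds of slice ``i`` (0 = oldest)."""
        if not 0 <= i < self.n_slices:
            raise PhylosumError(f"slice index {i} out of range")
        edges = [self.start, *self.boundaries, self.end]
        return edges[i], edges[i + 1]


def assign_tip_ages(
    tree: TimeTree,
    intervals: dict[str, tuple[float, float]],
    site_ids: dict[str, str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> TimeTree:
    """Draw tip ages uniformly within stratigraphic intervals.

    ``intervals`` maps tip label to an (older, younger) age pair; tips
    sharing a ``site_ids`` value are from one fossil site, hence
    contemporaneous, and receive a single shared draw (the same fraction
    of their respective intervals, and the same age when intervals
    coincide).  A drawn age older than the tip's parent node is an error.
    Returns a new tree; branch lengths are recomputed from ages.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site_ids = site_ids or {}
    out = tree.copy()
    site_draw: dict[str, float] = {}
    for tip in sorted(out.tips(), key=lambda t: t.label):
        if tip.label not in intervals:
            continue
        older, younger = intervals[tip.label]
        if older < younger:
            raise PhylosumError(
                f"interval for {tip.label!r} must be (older, younger)"
            )
        site = site_ids.get(tip.label)
        if site is not None:
            if site not in site_draw:
                site_draw[site] = float(rng.random())
            u = site_draw[site]
        else:
            u = float(rng.random())
        age = younger + u * (older - younger)
        if tip.parent is not None and age > tip.parent.age:
            raise PhylosumError(
                f"drawn age {age:.3f} for {tip.label!r} exceeds parent age "
                f"{tip.parent.age:.3f}"
            )
        tip.age = age
    out.compute_branch_lengths_from_ages()
    return out


# ----------------------------------------------------------------------
# forward FBD simulation
# ----------------------------------------------------------------------
@dataclass
class _Lineage:
    parent: int | None
    birth: float  # age at which the lineage starts (older)
    end: float | None = None  # age at which it ends
    children: list[int] = field(default_factory=list)
    fossils: list[float] = field(default_factory=list)


def _simulate_forward(
    params: FBDParams, rng: np.random.Generator, max_lineages: int
) -> list[_Lineage] | None:
    """One forward pass from the origin to the present; None if it exploded."""
    lineages: list[_Lineage] = [_Lineage(parent=None, birth=params.origin)]
    active: list[int] = [0]
    t = params.origin
    total_rate_per_lineage = params.lam + params.mu + params.psi
    while active and t > 0:
        n = len(active)
        t -= rng.exponential(1.0 / (n * total_rate_per_lineage))
        if t <= 0:
            break
        which = active[rng.integers(n)]
        u = rng.random() * total_rate_per_lineage
        if u < params.lam:
            lineages[which].end = t
            for _ in range(2):
                lineages.append(_Lineage(parent=which, birth=t))
                lineages[which].children.append(len(lineages) - 1)
                active.append(len(lineages) - 1)
            active.remove(which)
            if len(lineages) > max_lineages:
                return None
        elif u < params.lam + params.mu:
            lineages[which].end = t
            active.remove(which)
        else:
            lineages[which].fossils.append(t)
    for i in active:  # unsampled survivors reach the present (ρ = 0)
        lineages[i].end = 0.0
    return lineages


def _reconstruct(lineages: list[_Lineage]) -> tuple[TreeNode | None, int, int]:
    """Build the reconstructed sampled tree; returns (root, n_tips, n_SA).

    Only lineages ancestral to at least one fossil are retained; fossils
    with sampled descendants become zero-length sampled-ancestor tips.
    """
    n = len(lineages)
    retained = [False] * n
    for i in range(n - 1, -1, -1):
        lin = lineages[i]
        retained[i] = bool(lin.fossils) or any(retained[c] for c in lin.children)

    tip_counter = [0]
    sa_counter = [0]

    def build(i: int) -> TreeNode | None:
        lin = lineages[i]
        # events on this lineage, oldest first: speciations to retained
        # children and fossilization events
        events: list[tuple[float, str, object]] = []
        for c in lin.children:
            if retained[c]:
                events.append((lineages[c].birth, "spec", c))
        for f in lin.fossils:
            events.append((f, "fossil", None))
        if not events:
            return None
        events.sort(key=lambda e: e[0])  # youngest first
        current: TreeNode | None = None
        for age, kind, payload in events:
            if kind == "fossil":
                tip_counter[0] += 1
                tip = TreeNode(label=f"F{tip_counter[0]}", age=age)
                if current is None:
                    current = tip  # youngest sample on this path: terminal tip
                else:
                    sa_counter[0] += 1
                    joint = TreeNode(age=age)
                    joint.add_child(current)
                    joint.add_child(tip)  # zero-length branch
                    current = joint
            else:
                sub = build(payload)
                assert sub is not None
                if current is None:
                    current = sub
                else:
                    joint = TreeNode(age=age)
                    joint.add_child(current)
                    joint.add_child(sub)
                    current = joint
        return current

    if not retained[0]:
        return None, 0, 0
    root = build(0)
    return root, tip_counter[0], sa_counter[0]


def simulate_fbd_tree(
    params: FBDParams,
    seed: int | np.random.Generator | None = None,
    min_tips: int = 10,
    max_attempts: int = 1000,
    max_lineages: int = 20_000,
) -> tuple[TimeTree, dict]:
    """Simulate one reconstructed FBD tree by rejection sampling.

    Forward birth-death-fossilization simulation from the origin, with
    extant-sampling probability fixed at 0 (all samples are fossils);
    attempts are rejected until at least ``min_tips`` fossil samples are
    ancestral to the reconstruction.  Returns the tree and a truth record
    with the fossil count, sampled-ancestor count and attempt number.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.psi == 0:
        raise PhylosumError("ψ = 0 yields no fossil samples; nothing to reconstruct")
    if min_tips < 2:
        raise PhylosumError("min_tips must be >= 2")
    for attempt in range(1, max_attempts + 1):
        lineages = _simulate_forward(params, rng, max_lineages)
        if lineages is None:
            continue
        root, n_tips, n_sa = _reconstruct(lineages)
        if root is None or n_tips < min_tips:
            continue
        if root.is_tip:
            continue
        tree = TimeTree(root)
        tree.compute_branch_lengths_from_ages()
        truth = {
            "n_tips": n_tips,
            "n_sampled_ancestors": n_sa,
            "attempt": attempt,
            "params": {
                "lambda": params.lam,
                "mu": params.mu,
                "psi": params.psi,
                "origin": params.origin,
            },
        }
        return tree, truth
    raise PhylosumError(
        f"no acceptable tree in {max_attempts} attempts; consider raising ψ "
        "or the origin time, or lowering min_tips"
    )


# ----------------------------------------------------------------------
# random topologies and pseudo-posteriors
# ----------------------------------------------------------------------
def random_time_tree(
    n_tips: int,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
    tip_age: float = 0.0,
) -> TimeTree:
    """Uniformly random rooted binary labeled topology with jittered ages.

    Topologies are uniform over the ``(2n-3)!!`` rooted binary labeled
    shapes (sequential attachment of each new leaf to one of the
    ``2k - 1`` insertion positions, including above the root).  Internal
    node ages are ``max(child ages) + U(0.5, 1.5)``, giving a valid time
    tree with almost-surely distinct internal ages.
    """
    if n_tips < 2:
        raise PhylosumError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        width = len(str(n_tips))
        labels = [f"T{str(i + 1).zfill(width)}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise PhylosumError("label count must equal n_tips")

    root = TreeNode()
    root.add_child(TreeNode(label=labels[0]))
    root.add_child(TreeNode(label=labels[1]))
    tree = TimeTree(root)
    for k in range(2, n_tips):
        edges: list[TreeNode] = [
            node for node in tree.preorder() if node is not tree.root
        ]
        pos = int(rng.integers(len(edges) + 1))
        new_leaf = TreeNode(label=labels[k])
        new_node = TreeNode()
        if pos == len(edges):  # above the root
            new_node.add_child(tree.root)
            new_node.add_child(new_leaf)
            tree.root = new_node
        else:
            child = edges[pos]
            parent = child.parent
            idx = parent.children.index(child)
            parent.children[idx] = new_node
            new_node.parent = parent
            new_node.add_child(child)
            new_node.add_child(new_leaf)
    for node in tree.postorder():
        if node.is_tip:
            node.age = tip_age
        else:
            node.age = max(c.age for c in node.children) + float(
                rng.uniform(0.5, 1.5)
            )
    tree.compute_branch_lengths_from_ages()
    return tree


@dataclass
class PseudoPosteriorConfig:
    """Recipe for a posterior-like tree sample with wildcard taxa.

    ``locality`` controls how far a wildcard strays from its true
    attachment: reattachment weights are ``exp(-locality * d)`` over
    candidate branches, with ``d`` the topological distance from the true
    attachment point.  ``locality = 0`` is a uniform wildcard; large
    values confine it to its home neighbourhood.
    """

    backbone: TimeTree
    wildcards: frozenset[str] = frozenset()
    locality: float = 0.0
    nni_probability: float = 0.0
    n_trees: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.wildcards <= self.backbone.taxa:
            raise PhylosumError("wildcards must be backbone tips")
        if self.locality < 0:
            raise PhylosumError("locality must be >= 0")
        if not 0.0 <= self.nni_probability <= 1.0:
            raise PhylosumError("nni_probability must be a probability")
        if self.n_trees < 1:
            raise PhylosumError("n_trees must be >= 1")
        if len(self.backbone.taxa - self.wildcards) < 3:
            raise PhylosumError("need at least 3 non-wildcard taxa")


def _detach_tip(tree: TimeTree, label: str) -> TreeNode:
    """Remove a tip, suppress the resulting degree-2 node; returns the
    node the tip was attached next to (its former sibling side)."""
    tip = tree.find_tip(label)
    parent = tip.parent
    if parent is None:
        raise PhylosumError("cannot detach the root")
    parent.remove_child(tip)
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        if grand is None:
            only.parent = None
            tree.root = only
            return only
        idx = grand.children.index(parent)
        grand.children[idx] = only
        only.parent = grand
        return only
    return parent


def _attach_tip(
    tree: TimeTree,
    tip: TreeNode,
    edge_child: TreeNode,
    attach_age: float,
) -> None:
    new_node = TreeNode(age=attach_age)
    parent = edge_child.parent
    if parent is None:  # attach above the root
        new_node.add_child(tree.root)
        new_node.add_child(tip)
        tree.root = new_node
    else:
        idx = parent.children.index(edge_child)
        parent.children[idx] = new_node
        new_node.parent = parent
        new_node.add_child(edge_child)
        new_node.add_child(tip)


def _node_graph_distances(tree: TimeTree, start: TreeNode) -> dict[int, int]:
    from collections import deque

    dist = {id(start): 0}
    by_id = {id(start): start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        neighbours = list(node.children)
        if node.parent is not None:
            neighbours.append(node.parent)
        for nb in neighbours:
            if id(nb) not in dist:
                dist[id(nb)] = dist[id(node)] + 1
                by_id[id(nb)] = nb
                queue.append(nb)
    return dist


def _try_nni(tree: TimeTree, rng: np.random.Generator, max_tries: int = 20) -> bool:
    """One age-valid nearest-neighbour interchange; False if none found."""
    internal_edges = [
        n
        for n in tree.preorder()
        if (not n.is_tip) and n.parent is not None and len(n.children) == 2
    ]
    if not internal_edges:
        return False
    for _ in range(max_tries):
        child = internal_edges[int(rng.integers(len(internal_edges)))]
        parent = child.parent
        siblings = [c for c in parent.children if c is not child]
        if not siblings:
            continue
        sib = siblings[int(rng.integers(len(siblings)))]
        grand_children = child.children
        g = grand_children[int(rng.integers(len(grand_children)))]
        # swap sib <-> g; ages must stay monotone: g under parent is fine
        # (parent older than child older than g); sib under child needs
        # child.age > sib.age
        if child.age <= sib.age:
            continue
        pi = parent.children.index(sib)
        ci = child.children.index(g)
        parent.children[pi] = g
        g.parent = parent
        child.children[ci] = sib
        sib.parent = child
        return True
    return False


def generate_pseudo_posterior(
    config: PseudoPosteriorConfig,
) -> tuple[TreeSample, dict]:
    """Generate a posterior-like sample from a backbone with wildcards.

    Per tree: the backbone is copied; with ``nni_probability`` one
    age-valid NNI perturbs it; each wildcard is detached and reattached
    to a branch drawn with weight ``exp(-locality * d)`` (``d`` =
    topological distance from its true attachment), at an age drawn
    uniformly within the feasible part of the branch.  The truth record
    lists the wildcards and the backbone's nontrivial clades, both with
    and without the wildcards.
    """
    from .clade_support import extract_clades, prune_tree

    rng = np.random.default_rng(config.seed)
    wildcards = sorted(config.wildcards)
    trees: list[TimeTree] = []
    for _ in range(config.n_trees):
        tree = config.backbone.copy()
        if config.nni_probability > 0 and rng.random() < config.nni_probability:
            _try_nni(tree, rng)
        for w in wildcards:
            w_age = tree.find_tip(w).age
            anchor = _detach_tip(tree, w)
            dists = _node_graph_distances(tree, anchor)
            candidates: list[tuple[TreeNode, float, float, int]] = []
            for node in tree.preorder():
                if node.parent is None:
                    lo = max(node.age, w_age)
                    hi = lo + 1.0  # attachment above the root
                    candidates.append((node, lo, hi, dists[id(node)]))
                else:
                    hi = node.parent.age
                    lo = max(node.age, w_age)
                    if hi > lo:
                        candidates.append((node, lo, hi, dists[id(node)]))
            d_arr = np.array([c[3] for c in candidates], dtype=float)
            weights = np.exp(-config.locality * d_arr)
            weights /= weights.sum()
            pick = int(rng.choice(len(candidates), p=weights))
            node, lo, hi, _d = candidates[pick]
            attach_age = float(rng.uniform(lo, hi))
            new_tip = TreeNode(label=w, age=w_age)
            _attach_tip(tree, new_tip, node, attach_age)
        tree.compute_branch_lengths_from_ages()
        trees.append(tree)
    sample = TreeSample(trees=trees, source="pseudo_posterior")
    backbone_clades = extract_clades(config.backbone)
    stable = sorted(config.backbone.taxa - config.wildcards)
    truth = {
        "wildcards": wildcards,
        "locality": config.locality,
        "nni_probability": config.nni_probability,
        "n_trees": config.n_trees,
        "seed": config.seed,
        "backbone_clades": sorted(sorted(c) for c in backbone_clades),
        "stable_taxa": stable,
        "stable_backbone_clades": sorted(
            sorted(c)
            for c in extract_clades(prune_tree(config.backbone, stable))
        ),
    }
    return sample, truth
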