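"""Core containers: rooted time trees, tree samples and clades.

A :class:`TimeTree` is a rooted, time-calibrated tree.  Every node carries
an *age* (time before present, in million years) and a *branch length*
(the age difference to its parent).  Fossil tips have positive ages;
sampled ancestors — fossils lying on an internal lineage — are represented
as tips attached by a branch of length (approximately) zero, the
convention used by Bayesian tip-dating software when serializing trees.

Clades are plain ``frozenset`` objects of tip labels, so that set algebra
(intersection, containment) is available directly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Taxon",
    "TreeNode",
    "TimeTree",
    "TreeSample",
    "PhylosumError",
    "NamespaceError",
    "DEFAULT_SA_EPSILON",
]

#: terminal branches at or below this length (my) are sampled-ancestor
#: attachments for bookkeeping purposes
DEFAULT_SA_EPSILON = 1e-8


class PhylosumError(Exception):
    """Base class for errors raised by this package."""


class NamespaceError(PhylosumError):
    """Taxon namespace violation (duplicate or unknown labels)."""


@dataclass(frozen=True)
class Taxon:
    """An operational taxonomic unit.

    Parameters
    ----------
    label
        Unique, non-empty tip label.
    site_id
        Optional fossil-site grouping key; tips sharing a site are assumed
        contemporaneous and receive synchronized ages when ages are drawn
        from stratigraphic intervals.
    """

    label: str
    site_id: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise NamespaceError("taxon label must be non-empty")


class TreeNode:
    """A node of a :class:`TimeTree`."""

    __slots__ = ("parent", "children", "branch_length", "age", "annotations", "label")

    def __init__(
        self,
        label: str | None = None,
        branch_length: float | None = None,
        age: float | None = None,
        annotations: dict | None = None,
    ) -> None:
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.branch_length = branch_length
        self.age = age
        self.annotations: dict = annotations if annotations is not None else {}
        self.label = label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.label or ''} {kind} age={self.age}>"


class TimeTree:
    """Rooted time-calibrated tree with node ages and annotations.

    Invariants (checked by :meth:`validate`):

    * exactly one root;
    * ``age(parent) >= age(child)`` for every node;
    * ``branch_length == age(parent) - age(child)`` within tolerance.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tips())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.label == label:
                return t
        raise NamespaceError(f"tip {label!r} not found in tree")

    # ------------------------------------------------------------------
    # ages and branch lengths
    # ------------------------------------------------------------------
    def compute_ages_from_branch_lengths(self) -> None:
        """Set node ages from branch lengths, youngest tip at age 0.

        The reference point is the youngest tip (largest root-to-tip path),
        which is the natural "present" for non-ultrametric fossil trees.
        """
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            bl = node.branch_length if node.branch_length is not None else 0.0
            depth[id(node)] = depth[id(node.parent)] + bl
        max_depth = max(depth[id(t)] for t in self.tips())
        for node in self.preorder():
            node.age = max_depth - depth[id(node)]

    def compute_branch_lengths_from_ages(self) -> None:
        for node in self.preorder():
            if node is self.root:
                node.branch_length = None
            else:
                node.branch_length = node.parent.age - node.age

    def validate(self, tol: float = 1e-9, allow_negative: bool = True) -> None:
        """Check age monotonicity and age/branch-length consistency.

        Negative branch lengths (which "keep target heights" MCC trees can
        legitimately contain) are tolerated by default but the corresponding
        age inversion is still reported through the returned exception
        message when ``allow_negative`` is False.
        """
        seen_labels: set[str] = set()
        for node in self.preorder():
            if node.is_tip:
                if node.label is None:
                    raise NamespaceError("unlabeled tip")
                if node.label in seen_labels:
                    raise NamespaceError(f"duplicate tip label {node.label!r}")
                seen_labels.add(node.label)
            if node is self.root:
                continue
            if node.age is None or node.parent.age is None:
                raise PhylosumError("node without age")
            if not allow_negative and node.parent.age < node.age - tol:
                raise PhylosumError(
                    f"age inversion: parent {node.parent.age} < child {node.age}"
                )
            if node.branch_length is not None:
                expected = node.parent.age - node.age
                if abs(node.branch_length - expected) > max(tol, tol * abs(expected)):
                    raise PhylosumError(
                        "branch length inconsistent with ages: "
                        f"{node.branch_length} vs {expected}"
                    )

    # ------------------------------------------------------------------
    # copying
    # ------------------------------------------------------------------
    def copy(self) -> "TimeTree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(
                label=node.label,
                branch_length=node.branch_length,
                age=node.age,
                annotations=dict(node.annotations),
            )
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return TimeTree(_clone(self.root))

    # ------------------------------------------------------------------
    # clades and topology helpers
    # ------------------------------------------------------------------
    def clade_of(self, node: TreeNode) -> frozenset[str]:
        """Tip-label set of the subtree rooted at ``node``."""
        labels: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def node_clades(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` -> tip set, computed in one postorder sweep."""
        clades: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                clades[id(node)] = frozenset((node.label,))
            else:
                clades[id(node)] = frozenset().union(
                    *(clades[id(c)] for c in node.children)
                )
        return clades

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of a set of tip labels."""
        want = frozenset(labels)
        if not want:
            raise PhylosumError("mrca of empty set")
        missing = want - self.taxa
        if missing:
            raise NamespaceError(f"tips not in tree: {sorted(missing)}")
        clades = self.node_clades()
        best: TreeNode | None = None
        best_size = None
        for node in self.preorder():
            cl = clades[id(node)]
            if want <= cl and (best_size is None or len(cl) < best_size):
                best = node
                best_size = len(cl)
        assert best is not None
        return best

    def tip_adjacency_distances(self, label: str) -> dict[str, int]:
        """Topological distances (edge counts) from one tip to all others."""
        start = self.find_tip(label)
        dist: dict[int, int] = {id(start): 0}
        node_by_id = {id(start): start}
        queue = deque([start])
        out: dict[str, int] = {}
        while queue:
            node = queue.popleft()
            neighbors = list(node.children)
            if node.parent is not None:
                neighbors.append(node.parent)
            for nb in neighbors:
                if id(nb) in dist:
                    continue
                dist[id(nb)] = dist[id(node)] + 1
                node_by_id[id(nb)] = nb
                if nb.is_tip:
                    out[nb.label] = dist[id(nb)]
                queue.append(nb)
        return out


@dataclass
class TreeSample:
    """An ordered collection of time trees on one shared taxon namespace.

    Typically a (burn-in filtered) posterior sample from a Bayesian
    tip-dating analysis, or a pseudo-posterior from the synthetic
    generator.
    """

    trees: list[TimeTree]
    source: str = ""
    burnin_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise PhylosumError("burnin_fraction must be in [0, 1)")
        if self.trees:
            ref = self.trees[0].taxa
            for i, t in enumerate(self.trees[1:], start=1):
                if t.taxa != ref:
                    diff = sorted(t.taxa ^ ref)
                    raise NamespaceError(
                        f"tree {i} tip set differs from tree 0; "
                        f"symmetric difference: {diff}"
                    )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[TimeTree]:
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def taxa(self) -> frozenset[str]:
        if not self.trees:
            raise PhylosumError("empty tree sample")
        return self.trees[0].taxa
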