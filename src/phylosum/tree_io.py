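"""Reading and writing posterior tree samples and annotated summary trees.

Supports the NEXUS/Newick dialects emitted by Bayesian tip-dating software
(BEAST-family): ``Translate`` tables and ``[&key=value,...]`` node comments
("hot comments") carrying posterior probabilities, HPD intervals and the
like.  Parsing is delegated to :mod:`dendropy`; trees are converted into
the package's own :class:`~phylosum.trees.TimeTree` containers with node
ages computed from branch lengths (youngest tip defines the age reference)
unless explicit ``height`` annotations are present, in which case the
annotations win.

Unknown annotation keys are preserved verbatim and never interpreted.
Negative branch lengths (which summary trees produced with "keep target
heights" may contain) are preserved on output; a warning is emitted.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import dendropy

from .trees import (
    DEFAULT_SA_EPSILON,
    NamespaceError,
    PhylosumError,
    TimeTree,
    TreeNode,
    TreeSample,
)

__all__ = [
    "ParseError",
    "parse_newick",
    "parse_nexus_trees",
    "combine_runs",
    "count_sampled_ancestors",
    "write_annotated_tree",
    "write_nexus_sample",
]


class ParseError(PhylosumError):
    """Malformed Newick/NEXUS input."""


def _coerce(value):
    """Convert annotation values parsed as strings into numbers where possible."""
    if isinstance(value, list):
        return [_coerce(v) for v in value]
    if isinstance(value, str):
        try:
            return int(value)
        except ValueError:
            pass
        try:
            return float(value)
        except ValueError:
            return value
    return value


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    root = None
    mapping: dict[int, TreeNode] = {}
    for dnode in dtree.preorder_node_iter():
        ann = {a.name: _coerce(a.value) for a in dnode.annotations}
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, branch_length=dnode.edge.length, annotations=ann)
        mapping[id(dnode)] = node
        if dnode.parent_node is None:
            root = node
        else:
            mapping[id(dnode.parent_node)].add_child(node)
    if root is None:
        raise ParseError("empty tree")
    tree = TimeTree(root)

    labels = [t.label for t in tree.tips()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NamespaceError(f"duplicate tip labels: {dupes}")

    heights = [n.annotations.get("height") for n in tree.preorder()]
    if all(h is not None for h in heights):
        for n in tree.preorder():
            n.age = float(n.annotations["height"])
        tree.compute_branch_lengths_from_ages()
    else:
        tree.compute_ages_from_branch_lengths()

    if any(
        n.branch_length is not None and n.branch_length < 0 for n in tree.preorder()
    ):
        warnings.warn(
            "tree contains negative branch lengths (kept as-is); this can "
            "occur in summary trees with node heights taken from the target "
            "tree itself",
            stacklevel=3,
        )
    return tree


def parse_newick(text: str, namespace: Sequence[str] | None = None) -> TimeTree:
    """Parse a single Newick string into a :class:`TimeTree`.

    ``[&...]`` hot comments on nodes and branches are preserved in the
    node annotation maps.  If ``namespace`` is given, the tip label set
    must be a subset of it.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"newick parse error: {exc}") from exc
    tree = _from_dendropy(dtree)
    if namespace is not None:
        extra = tree.taxa - frozenset(namespace)
        if extra:
            raise NamespaceError(f"tips outside declared namespace: {sorted(extra)}")
    return tree


def parse_nexus_trees(path: str, burnin_fraction: float = 0.0) -> TreeSample:
    """Read all trees from a NEXUS file into a :class:`TreeSample`.

    ``Translate`` tables are applied, tree order is preserved, and
    BEAST-style node annotations are attached to nodes.  ``burnin_fraction``
    is recorded on the sample but *not* applied; use :func:`combine_runs`
    to discard burn-in.
    """
    try:
        dtrees = dendropy.TreeList.get(
            path=path,
            schema="nexus",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"nexus parse error in {path}: {exc}") from exc
    trees = [_from_dendropy(dt) for dt in dtrees]
    if not trees:
        raise ParseError(f"no trees found in {path}")
    return TreeSample(trees=trees, source=str(path), burnin_fraction=burnin_fraction)


def combine_runs(
    samples: Sequence[TreeSample], burnin_fraction: float = 0.1
) -> TreeSample:
    """Discard per-run burn-in and concatenate independent runs.

    The leading ``floor(n * burnin_fraction)`` trees of each run are
    dropped (the convention for discarding initial MCMC samples) and the
    remainders are concatenated in run order.  All runs must share the
    same tip set.
    """
    if not samples:
        raise PhylosumError("no runs to combine")
    if not 0.0 <= burnin_fraction < 1.0:
        raise PhylosumError("burnin_fraction must be in [0, 1)")
    ref = samples[0].taxa
    for s in samples[1:]:
        if s.taxa != ref:
            raise NamespaceError(
                f"tip sets differ between runs; symmetric difference: "
                f"{sorted(s.taxa ^ ref)}"
            )
    combined: list[TimeTree] = []
    for s in samples:
        skip = math.floor(len(s) * burnin_fraction)
        combined.extend(s.trees[skip:])
    return TreeSample(
        trees=combined,
        source="+".join(s.source for s in samples),
        burnin_fraction=burnin_fraction,
    )


def count_sampled_ancestors(tree: TimeTree, epsilon: float = DEFAULT_SA_EPSILON) -> int:
    """Number of tips attached by a terminal branch of length <= epsilon.

    Sampled ancestors (fossils lying on internal lineages) are serialized
    as zero-length terminal branches by tip-dating software; this counts
    them under that convention.
    """
    if epsilon < 0:
        raise PhylosumError("epsilon must be >= 0")
    count = 0
    for tip in tree.tips():
        bl = tip.branch_length
        if bl is None:
            bl = (tip.parent.age - tip.age) if tip.parent is not None else 0.0
        if abs(bl) <= epsilon:
            count += 1
    return count


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------
def _format_value(v) -> str:
    if isinstance(v, list):
        return "{" + ",".join(_format_value(x) for x in v) + "}"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _annotation_comment(ann: dict) -> str:
    if not ann:
        return ""
    parts = [f"{k}={_format_value(v)}" for k, v in ann.items()]
    return "[&" + ",".join(parts) + "]"


_NEEDS_QUOTE = set(" ()[]{}:;,'\"")


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, with_annotations: bool) -> str:
    if node.is_tip:
        s = _format_label(node.label)
    else:
        s = "(" + ",".join(
            _newick_node(c, with_annotations) for c in node.children
        ) + ")"
        if node.label:
            s += _format_label(node.label)
    if with_annotations:
        s += _annotation_comment(node.annotations)
    if node.branch_length is not None:
        s += f":{node.branch_length!r}"
    return s


def write_annotated_tree(tree: TimeTree, format: str = "newick") -> str:
    """Serialize a tree with its ``[&...]`` annotation comments.

    Round-trips through :func:`parse_newick` / :func:`parse_nexus_trees`:
    topology, branch lengths (to 1e-9) and annotations are preserved.
    """
    with_ann = any(n.annotations for n in tree.preorder())
    newick = _newick_node(tree.root, with_ann) + ";"
    if format == "newick":
        return newick
    if format == "nexus":
        taxa = sorted(tree.taxa)
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={len(taxa)};",
            "    TAXLABELS " + " ".join(_format_label(t) for t in taxa) + ";",
            "END;",
            "BEGIN TREES;",
            f"    TREE summary = [&R] {newick}",
            "END;",
        ]
        return "\n".join(lines) + "\n"
    raise PhylosumError(f"unknown format {format!r}")


def write_nexus_sample(sample: TreeSample, path: str) -> None:
    """Write a whole tree sample as a NEXUS TREES block with Translate table."""
    taxa = sorted(sample.taxa)
    index = {t: str(i + 1) for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS " + " ".join(_format_label(t) for t in taxa) + ";",
        "END;",
        "BEGIN TREES;",
        "    TRANSLATE",
    ]
    lines.extend(
        f"        {index[t]} {_format_label(t)}" + ("," if i < len(taxa) - 1 else "")
        for i, t in enumerate(taxa)
    )
    lines.append("    ;")
    for i, tree in enumerate(sample):
        t = tree.copy()
        for tip in t.tips():
            tip.label = index[tip.label]
        with_ann = any(n.annotations for n in t.preorder())
        lines.append(f"    TREE STATE_{i} = [&R] " + _newick_node(t.root, with_ann) + ";")
    lines.append("END;")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
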