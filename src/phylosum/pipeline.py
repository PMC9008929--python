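"""End-to-end orchestration: from tree samples to the study report tables.

``run_summary`` reproduces the full summary flow for one dataset:
burn-in filtering and run combination, full MCC tree, a-posteriori
pruned MCC trees per retained taxon set, equivalent-node comparison,
mean clade PP, MCC-vs-posterior similarity distributions and the
per-taxon stability report.  ``compare_datasets`` collates several such
bundles into cross-dataset tables (pairwise MCC similarities, per-dataset
support summaries).

Outputs are TSV tables (via pandas), annotated NEXUS trees and a JSON
manifest recording seeds, burn-in counts and estimator modes, so every
emitted number can be recomputed by calling the underlying module
functions directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clade_support import (
    equivalent_nodes,
    mcc_tree,
    mean_clade_pp,
    prune_sample,
    summarize_support,
)
from .rogue import stability_report
from .similarity import (
    DEFAULT_EXACT_LIMIT,
    DEFAULT_MC_SAMPLES,
    bipartition_similarity,
    quartet_similarity,
    rescale_quartet,
    similarity_to_sample,
    summarize_similarities,
)
from .tree_io import combine_runs, parse_nexus_trees, write_annotated_tree
from .trees import PhylosumError, TreeSample

__all__ = ["AnalysisConfig", "Bundle", "run_summary", "compare_datasets"]


@dataclass
class AnalysisConfig:
    """Configuration of one dataset analysis."""

    label: str
    tree_files: list[str] = field(default_factory=list)
    sample: TreeSample | None = None  # alternative to tree_files
    burnin_fraction: float = 0.1
    retained_sets: dict[str, list[str]] = field(default_factory=dict)
    exact_limit: int = DEFAULT_EXACT_LIMIT
    mc_samples: int = DEFAULT_MC_SAMPLES
    quartet_budget: int | None = 1000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class Bundle:
    """Artifacts of one dataset summary."""

    label: str
    sample: TreeSample
    full_mcc: "TimeTree"
    mean_clade_pp: float
    pruned: dict  # name -> {mcc, records, summary, mean_clade_pp}
    mcc_vs_posterior: dict
    stability: list
    manifest: dict


def _load_sample(config: AnalysisConfig) -> TreeSample:
    if config.sample is not None:
        if config.tree_files:
            raise PhylosumError("give either tree_files or an in-memory sample")
        return config.sample
    if not config.tree_files:
        raise PhylosumError("no input trees configured")
    runs = [parse_nexus_trees(p) for p in config.tree_files]
    return combine_runs(runs, config.burnin_fraction)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PhylosumError as exc:
        raise PhylosumError(f"[{name}] {exc}") from exc


def run_summary(config: AnalysisConfig) -> Bundle:
    """Run the full summary flow for one dataset; optionally write artifacts."""
    sample = _stage("load", _load_sample, config)
    full = _stage("mcc", mcc_tree, sample)
    mean_pp = _stage("mean_clade_pp", mean_clade_pp, full)

    pruned_out: dict = {}
    for name, retained in config.retained_sets.items():
        psample = _stage(f"prune:{name}", prune_sample, sample, retained)
        pmcc = _stage(f"pruned_mcc:{name}", mcc_tree, psample)
        records = _stage(
            f"equivalent_nodes:{name}", equivalent_nodes, full, pmcc, retained
        )
        pruned_out[name] = {
            "mcc": pmcc,
            "records": records,
            "summary": summarize_support(records),
            "mean_clade_pp": mean_clade_pp(pmcc),
        }

    sim_records = _stage(
        "similarity",
        similarity_to_sample,
        full,
        sample,
        reference_id=f"{config.label}:full_mcc",
        exact_limit=config.exact_limit,
        n_samples=config.mc_samples,
        seed=config.seed,
    )
    sim_summary = summarize_similarities(sim_records)

    stab = _stage(
        "stability",
        stability_report,
        sample,
        full,
        quartet_budget=config.quartet_budget,
        seed=config.seed,
    )

    manifest = {
        "label": config.label,
        "phylosum_version": __version__,
        "n_trees": len(sample),
        "burnin_fraction": config.burnin_fraction,
        "seed": config.seed,
        "exact_limit": config.exact_limit,
        "mc_samples": config.mc_samples,
        "quartet_budget": config.quartet_budget,
        "retained_sets": {k: sorted(v) for k, v in config.retained_sets.items()},
    }

    bundle = Bundle(
        label=config.label,
        sample=sample,
        full_mcc=full,
        mean_clade_pp=mean_pp,
        pruned=pruned_out,
        mcc_vs_posterior=sim_summary,
        stability=stab,
        manifest=manifest,
    )
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def equivalent_nodes_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pruned_clade": ["|".join(sorted(r.pruned_clade)) for r in records],
            "pp_pruned": [r.pp_pruned for r in records],
            "full_node_clade": ["|".join(sorted(r.full_node_clade)) for r in records],
            "pp_full": [r.pp_full for r in records],
            "pp_difference": [r.pp_pruned - r.pp_full for r in records],
            "contradicting": [r.contradicting for r in records],
        }
    )


def stability_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "taxon": r.taxon,
            "AgeMCC": r.tip_age,
            "lsDif": r.ls_dif,
            "lsEnt": r.ls_ent,
            "lsMax": r.ls_max,
        }
        for i in range(len(r.ct_mean)):
            row[f"ct{i + 1}mean"] = r.ct_mean[i]
            row[f"ct{i + 1}max"] = r.ct_max[i]
            row[f"ct{i + 1}q95"] = r.ct_q95[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(bundle: Bundle, output_dir: str) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{bundle.label}_full_mcc.nex").write_text(
        write_annotated_tree(bundle.full_mcc, "nexus")
    )
    for name, p in bundle.pruned.items():
        (out / f"{bundle.label}_pruned_mcc_{name}.nex").write_text(
            write_annotated_tree(p["mcc"], "nexus")
        )
        equivalent_nodes_frame(p["records"]).to_csv(
            out / f"{bundle.label}_equivalent_nodes_{name}.tsv", sep="\t", index=False
        )
    stability_frame(bundle.stability).to_csv(
        out / f"{bundle.label}_stability.tsv", sep="\t", index=False
    )
    summary = {
        "mean_clade_pp_full": bundle.mean_clade_pp,
        "mean_clade_pp_pruned": {
            k: v["mean_clade_pp"] for k, v in bundle.pruned.items()
        },
        "support": {
            k: vars(v["summary"]) for k, v in bundle.pruned.items()
        },
        "mcc_vs_posterior": bundle.mcc_vs_posterior,
        "manifest": bundle.manifest,
    }
    (out / f"{bundle.label}_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def compare_datasets(bundles: list[Bundle], seed: int = 0) -> dict[str, pd.DataFrame]:
    """Cross-dataset comparison tables from two or more summary bundles.

    Returns a per-dataset support table and pairwise full-MCC similarity
    matrices (bipartition, quartet and rescaled quartet), restricted to
    shared taxa per pair.
    """
    if len(bundles) < 2:
        raise PhylosumError("need at least two bundles to compare")
    labels = [b.label for b in bundles]
    if len(set(labels)) != len(labels):
        raise PhylosumError("bundle labels must be unique")

    support = pd.DataFrame(
        {
            "dataset": labels,
            "n_trees": [len(b.sample) for b in bundles],
            "mean_clade_pp": [b.mean_clade_pp for b in bundles],
            "posterior_bipartition_mean": [
                b.mcc_vs_posterior["bipartition_mean"] for b in bundles
            ],
            "posterior_quartet_mean": [
                b.mcc_vs_posterior["quartet_mean"] for b in bundles
            ],
        }
    )

    n = len(bundles)
    bip = pd.DataFrame(1.0, index=labels, columns=labels)
    quart = pd.DataFrame(1.0, index=labels, columns=labels)
    resq = pd.DataFrame(1.0, index=labels, columns=labels)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = bundles[i].full_mcc, bundles[j].full_mcc
            bs = bipartition_similarity(a, b)
            qs, _se, _est, _m = quartet_similarity(a, b, seed=seed)
            bip.iloc[i, j] = bip.iloc[j, i] = bs
            quart.iloc[i, j] = quart.iloc[j, i] = qs
            resq.iloc[i, j] = resq.iloc[j, i] = rescale_quartet(qs)
    return {
        "support": support,
        "bipartition": bip,
        "quartet": quart,
        "rescaled_quartet": resq,
    }
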