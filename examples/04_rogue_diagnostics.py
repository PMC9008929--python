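"""Leaf stability and closest-tip node distances: finding the wildcards.

Generates a pseudo-posterior with two known wildcards among 18 taxa,
then shows that the stability report singles them out: lowest lsDif and
the largest mean node distances to their MCC-tree neighbours.
"""

from phylosum import (
    PseudoPosteriorConfig,
    generate_pseudo_posterior,
    mcc_tree,
    random_time_tree,
    stability_report,
)

backbone = random_time_tree(18, seed=20)
taxa = sorted(backbone.taxa)
wildcards = set(taxa[:2])
sample, truth = generate_pseudo_posterior(
    PseudoPosteriorConfig(
        backbone=backbone, wildcards=frozenset(wildcards),
        locality=0.2,  # mildly localized: wanders, but prefers home
        n_trees=150, seed=21,
    )
)

mcc = mcc_tree(sample)
records = stability_report(sample, mcc, seed=0)

print(f"{'taxon':<6} {'lsDif':>6} {'lsEnt':>6} {'lsMax':>6} "
      f"{'ct1mean':>8} {'ct1max':>7}  wildcard?")
for r in sorted(records, key=lambda r: r.ls_dif)[:6]:
    print(f"{r.taxon:<6} {r.ls_dif:6.3f} {r.ls_ent:6.3f} {r.ls_max:6.3f} "
          f"{r.ct_mean[0]:8.2f} {r.ct_max[0]:7.0f}  "
          f"{'<- yes' if r.taxon in wildcards else ''}")
# lsDif near 1 = the taxon's quartets resolve the same way in every tree;
# ct1mean = mean node distance to its closest MCC-tree neighbour across
# the posterior (1 = always sisters). Wildcards combine low stability
# with large distances; a stable taxon whose neighbour IS a wildcard can
# show inflated distances despite high stability.
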