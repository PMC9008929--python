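"""FBD simulation, stratigraphic machinery and pseudo-posterior generation."""

import numpy as np
import pytest
from scipy.stats import kstest

from phylosum import (
    FBDParams,
    PhylosumError,
    PseudoPosteriorConfig,
    StageSliceScheme,
    assign_tip_ages,
    clade_posteriors,
    count_sampled_ancestors,
    extract_clades,
    fbd_convert,
    fbd_invert,
    generate_pseudo_posterior,
    mcc_tree,
    parse_newick,
    random_time_tree,
    sample_origin_prior,
    simulate_fbd_tree,
    stage_slice_boundaries,
    write_annotated_tree,
)


class TestFBDParametrization:
    def test_forward_values(self):
        assert fbd_convert(2.0, 1.0, 1.0) == pytest.approx((1.0, 0.5, 0.5))
        assert fbd_convert(1.0, 0.0, 0.0) == pytest.approx((1.0, 0.0, 0.0))

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lam = rng.uniform(0.1, 5.0)
            mu = rng.uniform(0.0, lam * 0.99)
            psi = rng.uniform(0.0, 3.0)
            d, r, s = fbd_convert(lam, mu, psi)
            if s == 0.0 and psi > 0:
                continue  # mu == 0 loses psi information by construction
            lam2, mu2, psi2 = fbd_invert(d, r, s)
            assert (lam2, mu2, psi2) == pytest.approx((lam, mu, psi), abs=1e-12)

    def test_nonpositive_diversification_rejected(self):
        with pytest.raises(PhylosumError):
            fbd_convert(1.0, 1.0, 0.5)
        with pytest.raises(PhylosumError):
            FBDParams(lam=1.0, mu=2.0, psi=0.5, origin=10.0)

    def test_derived_properties(self):
        p = FBDParams.from_drs(d=1.0, r=0.5, s=0.5, origin=20.0)
        assert (p.lam, p.mu, p.psi) == pytest.approx((2.0, 1.0, 1.0))
        assert (p.d, p.r, p.s) == pytest.approx((1.0, 0.5, 0.5))


class TestOriginPrior:
    def test_mean_excess(self):
        draws = sample_origin_prior(0.1, 489.5, n=200_000, seed=1)
        assert draws.min() >= 489.5
        assert draws.mean() - 489.5 == pytest.approx(0.1, abs=0.002)

    def test_small_mean_collapses_to_offset(self):
        draws = sample_origin_prior(1e-9, 489.5, n=1000, seed=2)
        assert draws == pytest.approx(489.5, abs=1e-6)

    def test_seed_reproducible(self):
        a = sample_origin_prior(0.1, 489.5, n=100, seed=3)
        b = sample_origin_prior(0.1, 489.5, n=100, seed=3)
        assert np.array_equal(a, b)


class TestStageSlices:
    def test_dapingian_boundaries(self):
        assert stage_slice_boundaries(470.0, 467.3, 3) == pytest.approx(
            [469.1, 468.2]
        )

    def test_single_slice_no_boundaries(self):
        assert stage_slice_boundaries(470.0, 467.3, 1) == []

    def test_even_spacing(self):
        assert stage_slice_boundaries(10.0, 0.0, 5) == pytest.approx([8, 6, 4, 2])

    def test_inverted_stage_rejected(self):
        with pytest.raises(PhylosumError):
            stage_slice_boundaries(467.3, 470.0, 3)

    def test_scheme_slice_intervals(self):
        scheme = StageSliceScheme("Dapingian", 470.0, 467.3, 3)
        assert scheme.slice_interval(0) == pytest.approx((470.0, 469.1))
        assert scheme.slice_interval(2) == pytest.approx((468.2, 467.3))


class TestTipAges:
    def test_same_site_synchronized(self):
        tree = parse_newick("((A:5,B:5):5,C:10);")
        intervals = {"A": (4.0, 1.0), "B": (4.0, 1.0), "C": (3.0, 2.0)}
        sites = {"A": "locality1", "B": "locality1"}
        aged = assign_tip_ages(tree, intervals, sites, seed=4)
        a, b = aged.find_tip("A"), aged.find_tip("B")
        assert a.age == b.age
        assert 1.0 <= a.age <= 4.0
        aged.validate()

    def test_degenerate_interval_exact(self):
        tree = parse_newick("((A:5,B:5):5,C:10);")
        aged = assign_tip_ages(tree, {"A": (2.5, 2.5)}, seed=5)
        assert aged.find_tip("A").age == pytest.approx(2.5)

    def test_draws_cover_interval_uniformly(self):
        tree = parse_newick("((A:5,B:5):5,C:10);")
        ages = [
            assign_tip_ages(tree, {"A": (4.0, 1.0)}, seed=s).find_tip("A").age
            for s in range(1000)
        ]
        stat = kstest((np.array(ages) - 1.0) / 3.0, "uniform")
        assert stat.pvalue > 0.01

    def test_interval_violating_parent_age_rejected(self):
        tree = parse_newick("((A:1,B:1):5,C:6);")
        with pytest.raises(PhylosumError):
            # parent node at age 5; force a draw at 5.5
            assign_tip_ages(tree, {"A": (5.5, 5.5)}, seed=6)


class TestFBDSimulation:
    PARAMS = FBDParams(lam=1.0, mu=0.4, psi=0.8, origin=8.0)

    def test_psi_zero_rejected(self):
        with pytest.raises(PhylosumError):
            simulate_fbd_tree(FBDParams(lam=1.0, mu=0.4, psi=0.0, origin=8.0), seed=0)

    def test_fixed_seed_bit_identical(self):
        t1, r1 = simulate_fbd_tree(self.PARAMS, seed=7, min_tips=8)
        t2, r2 = simulate_fbd_tree(self.PARAMS, seed=7, min_tips=8)
        assert write_annotated_tree(t1) == write_annotated_tree(t2)
        assert r1 == r2

    def test_truth_record_matches_tree(self):
        for seed in range(25):
            tree, truth = simulate_fbd_tree(self.PARAMS, seed=seed, min_tips=5)
            tree.validate(tol=1e-8)
            assert tree.n_tips == truth["n_tips"]
            assert count_sampled_ancestors(tree) == truth["n_sampled_ancestors"]
            assert tree.root.age <= self.PARAMS.origin

    def test_no_extinction_all_fossils_on_surviving_lineages(self):
        # with mu = 0 every lineage survives to the present, so every fossil
        # that is not the youngest sample of its lineage path is an ancestor
        params = FBDParams(lam=0.6, mu=0.0, psi=1.5, origin=6.0)
        tree, truth = simulate_fbd_tree(params, seed=11, min_tips=5)
        assert truth["n_sampled_ancestors"] == count_sampled_ancestors(tree)
        assert truth["n_sampled_ancestors"] > 0

    def test_ages_within_origin_and_positive(self):
        tree, _ = simulate_fbd_tree(self.PARAMS, seed=13, min_tips=8)
        for node in tree.preorder():
            assert 0.0 <= node.age <= self.PARAMS.origin


class TestRandomTimeTree:
    def test_uniform_topologies_on_three_taxa(self):
        # 3 rooted labeled topologies, each ~1/3 under sequential insertion
        from collections import Counter

        rng = np.random.default_rng(14)
        counts = Counter()
        for _ in range(3000):
            t = random_time_tree(3, seed=rng, labels=["A", "B", "C"])
            (clade,) = extract_clades(t)
            counts["".join(sorted(clade))] += 1
        freqs = np.array([counts[k] for k in ("AB", "AC", "BC")]) / 3000
        assert np.all(np.abs(freqs - 1 / 3) < 0.04)

    def test_valid_time_tree(self):
        for seed in range(20):
            t = random_time_tree(12, seed=seed)
            t.validate()
            ages = [n.age for n in t.internal_nodes()]
            assert len(set(ages)) == len(ages)  # distinct internal ages


class TestPseudoPosterior:
    def test_no_perturbation_identity(self):
        backbone = random_time_tree(10, seed=15)
        sample, truth = generate_pseudo_posterior(
            PseudoPosteriorConfig(backbone=backbone, n_trees=20, seed=16)
        )
        table = clade_posteriors(sample)
        assert all(c == 20 for c in table.counts.values())
        assert extract_clades(mcc_tree(sample)) == extract_clades(backbone)

    def test_uniform_wildcard_depresses_containing_clades(self):
        backbone = random_time_tree(10, seed=17)
        wc = sorted(backbone.taxa)[0]
        sample, truth = generate_pseudo_posterior(
            PseudoPosteriorConfig(
                backbone=backbone,
                wildcards=frozenset({wc}),
                locality=0.0,
                n_trees=100,
                seed=18,
            )
        )
        from phylosum import prune_sample

        table = clade_posteriors(sample)
        containing = [
            frozenset(c) for c in truth["backbone_clades"] if wc in c
        ]
        # clades containing the wildcard lose posterior mass in the full
        # sample; excluding the wildcard a posteriori restores PP = 1 for
        # every backbone clade of the stable taxa
        assert all(table.pp(c) < 1.0 for c in containing)
        pruned_table = clade_posteriors(prune_sample(sample, truth["stable_taxa"]))
        assert all(
            pruned_table.pp(frozenset(c)) == pytest.approx(1.0)
            for c in truth["stable_backbone_clades"]
        )

    def test_high_locality_confines_wildcard(self):
        backbone = random_time_tree(14, seed=19)
        wc = sorted(backbone.taxa)[5]
        loose, _ = generate_pseudo_posterior(
            PseudoPosteriorConfig(
                backbone=backbone, wildcards=frozenset({wc}),
                locality=0.0, n_trees=60, seed=20,
            )
        )
        tight, _ = generate_pseudo_posterior(
            PseudoPosteriorConfig(
                backbone=backbone, wildcards=frozenset({wc}),
                locality=5.0, n_trees=60, seed=20,
            )
        )

        def mean_ct1(sample):
            from phylosum import instability_profile

            return instability_profile(sample, backbone, wc)["mean"][0]

        assert mean_ct1(tight) < mean_ct1(loose)

    def test_every_tree_is_a_valid_time_tree(self):
        backbone = random_time_tree(12, seed=21)
        sample, _ = generate_pseudo_posterior(
            PseudoPosteriorConfig(
                backbone=backbone,
                wildcards=frozenset(sorted(backbone.taxa)[:3]),
                locality=0.5,
                nni_probability=0.3,
                n_trees=50,
                seed=22,
            )
        )
        for tree in sample:
            tree.validate(tol=1e-8)
            assert tree.taxa == backbone.taxa

    def test_seed_reproducible(self):
        backbone = random_time_tree(8, seed=23)
        cfg = dict(
            backbone=backbone,
            wildcards=frozenset(sorted(backbone.taxa)[:1]),
            n_trees=10,
            seed=24,
        )
        s1, _ = generate_pseudo_posterior(PseudoPosteriorConfig(**cfg))
        s2, _ = generate_pseudo_posterior(PseudoPosteriorConfig(**cfg))
        assert [write_annotated_tree(t) for t in s1] == [
            write_annotated_tree(t) for t in s2
        ]
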