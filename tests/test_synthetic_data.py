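import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from phylothreat import (
    IUCN_CATEGORIES,
    Phylogeny,
    SyntheticConfig,
    build_proximity,
    generate_dataset,
    morans_i,
    read_risk_csv,
    threat_counts,
    validate_clade_map,
)
from phylothreat.synthetic_data import (
    deep_clades,
    simulate_risk,
    simulate_threats,
    simulate_tree,
)
from phylothreat.vocabulary import DATA_DEFICIENT, THREAT_CLASSES


class TestSimulateTree:
    def test_three_tip_tree_is_ultrametric(self):
        tree = simulate_tree(SyntheticConfig(n_species=3, seed=0))
        assert tree.n_tips == 3
        assert tree.is_ultrametric()

    def test_same_seed_identical_newick(self):
        cfg = SyntheticConfig(n_species=25, seed=17)
        assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()

    def test_yule_colless_imbalance_matches_independent_simulator(self):
        """With imbalance 0 the topology is Yule; mean Colless imbalance over
        replicates matches dendropy's own birth-death simulator."""
        from dendropy.model import birthdeath

        def colless(tree: Phylogeny) -> int:
            total = 0
            for nd in tree.root.preorder_iter():
                kids = nd.child_nodes()
                if len(kids) == 2:
                    a = sum(1 for _ in kids[0].leaf_iter())
                    b = sum(1 for _ in kids[1].leaf_iter())
                    total += abs(a - b)
            return total

        n, reps = 12, 250
        mine = [
            colless(simulate_tree(SyntheticConfig(n_species=n, imbalance=0.0, seed=s)))
            for s in range(reps)
        ]
        import random as pyrandom

        ref = []
        for s in range(reps):
            t = birthdeath.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=pyrandom.Random(7000 + s),
            )
            ref.append(colless(Phylogeny(t, impute_missing_lengths=True)))
        se = np.sqrt(np.var(mine) / reps + np.var(ref) / reps)
        assert np.mean(mine) == pytest.approx(np.mean(ref), abs=4 * se)

    def test_imbalance_knob_increases_colless(self):
        def colless_sum(imb, seeds):
            out = 0
            for s in seeds:
                tree = simulate_tree(SyntheticConfig(n_species=16, imbalance=imb, seed=s))
                for nd in tree.root.preorder_iter():
                    kids = nd.child_nodes()
                    if len(kids) == 2:
                        a = sum(1 for _ in kids[0].leaf_iter())
                        b = sum(1 for _ in kids[1].leaf_iter())
                        out += abs(a - b)
            return out

        assert colless_sum(0.95, range(40)) > colless_sum(0.0, range(40))


class TestSimulateThreats:
    def test_zero_signal_prevalence_within_binomial_ci(self):
        cfg = SyntheticConfig(n_species=400, threat_signal=0.0, seed=21)
        tree = simulate_tree(cfg)
        inc = simulate_threats(tree, cfg, np.random.default_rng(5))
        for threat, prev in zip(THREAT_CLASSES, cfg.threat_prevalence):
            k = int(inc[threat].sum())
            ci = binomtest(k, 400, prev).proportion_ci(confidence_level=0.999)
            assert ci.low <= prev <= ci.high or abs(k / 400 - prev) < 0.07

    def test_full_signal_concentrates_in_clades(self):
        """With signal 1, threat counts are phylogenetically autocorrelated
        (positive Moran's I) in the vast majority of replicates."""
        hits = 0
        reps = 60
        for s in range(reps):
            cfg = SyntheticConfig(n_species=60, threat_signal=1.0, seed=1000 + s)
            tree = simulate_tree(cfg)
            inc = simulate_threats(tree, cfg, np.random.default_rng(2000 + s))
            counts = threat_counts(inc)
            if counts.std() == 0:
                continue
            W = build_proximity("phylogenetic", tree)
            hits += morans_i(counts, W, n_perm=9, seed=0).statistic > 0
        assert hits / reps > 0.9

    def test_same_seed_identical_matrix(self):
        cfg = SyntheticConfig(n_species=30, seed=3)
        tree = simulate_tree(cfg)
        a = simulate_threats(tree, cfg, np.random.default_rng(7))
        b = simulate_threats(tree, cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)


class TestSimulateRisk:
    def test_zero_slope_independent_of_counts(self):
        cfg = SyntheticConfig(n_species=2000, risk_slope=0.0, dd_fraction=0.0, seed=4)
        counts = pd.Series(
            np.random.default_rng(0).poisson(2, 2000),
            index=[f"s{i}" for i in range(2000)],
        )
        risk = simulate_risk(counts, cfg, np.random.default_rng(1))
        from scipy.stats import spearmanr

        rho, p = spearmanr(counts.values, risk.map(
            {c: i for i, c in enumerate(IUCN_CATEGORIES)}).values)
        assert abs(rho) < 0.06

    def test_large_slope_couples_counts_to_rank(self):
        cfg = SyntheticConfig(n_species=500, risk_slope=3.0, dd_fraction=0.0, seed=5)
        counts = pd.Series(
            np.random.default_rng(2).poisson(3, 500),
            index=[f"s{i}" for i in range(500)],
        )
        risk = simulate_risk(counts, cfg, np.random.default_rng(3))
        from scipy.stats import spearmanr

        rho, _ = spearmanr(counts.values, risk.map(
            {c: i for i, c in enumerate(IUCN_CATEGORIES)}).values)
        assert rho > 0.6

    def test_dd_fraction_zero_means_no_dd(self):
        cfg = SyntheticConfig(n_species=200, dd_fraction=0.0, seed=6)
        counts = pd.Series(np.zeros(200), index=[f"s{i}" for i in range(200)])
        risk = simulate_risk(counts, cfg, np.random.default_rng(4))
        assert (risk != DATA_DEFICIENT).all()


class TestDeepClades:
    def test_disjoint_cover_of_all_tips(self, random_tree_factory):
        tree = random_tree_factory(50, seed=31)
        clades = deep_clades(tree, 8)
        all_tips = [t for members in clades.values() for t in members]
        assert len(all_tips) == len(set(all_tips)) == tree.n_tips
        validate_clade_map(tree, clades)  # every clade monophyletic


class TestGenerateDataset:
    def test_bundle_passes_all_readers(self, tmp_path):
        ds = generate_dataset(SyntheticConfig(n_species=30, seed=8))
        paths = ds.write(tmp_path / "bundle")
        tree = Phylogeny.from_file(paths["tree"])
        risk = read_risk_csv(paths["risk"])
        threats = pd.read_csv(paths["threats"], index_col=0)
        assert set(risk.index) == set(tree.tip_labels)
        assert list(threats.columns) == list(THREAT_CLASSES)
        assert set(threats.index) == set(tree.tip_labels)
        from phylothreat import read_clade_map

        clades = read_clade_map(paths["clades"])
        validate_clade_map(tree, clades)

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        a = generate_dataset(SyntheticConfig(n_species=20, seed=9)).write(tmp_path / "a")
        b = generate_dataset(SyntheticConfig(n_species=20, seed=9)).write(tmp_path / "b")
        for key in ("tree", "risk", "threats", "areas", "habitats", "clades"):
            assert open(a[key], "rb").read() == open(b[key], "rb").read()

    def test_cross_references_resolve(self, small_dataset):
        ds = small_dataset
        tips = set(ds.tree.tip_labels)
        assert set(ds.risk.index) == tips
        assert set(ds.threats.index) == tips
        assert set(ds.areas.index) == tips
        assert set(ds.habitats.index) == tips
        assert set().union(*ds.clades.values()) == tips

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_species=2)
        with pytest.raises(ValueError):
            SyntheticConfig(threat_signal=1.5)
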