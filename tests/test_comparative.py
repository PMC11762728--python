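import numpy as np
import pandas as pd
import pytest

import divelev as dl
from divelev.comparative import (
    asr_bm,
    bm_covariance,
    genus_temp_pref,
    lambda_transform,
    pagel_lambda,
)

from conftest import random_chronogram


def dense_rerooted_gls(tree, trait):
    """Independent oracle: for every internal node, re-root the tree there
    (dendropy), build the BM covariance from scratch via patristic paths,
    and solve the GLS normal equations with a dense inverse."""
    y_all = trait
    results = []
    dtree0 = tree.tree
    internal = [n for n in dtree0.preorder_node_iter() if not n.is_leaf()]
    # sigma2 from the unrooted-invariant ML at the original root
    C, taxa = bm_covariance(tree)
    y = y_all.loc[taxa].to_numpy(float)
    Cinv = np.linalg.inv(C)
    one = np.ones(len(y))
    mu = one @ Cinv @ y / (one @ Cinv @ one)
    sigma2 = (y - mu) @ Cinv @ (y - mu) / len(y)
    for idx in range(len(internal)):
        t2 = tree.tree.extract_tree()
        node = [n for n in t2.preorder_node_iter() if not n.is_leaf()][idx]
        if node.parent_node is not None:
            t2.reroot_at_node(node)
        # covariance on the re-rooted tree: shared root-to-MRCA path,
        # reconstructed from patristic distances and root-to-tip depths
        leaves = sorted(t2.leaf_node_iter(), key=lambda l: l.taxon.label)
        labels = [lf.taxon.label for lf in leaves]
        k = len(labels)
        C2 = np.zeros((k, k))
        # root-to-tip distances
        depth = {}
        for lf in leaves:
            d, n2 = 0.0, lf
            while n2.parent_node is not None:
                d += n2.edge.length or 0.0
                n2 = n2.parent_node
            depth[lf.taxon.label] = d
        import dendropy

        pdmat = dendropy.PhylogeneticDistanceMatrix.from_tree(t2)
        tx = {t.label: t for t in t2.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    C2[i, i] = depth[a]
                else:
                    patristic = pdmat.patristic_distance(tx[a], tx[b])
                    C2[i, j] = (depth[a] + depth[b] - patristic) / 2.0
        yv = y_all.loc[labels].to_numpy(float)
        Ci = np.linalg.inv(C2)
        o = np.ones(k)
        est = o @ Ci @ yv / (o @ Ci @ o)
        var = sigma2 / (o @ Ci @ o)
        results.append((est, var))
    return results


class TestGenusTempPref:
    def test_mean_over_bands(self):
        records = pd.DataFrame(
            {"gradient_id": ["g1", "g1"], "genus": ["A", "A"],
             "elevation_m": [100.0, 300.0], "dataset_class": ["all", "all"]}
        )
        stats = pd.DataFrame(
            {"gradient_id": ["g1", "g1"], "elevation_m": [100.0, 300.0],
             "bio1": [10.0, 14.0]}
        )
        pref, dropped = genus_temp_pref(records, stats)
        assert pref["A"] == pytest.approx(12.0)
        assert not dropped

    def test_single_band(self):
        records = pd.DataFrame(
            {"gradient_id": ["g1"], "genus": ["B"], "elevation_m": [100.0],
             "dataset_class": ["all"]}
        )
        stats = pd.DataFrame(
            {"gradient_id": ["g1"], "elevation_m": [100.0], "bio1": [7.5]}
        )
        pref, _ = genus_temp_pref(records, stats)
        assert pref["B"] == 7.5

    def test_genus_without_climate_logged(self):
        records = pd.DataFrame(
            {"gradient_id": ["g1", "g1"], "genus": ["A", "B"],
             "elevation_m": [100.0, 900.0], "dataset_class": ["all", "all"]}
        )
        stats = pd.DataFrame(
            {"gradient_id": ["g1", "g1"], "elevation_m": [100.0, 900.0],
             "bio1": [10.0, np.nan]}
        )
        pref, dropped = genus_temp_pref(records, stats)
        assert dropped == ["B"] and "B" not in pref.index

    def test_matches_groupby_oracle(self, synth_data, synth_result):
        d, res = synth_data, synth_result
        band = res.band_stats[res.band_stats.dataset_class == "all"]
        rec = d.records[d.records.dataset_class == "all"].drop_duplicates()
        pref, _ = genus_temp_pref(rec, band)
        merged = rec.merge(band, on=["gradient_id", "elevation_m"])
        oracle = merged.groupby("genus")["bio1"].mean()
        for g in pref.index:
            assert pref[g] == pytest.approx(oracle[g])


class TestLambdaTransform:
    def test_identity_at_one(self):
        tree = random_chronogram(2, n_tips=6)
        C, _ = bm_covariance(tree)
        assert np.allclose(lambda_transform(C, 1.0), C)

    def test_star_at_zero(self):
        tree = random_chronogram(2, n_tips=6)
        C, _ = bm_covariance(tree)
        T = lambda_transform(C, 0.0)
        assert np.allclose(T, np.diag(np.diag(C)))

    def test_half_scales_offdiagonals_exactly(self):
        tree = dl.read_newick_string("(((A:1,B:1):1,C:2):1,D:3);")
        C, _ = bm_covariance(tree)
        T = lambda_transform(C, 0.5)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(T[off], 0.5 * C[off])
        assert np.allclose(np.diag(T), np.diag(C))

    def test_domain(self):
        C = np.eye(3)
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                lambda_transform(C, bad)


class TestBmCovariance:
    def test_hand_values(self):
        tree = dl.read_newick_string("((A:3,B:3):7,C:10);")
        C, taxa = bm_covariance(tree)
        idx = {t: i for i, t in enumerate(taxa)}
        assert C[idx["A"], idx["A"]] == pytest.approx(10.0)
        assert C[idx["A"], idx["B"]] == pytest.approx(7.0)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)


class TestPagelLambda:
    def test_bm_trait_recovers_high_lambda(self):
        lams = []
        for seed in range(12):
            tree = random_chronogram(seed + 100, n_tips=150)
            trait = dl.synth.simulate_trait(
                tree, dl.SynthConfig(seed=seed, trait_sigma2=0.05, trait_lambda=1.0)
            )
            lams.append(pagel_lambda(tree, trait).lam)
        assert np.mean(lams) >= 0.9

    def test_iid_trait_gives_low_lambda(self):
        hits = 0
        for seed in range(12):
            tree = random_chronogram(seed + 300, n_tips=150)
            rng = np.random.default_rng(seed)
            trait = pd.Series(rng.normal(10, 3, tree.n_tips), index=tree.tip_labels)
            fit = pagel_lambda(tree, trait)
            hits += fit.lam <= 0.1
        assert hits >= 10  # >= 90% would be 10.8 of 12

    def test_loglik_at_optimum_dominates_grid(self):
        tree = random_chronogram(5, n_tips=60)
        trait = dl.synth.simulate_trait(
            tree, dl.SynthConfig(seed=5, trait_sigma2=0.05, trait_lambda=0.6)
        )
        fit = pagel_lambda(tree, trait)
        from divelev.comparative import _profile_loglik

        C, taxa = bm_covariance(tree, list(trait.index))
        y = trait.loc[taxa].to_numpy(float)
        grid = [_profile_loglik(lambda_transform(C, l), y)[0]
                for l in np.linspace(0, 1, 101)]
        assert fit.loglik >= max(grid) - 0.01
        assert fit.loglik >= fit.loglik_zero
        assert fit.loglik >= fit.loglik_one
        assert fit.lr_stat >= 0

    def test_too_few_tips(self):
        tree = dl.read_newick_string("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            pagel_lambda(tree, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))


class TestAsrBm:
    def test_constant_tips_constant_nodes(self):
        tree = random_chronogram(6, n_tips=12)
        trait = pd.Series(4.2, index=tree.tip_labels)
        res = asr_bm(tree, trait)
        assert np.allclose(res.estimates["estimate"], 4.2)
        assert (res.estimates["variance"] > 0).all()

    def test_two_tip_closed_form(self):
        tree = dl.read_newick_string("(A:1,B:2);")
        res = asr_bm(tree, pd.Series({"A": 0.0, "B": 3.0}))
        # inverse-branch-length weighting: (0/1 + 3/2) / (1/1 + 1/2) = 1.0
        assert res.estimates.iloc[0]["estimate"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_rerooted_gls_oracle(self, seed):
        tree = random_chronogram(seed + 40, n_tips=8)
        rng = np.random.default_rng(seed)
        trait = pd.Series(rng.normal(10, 2, 8), index=tree.tip_labels)
        res = asr_bm(tree, trait)
        oracle = dense_rerooted_gls(tree, trait)
        assert len(oracle) == len(res.estimates)
        for (est, var), row in zip(oracle, res.estimates.itertuples(index=False)):
            assert row.estimate == pytest.approx(est, abs=1e-8)
            assert row.variance == pytest.approx(var, rel=1e-6)

    def test_shift_and_scale_equivariance(self):
        tree = random_chronogram(12, n_tips=15)
        rng = np.random.default_rng(12)
        trait = pd.Series(rng.normal(0, 1, 15), index=tree.tip_labels)
        base = asr_bm(tree, trait).estimates["estimate"].to_numpy()
        shifted = asr_bm(tree, trait + 7.0).estimates["estimate"].to_numpy()
        scaled = asr_bm(tree, trait * 3.0).estimates["estimate"].to_numpy()
        assert np.allclose(shifted, base + 7.0)
        assert np.allclose(scaled, base * 3.0)

    def test_estimates_within_tip_range(self):
        for seed in range(5):
            tree = random_chronogram(seed + 60, n_tips=25)
            rng = np.random.default_rng(seed)
            trait = pd.Series(rng.normal(5, 4, 25), index=tree.tip_labels)
            res = asr_bm(tree, trait)
            assert (res.estimates["estimate"] >= trait.min() - 1e-9).all()
            assert (res.estimates["estimate"] <= trait.max() + 1e-9).all()

    def test_ci_contains_estimate_once_per_node(self):
        tree = random_chronogram(8, n_tips=20)
        rng = np.random.default_rng(8)
        trait = pd.Series(rng.normal(8, 2, 20), index=tree.tip_labels)
        res = asr_bm(tree, trait)
        e = res.estimates
        n_internal = sum(1 for n in tree.tree.preorder_node_iter() if not n.is_leaf())
        assert len(e) == n_internal == e["node_id"].nunique()
        assert ((e["ci_low"] <= e["estimate"]) & (e["estimate"] <= e["ci_high"])).all()

    def test_missing_tip_value_rejected(self):
        tree = dl.read_newick_string("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            asr_bm(tree, pd.Series({"A": 1.0, "B": 2.0}))

    def test_annotated_newick_carries_estimates(self):
        tree = random_chronogram(3, n_tips=6)
        rng = np.random.default_rng(3)
        trait = pd.Series(rng.normal(10, 2, 6), index=tree.tip_labels)
        res = asr_bm(tree, trait)
        nwk = res.annotated_newick(tree)
        root_est = res.estimates.iloc[0]["estimate"]
        assert f"{root_est:.4f}" in nwk
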