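"""Coexpression network: adjacency, TOM, modules, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cernascout import coexpression as coex

from conftest import make_dataset


def two_block_dataset(rng, sizes=(50, 40), n_noise=10, n_samples=200, cor=0.9):
    """Latent-factor data with two blocks of within-block correlation ~cor."""
    lam = np.sqrt(cor)
    blocks = []
    truth = []
    for b, size in enumerate(sizes, start=1):
        f = rng.normal(size=n_samples)
        x = lam * f[None, :] + np.sqrt(1 - cor) * rng.normal(size=(size, n_samples))
        blocks.append(x)
        truth += [b] * size
    blocks.append(rng.normal(size=(n_noise, n_samples)))
    truth += [0] * n_noise
    return make_dataset(np.vstack(blocks), n_control=n_samples // 2), np.array(truth)


class TestOutlierRemoval:
    def test_constructed_outlier_removed(self, rng):
        x = rng.normal(size=(20, 11)) * 0.01
        x[:, 10] += 100.0
        ds = make_dataset(x, n_control=5)
        trimmed, removed = coex.remove_outlier_samples(ds)
        assert removed == [ds.sample_ids[10]]
        assert trimmed.n_samples == 10

    def test_identical_samples_none_removed(self):
        ds = make_dataset(np.ones((5, 6)), n_control=3)
        _, removed = coex.remove_outlier_samples(ds)
        assert removed == []

    def test_no_dominant_cluster_skips_removal(self, rng):
        # two equal tight groups far apart: splitting would discard half
        x = np.concatenate(
            [rng.normal(size=(30, 10)) * 0.01, rng.normal(size=(30, 10)) * 0.01 + 50],
            axis=1,
        )
        ds = make_dataset(x, n_control=10)
        _, removed = coex.remove_outlier_samples(ds)
        assert removed == []


class TestAdjacencyAndTom:
    def test_adjacency_bounds_symmetry_zero_diagonal(self, rng):
        ds = make_dataset(rng.normal(size=(15, 30)), n_control=15)
        a = coex.correlation_adjacency(ds, 6).to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        np.testing.assert_allclose(a, a.T)
        assert np.diag(a).sum() == 0

    def test_triangle_of_ones_tom_is_one(self):
        a = pd.DataFrame(np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]]),
                         index=list("abc"), columns=list("abc"))
        tom = coex.tom_similarity(a).to_numpy()
        np.testing.assert_allclose(tom, np.ones((3, 3)))

    def test_isolated_nodes_tom_zero(self):
        a = pd.DataFrame(np.zeros((2, 2)), index=list("ab"), columns=list("ab"))
        tom = coex.tom_similarity(a).to_numpy()
        assert tom[0, 1] == 0.0 and tom[1, 0] == 0.0

    def test_matches_bruteforce_double_loop(self, rng):
        n = 8
        raw = rng.uniform(size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        adf = pd.DataFrame(a, index=[f"n{i}" for i in range(n)],
                           columns=[f"n{i}" for i in range(n)])
        tom = coex.tom_similarity(adf).to_numpy()
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    expected = 1.0
                else:
                    shared = sum(a[i, u] * a[u, j] for u in range(n))
                    expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_tom_bounds_on_random_matrices(self, rng):
        for _ in range(5):
            raw = rng.uniform(size=(20, 20))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            ids = [f"n{i}" for i in range(20)]
            tom = coex.tom_similarity(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
            assert ((tom >= -1e-12) & (tom <= 1 + 1e-12)).all()


class TestSoftThreshold:
    def test_mean_connectivity_strictly_decreases(self, rng):
        ds = make_dataset(rng.normal(size=(40, 25)), n_control=12)
        _, fit = coex.pick_soft_threshold(ds, betas=[1, 2, 4, 6, 8])
        assert (np.diff(fit["mean_k"]) < 0).all()

    def test_equal_connectivity_degenerate_fit_is_nan(self):
        # all nodes identical -> one occupied bin -> undefined fit
        assert np.isnan(coex._scale_free_fit(np.ones(30)))

    def test_scale_free_network_reaches_goal(self, rng):
        # hub-and-spoke latent structure produces a heavy-tailed degree
        # distribution for which some candidate power fits well
        n, s = 200, 100
        f = rng.normal(size=s)
        lam = rng.uniform(0, 1, size=n) ** 2
        x = lam[:, None] * f[None, :] + rng.normal(size=(n, s))
        ds = make_dataset(x, n_control=50)
        beta, fit = coex.pick_soft_threshold(ds)
        assert beta in fit["beta"].to_numpy()
        assert np.nanmax(fit["signed_r2"].to_numpy()) > 0


class TestModuleDetection:
    def test_two_planted_blocks_recovered_exactly(self):
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds, truth = two_block_dataset(rng)
            adj = coex.correlation_adjacency(ds, 6)
            tom = coex.tom_similarity(adj)
            part = coex.detect_modules(tom, min_module_size=30, deep_split=2)
            aris.append(adjusted_rand_score(truth, part.labels.to_numpy()))
        assert np.mean(aris) >= 0.9

    def test_min_module_size_larger_than_n_gives_module_zero(self, rng):
        ds = make_dataset(rng.normal(size=(10, 20)), n_control=10)
        tom = coex.tom_similarity(coex.correlation_adjacency(ds, 6))
        part = coex.detect_modules(tom, min_module_size=50, deep_split=2)
        assert (part.labels == 0).all()

    def test_deeper_split_never_fewer_raw_clusters(self, rng):
        ds, _ = two_block_dataset(rng, sizes=(20, 15), n_noise=5, n_samples=80)
        tom = coex.tom_similarity(coex.correlation_adjacency(ds, 6))
        n_clusters = []
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        d = 1.0 - tom.to_numpy()
        np.fill_diagonal(d, 0.0)
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        h = link[:, 2]
        for ds_level in (0, 1, 2, 3, 4):
            cut = h.min() + coex.DEEP_SPLIT_Q[ds_level] * (h.max() - h.min())
            n_clusters.append(
                len(set(hierarchy.fcluster(link, t=cut, criterion="distance")))
            )
        assert (np.diff(n_clusters) >= 0).all()

    def test_label_equivariance_under_feature_permutation(self, rng):
        ds, truth = two_block_dataset(rng, sizes=(20, 15), n_noise=5, n_samples=100)
        perm = rng.permutation(ds.n_features)
        ds_perm = make_dataset(ds.values.to_numpy()[perm], n_control=50,
                               feature_ids=[ds.feature_ids[i] for i in perm])
        tom = coex.tom_similarity(coex.correlation_adjacency(ds, 6))
        tom_p = coex.tom_similarity(coex.correlation_adjacency(ds_perm, 6))
        part = coex.detect_modules(tom, min_module_size=10, deep_split=2)
        part_p = coex.detect_modules(tom_p, min_module_size=10, deep_split=2)
        merged = part.labels.reindex(part_p.labels.index)
        assert adjusted_rand_score(merged.to_numpy(), part_p.labels.to_numpy()) == 1.0


class TestEigengene:
    def test_identical_members_give_shared_z_profile(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        ds = make_dataset(np.tile(profile, (4, 1)), n_control=2)
        part = coex.ModulePartition(labels=pd.Series(1, index=ds.feature_ids))
        me = coex.module_eigengene(ds, part)["ME1"].to_numpy()
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me, z, atol=1e-10)

    def test_sign_flip_of_members_leaves_eigengene_invariant(self, rng):
        x = rng.normal(size=(6, 30))
        ds = make_dataset(x, n_control=15)
        ds_flip = make_dataset(-x, n_control=15)
        labels = pd.Series(1, index=ds.feature_ids)
        me = coex.module_eigengene(ds, coex.ModulePartition(labels=labels.copy()))
        me_flip = coex.module_eigengene(
            ds_flip, coex.ModulePartition(labels=labels.copy())
        )
        np.testing.assert_allclose(
            np.abs(me["ME1"].to_numpy()), np.abs(me_flip["ME1"].to_numpy()), atol=1e-8
        )

    def test_matches_direct_svd_oracle(self, rng):
        x = rng.normal(size=(5, 40))
        ds = make_dataset(x, n_control=20)
        part = coex.ModulePartition(labels=pd.Series(1, index=ds.feature_ids))
        me = coex.module_eigengene(ds, part)["ME1"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        ref = vt[0]
        ref = (ref - ref.mean()) / ref.std(ddof=1)
        agree = min(np.abs(me - ref).max(), np.abs(me + ref).max())
        assert agree < 1e-10

    def test_rayleigh_property_eigengene_explains_most_variance(self, rng):
        x = rng.normal(size=(8, 50))
        ds = make_dataset(x, n_control=25)
        part = coex.ModulePartition(labels=pd.Series(1, index=ds.feature_ids))
        me = coex.module_eigengene(ds, part)["ME1"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)

        def explained(v):
            v = v / np.linalg.norm(v)
            return ((z @ v) ** 2).sum()

        var_me = explained(me)
        for row in z:
            assert var_me >= explained(row) - 1e-9


class TestConnectivityAndHubs:
    def test_k_within_counts_co_members(self):
        ids = list("abcd")
        a = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids)
        part = coex.ModulePartition(labels=pd.Series([1, 1, 1, 1], index=ids))
        kw = coex.intramodular_connectivity(a, part)
        np.testing.assert_allclose(kw.to_numpy(), [3.0, 3.0, 3.0, 3.0])

    def test_singleton_module_zero_connectivity(self):
        ids = list("abc")
        a = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids, columns=ids)
        part = coex.ModulePartition(labels=pd.Series([1, 1, 2], index=ids))
        kw = coex.intramodular_connectivity(a, part)
        assert kw["c"] == 0.0

    def test_k_within_bounded_by_total_k(self, rng):
        n = 30
        raw = rng.uniform(size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        ids = [f"n{i}" for i in range(n)]
        adf = pd.DataFrame(a, index=ids, columns=ids)
        labels = pd.Series(rng.integers(1, 4, size=n), index=ids)
        kw = coex.intramodular_connectivity(adf, coex.ModulePartition(labels=labels))
        k_total = adf.sum(axis=1)
        assert (kw <= k_total + 1e-12).all()

    def test_single_lncrna_module_returns_it(self):
        ids = ["mRNA:a", "mRNA:b", "lncRNA:x"]
        a = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids, columns=ids)
        part = coex.ModulePartition(labels=pd.Series([1, 1, 1], index=ids))
        kw = coex.intramodular_connectivity(a, part)
        biotype = pd.Series(["mRNA", "mRNA", "lncRNA"], index=ids)
        hubs = coex.select_hub_lncrna(part, kw, biotype, adjacency=a)
        assert hubs.loc[0, "hub"] == "lncRNA:x"

    def test_tie_broken_by_meta_p(self):
        ids = ["lncRNA:x", "lncRNA:y", "mRNA:a"]
        a = pd.DataFrame([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]],
                         index=ids, columns=ids, dtype=float)
        part = coex.ModulePartition(labels=pd.Series([1, 1, 1], index=ids))
        kw = coex.intramodular_connectivity(a, part)
        biotype = pd.Series(["lncRNA", "lncRNA", "mRNA"], index=ids)
        meta = pd.DataFrame({"p_comb_adj": [0.2, 0.001], "T_comb": [1.0, 2.0]},
                            index=["lncRNA:x", "lncRNA:y"])
        hubs = coex.select_hub_lncrna(part, kw, biotype, meta_table=meta, adjacency=a)
        assert hubs.loc[0, "hub"] == "lncRNA:y"

    def test_module_without_lncrna_reported_hubless(self):
        ids = ["mRNA:a", "mRNA:b"]
        a = pd.DataFrame([[0, 1.0], [1.0, 0]], index=ids, columns=ids)
        part = coex.ModulePartition(labels=pd.Series([1, 1], index=ids))
        kw = coex.intramodular_connectivity(a, part)
        hubs = coex.select_hub_lncrna(part, kw, pd.Series("mRNA", index=ids))
        assert hubs.loc[0, "hub"] is None

    def test_planted_hub_selected_across_seeds(self):
        # one module: hub lncRNA loading 1.2 vs 0.6 for other lncRNAs
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_samples = 100
            f = rng.normal(size=n_samples)
            ids = [f"mRNA:m{i}" for i in range(40)] + [f"lncRNA:l{i}" for i in range(5)]
            lam = np.array([0.6] * 44 + [1.2])
            x = lam[:, None] * f[None, :] + rng.normal(size=(45, n_samples))
            ds = make_dataset(x, n_control=50, feature_ids=ids)
            biotype = pd.Series(["mRNA"] * 40 + ["lncRNA"] * 5, index=ids)
            adj = coex.correlation_adjacency(ds, 6)
            part = coex.ModulePartition(labels=pd.Series(1, index=ids))
            kw = coex.intramodular_connectivity(adj, part)
            hubs = coex.select_hub_lncrna(part, kw, biotype, adjacency=adj)
            hits += hubs.loc[0, "hub"] == "lncRNA:l4"
        assert hits >= 19
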