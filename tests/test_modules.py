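import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from amspipe.modules import (IntegratedMatrix, ams_modules, concatenate_omics,
                             dynamic_tree_cut, merge_close_modules,
                             module_eigengene, module_trait_association,
                             spearman_dissimilarity, ward_cluster)
from amspipe.preprocess import log2_transform

from conftest import make_matrix


def block_matrix(rng, n_samples, block_sizes, within_load=0.8, noise=0.7):
    """Latent-factor block data; returns (values, true labels)."""
    cols, labels = [], []
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            cols.append(within_load * f + noise * rng.standard_normal(n_samples))
            labels.append(b + 1)
    return np.column_stack(cols), np.array(labels)


class TestConcatenate:
    def test_dimensions(self, integrated_default):
        x, _, _ = integrated_default
        assert x.values.shape == (66, 429 + 984)
        assert x.omic_of_feature[:429] == ["protein"] * 429

    def test_feature_order_stable(self, rng):
        p = make_matrix(rng.normal(size=(5, 3)), omic="protein", scale="log2")
        m = make_matrix(rng.normal(size=(5, 2)), omic="metabolite", scale="log2",
                        prefix="X")
        x = concatenate_omics(p, m)
        assert x.features == ["protein:F0", "protein:F1", "protein:F2",
                              "metabolite:X0", "metabolite:X1"]

    def test_disjoint_samples_error(self, rng):
        p = make_matrix(rng.normal(size=(3, 2)), scale="log2")
        m = make_matrix(rng.normal(size=(3, 2)), omic="metabolite", scale="log2")
        m.samples = ["a", "b", "c"]
        with pytest.raises(ValueError, match="no samples"):
            concatenate_omics(p, m)

    def test_common_subset_order(self, rng):
        p = make_matrix(rng.normal(size=(4, 2)), scale="log2")
        m = make_matrix(rng.normal(size=(3, 2)), omic="metabolite", scale="log2")
        # metabolite matrix lacks S3
        x = concatenate_omics(p, m)
        assert x.samples == ["S0", "S1", "S2"]


class TestSpearmanDissimilarity:
    def test_self_zero_and_bounds(self, rng):
        d = spearman_dissimilarity(rng.normal(size=(10, 6)))
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 2.0
        assert np.allclose(d, d.T)

    def test_antimonotone_pair(self):
        x = np.column_stack([np.arange(10.0), -np.arange(10.0)])
        x = x + 0  # two perfectly anti-monotone features
        d = spearman_dissimilarity(np.column_stack([x[:, 0], x[:, 1],
                                                    np.random.default_rng(0).normal(size=10)]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_rank_arithmetic(self):
        # x={1,2,3}, y={1,3,2}: rho = 0.5 -> d = 0.5
        vals = np.column_stack([[1, 2, 3], [1, 3, 2], [3, 1, 2]])
        d = spearman_dissimilarity(vals.astype(float))
        assert d[0, 1] == pytest.approx(0.5)

    def test_constant_feature_named(self, rng):
        vals = rng.normal(size=(8, 3))
        vals[:, 1] = 4.0
        with pytest.raises(ValueError, match="1"):
            spearman_dissimilarity(vals)


def naive_ward(d):
    """O(n^3) Lance-Williams agglomeration on squared dissimilarities with
    square-rooted heights (ward.D2).  Returns merge list [(set, height)]."""
    d2 = d.astype(float) ** 2
    clusters = {i: frozenset([i]) for i in range(d.shape[0])}
    dist = {frozenset([i, j]): d2[i, j] for i in range(d.shape[0])
            for j in range(i + 1, d.shape[0])}
    merges = []
    next_id = d.shape[0]
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        a, b = sorted(pair)
        h2 = dist[pair]
        sa, sb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] | clusters[b]
        merges.append((merged, np.sqrt(h2)))
        del clusters[a], clusters[b]
        new_dists = {}
        for c, members in clusters.items():
            sc = len(members)
            dac = dist[frozenset([a, c])]
            dbc = dist[frozenset([b, c])]
            new = ((sa + sc) * dac + (sb + sc) * dbc - sc * h2) / (sa + sb + sc)
            new_dists[c] = new
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        clusters[next_id] = merged
        for c, v in new_dists.items():
            dist[frozenset([next_id, c])] = v
        next_id += 1
    return merges


class TestWard:
    def test_heights_nondecreasing(self, rng):
        d = spearman_dissimilarity(rng.normal(size=(20, 30)))
        Z = ward_cluster(d)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_two_blocks_final_merge_tallest(self, rng):
        vals, _ = block_matrix(rng, 30, [10, 10])
        d = spearman_dissimilarity(vals)
        Z = ward_cluster(d)
        assert Z[-1, 2] > 1.5 * Z[-2, 2]

    def test_asymmetric_rejected(self, rng):
        d = rng.random((4, 4))
        with pytest.raises(ValueError):
            ward_cluster(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 13)
        vals = rng.normal(size=(15, n))
        d = spearman_dissimilarity(vals)
        Z = ward_cluster(d)
        oracle = naive_ward(d)
        # same heights
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(h for _, h in oracle),
                                   rtol=1e-8)
        # same merged leaf sets
        from amspipe.modules import _subtree_leaves
        leaves = _subtree_leaves(Z, n)
        mine = {frozenset(leaves[n + k].tolist()) for k in range(Z.shape[0])}
        assert mine == {s for s, _ in oracle}


class TestDynamicTreeCut:
    def test_planted_blocks_recovered(self, rng):
        vals, labels = block_matrix(rng, 66, [60] * 6)
        d = spearman_dissimilarity(vals)
        a = dynamic_tree_cut(ward_cluster(d), d, min_cluster_size=45)
        assert adjusted_rand_score(labels, a) >= 0.9

    def test_single_block_one_module(self, rng):
        vals, _ = block_matrix(rng, 66, [100])
        d = spearman_dissimilarity(vals)
        a = dynamic_tree_cut(ward_cluster(d), d, min_cluster_size=45)
        assert set(a) == {1}

    def test_pure_noise_mostly_unassigned(self):
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.standard_normal((66, 300))
            d = spearman_dissimilarity(vals)
            a = dynamic_tree_cut(ward_cluster(d), d, min_cluster_size=45)
            fractions.append(np.mean(a == 0))
        assert all(f >= 0.8 for f in fractions)

    def test_min_size_bound(self, rng):
        vals = rng.normal(size=(10, 20))
        d = spearman_dissimilarity(vals)
        with pytest.raises(ValueError, match="min_cluster_size"):
            dynamic_tree_cut(ward_cluster(d), d, min_cluster_size=11)


class TestEigengene:
    def test_identical_features(self, rng):
        profile = rng.standard_normal(20)
        vals = np.column_stack([profile, 2 * profile + 3])  # identical z-profiles
        e = module_eigengene(vals, [0, 1])
        z = (profile - profile.mean()) / profile.std()
        corr = np.corrcoef(e, z)[0, 1]
        assert corr == pytest.approx(1.0)

    def test_unit_norm_and_sign(self, integrated_default, default_cohort):
        x, _, truth = integrated_default
        members = [i for i, f in enumerate(x.features)
                   if truth.module_of_feature[f.split(":", 1)[1]] == "M1"]
        e = module_eigengene(x.values, members)
        assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-9)
        z = (x.values[:, members] - x.values[:, members].mean(0)) / x.values[:, members].std(0)
        assert np.dot(e, z.mean(axis=1)) >= 0

    def test_variance_explained_optimal(self, rng):
        vals, _ = block_matrix(rng, 30, [12])
        members = list(range(12))
        e = module_eigengene(vals, members)
        z = (vals - vals.mean(0)) / vals.std(0)
        var_e = np.sum((z.T @ e) ** 2)
        for j in members:  # any single member profile as surrogate
            s = z[:, j] / np.linalg.norm(z[:, j])
            assert var_e >= np.sum((z.T @ s) ** 2) - 1e-9

    def test_sign_flip_symmetry(self, rng):
        vals, _ = block_matrix(rng, 25, [8])
        e1 = module_eigengene(vals, list(range(8)))
        e2 = module_eigengene(-vals, list(range(8)))
        np.testing.assert_allclose(e1, -e2, atol=1e-9)

    def test_constant_member_rejected(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(vals, [0, 1, 2])


class TestMergeCloseModules:
    def _integrated(self, vals):
        n, p = vals.shape
        return IntegratedMatrix(samples=[f"S{i}" for i in range(n)],
                                features=[f"F{j}" for j in range(p)],
                                values=vals, omic_of_feature=["protein"] * p)

    def test_same_factor_modules_merged(self, rng):
        f = rng.standard_normal(40)
        vals = np.column_stack([0.9 * f + 0.3 * rng.standard_normal(40)
                                for _ in range(20)])
        x = self._integrated(vals)
        assignment = np.r_[np.ones(10, int), np.full(10, 2, int)]
        ms = merge_close_modules(x, assignment, cut_height=0.4)
        assert len(ms.module_sizes) == 1
        assert ms.merge_history

    def test_orthogonal_modules_unchanged(self, rng):
        vals, labels = block_matrix(rng, 50, [10, 10])
        x = self._integrated(vals)
        ms = merge_close_modules(x, labels.copy(), cut_height=0.4)
        assert len(ms.module_sizes) == 2
        assert not ms.merge_history

    def test_count_never_increases(self, rng):
        vals, labels = block_matrix(rng, 40, [8, 8, 8])
        x = self._integrated(vals)
        ms = merge_close_modules(x, labels.copy(), cut_height=0.4)
        assert len(ms.module_sizes) <= 3
        # still a partition plus label-0 pool
        assert set(ms.assignment) <= {0, 1, 2, 3}


class TestModuleTrait:
    def test_perfect_correlation(self, rng):
        e = rng.standard_normal(30)
        eig = pd.DataFrame([e], index=["M1"], columns=[f"S{i}" for i in range(30)])
        traits = pd.DataFrame({"AMS_degree": e}, index=eig.columns)
        res = module_trait_association(eig, traits)
        row = res.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-20 and row["significant"]

    def test_pairwise_complete_and_not_computable(self, rng):
        e = rng.standard_normal(30)
        eig = pd.DataFrame([e], index=["M1"], columns=[f"S{i}" for i in range(30)])
        sparse = np.full(30, np.nan)
        sparse[:3] = [1.0, 2.0, 3.0]
        traits = pd.DataFrame({"mostly_missing": sparse, "fine": e + rng.normal(size=30)},
                              index=eig.columns)
        res = module_trait_association(eig, traits).set_index("trait")
        assert np.isnan(res.loc["mostly_missing", "r"])
        assert res.loc["fine", "n"] == 30

    def test_null_false_positive_rate(self):
        hits, cells = 0, 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            eig = pd.DataFrame(rng.standard_normal((3, 40)),
                               index=["M1", "M2", "M3"],
                               columns=[f"S{i}" for i in range(40)])
            traits = pd.DataFrame(rng.standard_normal((40, 4)),
                                  columns=list("abcd"), index=eig.columns)
            res = module_trait_association(eig, traits)
            hits += int(res["significant"].sum())
            cells += len(res)
        assert hits / cells <= 0.05 + 0.02

    def test_fdr_family_switch(self, rng):
        eig = pd.DataFrame(rng.standard_normal((2, 20)), index=["M1", "M2"],
                           columns=[f"S{i}" for i in range(20)])
        traits = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"],
                              index=eig.columns)
        grid = module_trait_association(eig, traits, fdr_family="grid")
        per = module_trait_association(eig, traits, fdr_family="per-trait")
        assert (grid["p"] == per["p"]).all()
        with pytest.raises(ValueError):
            module_trait_association(eig, traits, fdr_family="bogus")


def test_planted_structure_recovery_flags_informative_modules(integrated_default,
                                                              default_cohort):
    from amspipe.matrix import CLINICAL_VARIABLES
    x, clinical, truth = integrated_default
    d = spearman_dissimilarity(x)
    a = dynamic_tree_cut(ward_cluster(d), d, min_cluster_size=45)
    ms = merge_close_modules(x, a, cut_height=0.4)
    truth_labels = [truth.module_of_feature[f.split(":", 1)[1]] for f in x.features]
    assert adjusted_rand_score(truth_labels, ms.assignment) >= 0.9
    traits = clinical.loc[x.samples, CLINICAL_VARIABLES + ["AMS_degree"]]
    flagged = set(ams_modules(module_trait_association(ms.eigengenes, traits)))
    # every module housing an informative feature is flagged
    import collections
    for tm in {truth.module_of_feature[f] for f in truth.informative_features}:
        idx = [i for i, lab in enumerate(truth_labels) if lab == tm]
        detected = collections.Counter(ms.assignment[idx]).most_common(1)[0][0]
        assert f"M{detected}" in flagged
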