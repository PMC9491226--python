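import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import block_matrix
from seragut.netcluster import (
    MODULE_COLORS,
    detect_modules,
    module_eigenfeatures,
    module_trait_association,
    pick_soft_threshold,
    signed_adjacency,
    topological_overlap,
)


def _ari(labels_a, labels_b):
    from scipy.special import comb

    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    n = comb(ct.sum(), 2)
    expected = sum_a * sum_b / n
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return float((sum_comb - expected) / (max_idx - expected))


class TestAdjacency:
    def test_hand_worked_powers(self):
        # two perfectly anticorrelated features: (1 + (-1))/2 = 0
        # two identical-up-to-scale features: (1 + 1)/2 = 1
        df = pd.DataFrame(
            {"s1": [1.0, -1.0, 2.0], "s2": [2.0, -2.0, 4.0], "s3": [3.0, -3.0, 6.0]},
            index=["a", "b", "c"],
        )
        a = signed_adjacency(df, beta=9)
        assert a.loc["a", "b"] == pytest.approx(0.0)
        assert a.loc["a", "c"] == pytest.approx(1.0)
        assert a.loc["a", "a"] == 0.0

    def test_half_correlation_power(self):
        # r = 0 gives (1/2)^beta
        rng = np.random.default_rng(0)
        n = 20000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        df = pd.DataFrame(np.vstack([x, y]), index=["x", "y"])
        a = signed_adjacency(df, beta=9)
        assert a.loc["x", "y"] == pytest.approx(0.5**9, rel=0.2)

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(1)
        a = signed_adjacency(pd.DataFrame(rng.normal(size=(15, 10))), beta=6)
        v = a.to_numpy()
        assert v.min() >= 0 and v.max() <= 1

    def test_constant_feature_rejected(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        with pytest.raises(ValueError, match="constant"):
            signed_adjacency(df, beta=6)


class TestTom:
    def test_hand_worked_three_nodes(self):
        # path graph a-b-c with unit edges:
        # w_ac = (a_ab*a_bc + a_ac) / (min(k_a,k_c) + 1 - a_ac) = 1/(1+1) = 0.5
        # w_ab = (0 + 1) / (min(1,2) + 1 - 1) = 1 (a's neighborhood is inside b's)
        a = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        w = topological_overlap(a).to_numpy()
        assert w[0, 2] == pytest.approx(0.5)
        assert w[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(w), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        r = np.corrcoef(rng.normal(size=(12, 30)))
        a = ((1 + r) / 2) ** 6
        np.fill_diagonal(a, 0.0)
        w = topological_overlap(a).to_numpy()
        n = a.shape[0]
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert w[i, j] == pytest.approx(expect, rel=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        r = np.corrcoef(rng.normal(size=(20, 30)))
        a = ((1 + r) / 2) ** 6
        np.fill_diagonal(a, 0.0)
        w = topological_overlap(a).to_numpy()
        assert np.allclose(w, w.T, atol=1e-12)
        assert w.min() >= 0 and w.max() <= 1 + 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(np.array([[0.0, 0.5], [0.4, 0.0]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            topological_overlap(np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestSoftThreshold:
    def test_planted_cluster_data_reaches_r2(self, scenario):
        # baseline samples of the 5-cluster planted metabolome qualify
        fm, info = scenario["metabolome"], scenario["info"]
        pre = info[(info["timepoint"] == "pre") & ~info["is_qc"]]
        sub = fm.subset_samples(list(pre.index))
        scan = pick_soft_threshold(sub, log2_transform=True)
        assert scan.chosen_beta is not None
        row = scan.scan[scan.scan["beta"] == scan.chosen_beta].iloc[0]
        assert row["signed_r2"] >= 0.85
        # smaller betas all fail the cut (smallest-qualifying rule)
        before = scan.scan[scan.scan["beta"] < scan.chosen_beta]
        assert (before["signed_r2"].fillna(-1) < 0.85).all()

    def test_pure_noise_rarely_qualifies(self):
        none = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = pd.DataFrame(rng.normal(size=(200, 50)))
            scan = pick_soft_threshold(data)
            if scan.chosen_beta is None:
                none += 1
        assert none >= 16

    def test_mean_connectivity_decreases_with_beta(self):
        rng = np.random.default_rng(4)
        data = block_matrix(rng, 3, 12, 10, 25)
        scan = pick_soft_threshold(data)
        mk = scan.scan["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mk) < 0)

    def test_minimum_feature_count(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="30 features"):
            pick_soft_threshold(pd.DataFrame(rng.normal(size=(10, 8))))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        data = block_matrix(rng, 3, 12, 10, 25)
        perm = rng.permutation(len(data))
        scan_a = pick_soft_threshold(data)
        scan_b = pick_soft_threshold(data.iloc[perm])
        assert scan_a.chosen_beta == scan_b.chosen_beta
        pd.testing.assert_frame_equal(scan_a.scan, scan_b.scan)


class TestDetectModules:
    def test_orthogonal_blocks_exact_recovery(self):
        # 3 planted blocks of 20 at within-r 0.9 and 100 samples: exactly
        # 3 modules, ARI 1 against truth, every seed
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            data = block_matrix(rng, n_blocks=3, block_size=20, n_noise=0,
                                n_samples=100, within_r=0.9)
            mods = detect_modules(data, beta=6, min_size=10)
            true = [f.split("_")[0] for f in data.index]
            assert len(mods.labels) == 3
            assert _ari(true, mods.assignment.to_numpy()) == 1.0

    def test_blocks_with_noise_high_ari(self):
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            data = block_matrix(rng, n_blocks=3, block_size=20, n_noise=30,
                                n_samples=60, within_r=0.8)
            mods = detect_modules(data, beta=6, min_size=10)
            block_feats = [f for f in data.index if f.startswith("B")]
            true = [f.split("_")[0] for f in block_feats]
            got = mods.assignment[block_feats].to_numpy()
            aris.append(_ari(true, got))
        assert min(aris) >= 0.8

    def test_pure_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            data = pd.DataFrame(rng.normal(size=(50, 30)),
                                index=[f"f{i}" for i in range(50)])
            mods = detect_modules(data, beta=6, min_size=10)
            fracs.append(float((mods.assignment == 0).mean()))
        assert np.mean(fracs) >= 0.9

    def test_colors_by_decreasing_size(self):
        rng = np.random.default_rng(7)
        data = pd.concat([
            block_matrix(rng, 1, 25, 0, 40, within_r=0.85),
            block_matrix(rng, 1, 12, 0, 40, within_r=0.85).set_axis(
                [f"C_{j}" for j in range(12)]),
        ])
        mods = detect_modules(data, beta=6, min_size=10)
        assert len(mods.labels) == 2
        sizes = {l: len(mods.members(l)) for l in mods.labels}
        assert sizes[1] >= sizes[2]
        assert mods.module_colors[1] == "turquoise"
        assert mods.module_colors[2] == "blue"
        assert mods.module_colors[0] == "grey"
        assert set(mods.eigenfeatures.index) == {"MEturquoise", "MEblue"}

    def test_kme_rescue_assigns_correlated_strays(self):
        rng = np.random.default_rng(8)
        data = block_matrix(rng, n_blocks=2, block_size=15, n_noise=0,
                            n_samples=40, within_r=0.9)
        # append weakly-block-0-correlated strays plus pure noise
        f0 = data.loc["B0_0"].to_numpy()
        extra = []
        for j in range(3):
            extra.append(0.55 * f0 + 0.8 * rng.normal(size=40))
        for j in range(3):
            extra.append(rng.normal(size=40))
        extra = pd.DataFrame(extra, index=[f"X_{j}" for j in range(6)])
        mods = detect_modules(pd.concat([data, extra]), beta=6, min_size=10)
        lab0 = mods.assignment["B0_0"]
        rescued = [mods.assignment[f"X_{j}"] for j in range(3)]
        assert all(l == lab0 for l in rescued)
        kme_rescued = mods.kme[[f"X_{j}" for j in range(3)]]
        assert (kme_rescued.abs() >= 0.3).all()

    def test_merge_joins_highly_correlated_modules(self):
        # two blocks on strongly correlated factors: separable branches whose
        # eigenfeatures correlate ~0.9, so they merge at the default height
        # but stay apart when merging is effectively disabled
        rng = np.random.default_rng(9)
        n = 60
        f = rng.normal(size=n)
        g = np.sqrt(0.81) * f + np.sqrt(0.19) * rng.normal(size=n)
        feats = {}
        for j in range(15):
            feats[f"B0_{j}"] = np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(size=n)
        for j in range(15):
            feats[f"B1_{j}"] = np.sqrt(0.9) * g + np.sqrt(0.1) * rng.normal(size=n)
        data = pd.DataFrame(feats).T
        unmerged = detect_modules(data, beta=6, min_size=10, merge_height=0.02)
        merged = detect_modules(data, beta=6, min_size=10, merge_height=0.25)
        assert len(unmerged.labels) == 2
        assert len(merged.labels) == 1

    def test_palette_has_40_unique_colors(self):
        assert len(MODULE_COLORS) == 40
        assert len(set(MODULE_COLORS)) == 40
        assert MODULE_COLORS[0] == "turquoise"
        assert "grey" not in MODULE_COLORS

    def test_scenario_metabolome_recovers_planted_clusters(self, scenario):
        # clusters are a study-wide property: detect on all 30 study samples
        fm, info, truth = scenario["metabolome"], scenario["info"], scenario["truth"]
        study = info[~info["is_qc"]]
        sub = fm.subset_samples(list(study.index))
        scan = pick_soft_threshold(sub, log2_transform=True)
        beta = scan.chosen_beta or 12
        mods = detect_modules(sub, beta=beta, min_size=10, log2_transform=True)
        planted = [f for mem in truth.planted_cluster_members.values() for f in mem]
        true = []
        for cid, mem in truth.planted_cluster_members.items():
            true.extend([cid] * len(mem))
        got = mods.assignment[planted].to_numpy()
        assert _ari(true, got) >= 0.8


class TestEigenfeatures:
    def test_var_explained_and_kme_high_for_tight_module(self):
        rng = np.random.default_rng(10)
        data = block_matrix(rng, 1, 20, 0, 30, within_r=0.9)
        assignment = pd.Series(1, index=data.index)
        eig, var_expl, kme = module_eigenfeatures(data, assignment)
        assert var_expl[1] > 0.7
        assert (kme[1].abs() > 0.7).all()
        e = eig.loc[1].to_numpy()
        assert e.mean() == pytest.approx(0.0, abs=1e-10)
        assert e.std(ddof=0) == pytest.approx(1.0)

    def test_sign_orientation_positive_mean_cor(self):
        rng = np.random.default_rng(11)
        data = block_matrix(rng, 1, 15, 0, 25, within_r=0.8)
        eig, _, kme = module_eigenfeatures(data, pd.Series(1, index=data.index))
        assert kme[1].mean() > 0

    def test_constant_member_dropped(self):
        rng = np.random.default_rng(12)
        data = block_matrix(rng, 1, 10, 0, 20, within_r=0.8)
        data.loc["const"] = 1.0
        assignment = pd.Series(1, index=data.index)
        eig, var_expl, kme = module_eigenfeatures(data, assignment)
        assert np.isnan(kme.loc["const", 1])
        assert len(eig) == 1

    def test_tiny_module_rejected(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        assignment = pd.Series([1, 0, 0], index=data.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigenfeatures(data, assignment)


class TestTraitAssociation:
    def test_plain_spearman_matches_scipy(self):
        rng = np.random.default_rng(14)
        e = rng.normal(size=20)
        trait = e + rng.normal(0, 0.5, 20)
        eig = pd.DataFrame([e], index=["MEblue"])
        out = module_trait_association(eig, trait)
        ref_r, ref_p = sps.spearmanr(e, trait)
        assert out.loc["MEblue", "spearman_r"] == pytest.approx(ref_r)
        assert out.loc["MEblue", "spearman_p"] == pytest.approx(ref_p)

    def test_partial_removes_covariate_driven_association(self):
        # eigenfeature depends on the trait only through the covariate:
        # the partial correlation collapses while the marginal stays high
        rng = np.random.default_rng(15)
        n = 60
        cov = rng.normal(size=n)
        trait = cov + 0.3 * rng.normal(size=n)
        e = cov + 0.3 * rng.normal(size=n)
        eig = pd.DataFrame([e], index=["MEred"])
        out = module_trait_association(eig, trait, covariate=cov)
        assert abs(out.loc["MEred", "spearman_r"]) > 0.7
        assert abs(out.loc["MEred", "partial_r"]) < 0.35

    def test_partial_keeps_direct_association(self):
        rng = np.random.default_rng(16)
        n = 60
        cov = rng.normal(size=n)
        trait = rng.normal(size=n)
        e = trait + 0.3 * rng.normal(size=n)
        eig = pd.DataFrame([e], index=["MEgreen"])
        out = module_trait_association(eig, trait, covariate=cov)
        assert out.loc["MEgreen", "partial_r"] > 0.7
        assert out.loc["MEgreen", "partial_p"] < 1e-6

    def test_degenerate_covariate_flagged(self):
        e = np.arange(10.0)
        trait = np.arange(10.0)[::-1]
        eig = pd.DataFrame([e], index=["MEtan"])
        out = module_trait_association(eig, trait, covariate=trait.copy())
        assert np.isnan(out.loc["MEtan", "partial_r"])
        assert "perfectly" in out.loc["MEtan", "partial_note"]

    def test_length_mismatch_rejected(self):
        eig = pd.DataFrame([[1.0, 2.0, 3.0]], index=["MEblue"])
        with pytest.raises(ValueError, match="length"):
            module_trait_association(eig, np.array([1.0, 2.0]))
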