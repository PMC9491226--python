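import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial import procrustes as scipy_procrustes

from seragut.io_tables import FeatureMatrix, KoModuleMap
from seragut.integrate import (
    correlate_differential,
    crossdomain_map,
    ko_phenotype_module_test,
    procrustes_m2,
    protest,
)


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestProcrustes:
    def test_similarity_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        y = 3.0 * (x @ _rot(np.deg2rad(37)).T) + np.array([5.0, -2.0])
        fit = procrustes_m2(x, y)
        assert fit.m2 == pytest.approx(0.0, abs=1e-10)

    def test_reflection_allowed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 2))
        y = x.copy()
        y[:, 0] *= -1
        fit = procrustes_m2(x, y)
        assert fit.m2 == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(fit.rotation) == pytest.approx(-1.0)

    def test_matches_scipy_disparity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=(15, 2))
        fit = procrustes_m2(x, y)
        _, _, disparity = scipy_procrustes(x, y)
        assert fit.m2 == pytest.approx(disparity, rel=1e-9)

    def test_displaced_square_vs_brute_force(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        y = x.copy()
        y[0] += np.array([0.1, 0.0])
        fit = procrustes_m2(x, y)

        # brute force: minimize residual SS over angle x scale x translation
        xs = x - x.mean(axis=0)
        xs = xs / np.sqrt((xs**2).sum())
        ys = y - y.mean(axis=0)
        ys = ys / np.sqrt((ys**2).sum())
        best = np.inf
        for theta in np.arange(0, 2 * np.pi, 1e-4):
            rot = _rot(theta)
            mapped = xs @ rot.T
            # optimal scale for fixed rotation in closed form
            s = (mapped * ys).sum()
            resid = ((s * mapped - ys) ** 2).sum()
            best = min(best, resid)
        assert fit.m2 == pytest.approx(best, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 2))
        y = rng.normal(size=(20, 2))
        assert abs(procrustes_m2(x, y).m2 - procrustes_m2(y, x).m2) < 1e-10

    def test_error_cases(self):
        with pytest.raises(ValueError, match="same number of rows"):
            procrustes_m2(np.zeros((3, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="fewer rows"):
            procrustes_m2(np.eye(2, 3), np.eye(2, 3))
        with pytest.raises(ValueError, match="zero-variance"):
            procrustes_m2(np.ones((5, 2)), np.eye(5, 2))


class TestProtest:
    def test_near_identical_shapes_minimal_p(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 2))
        y = x + 1e-6 * rng.normal(size=(30, 2))
        fit = protest(x, y, n_perm=999, seed=0)
        assert fit.protest_p == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=(15, 2))
        a = protest(x, y, n_perm=199, seed=3)
        b = protest(x, y, n_perm=199, seed=3)
        assert a.protest_p == b.protest_p

    def test_null_calibration(self):
        # independent configurations: p <= 0.05 rate stays near nominal
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            x = rng.normal(size=(15, 2))
            y = rng.normal(size=(15, 2))
            fit = protest(x, y, n_perm=99, seed=rep)
            if fit.protest_p <= 0.05:
                hits += 1
        assert hits / n_rep <= 0.08

    def test_small_n_warning(self):
        rng = np.random.default_rng(6)
        fit = protest(rng.normal(size=(4, 2)), rng.normal(size=(4, 2)), n_perm=99)
        assert "unreliable" in fit.note

    def test_min_permutations(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match=">= 99"):
            protest(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)), n_perm=10)


def _fm(arr, prefix, samples=None):
    # exponentiate so arbitrary real inputs satisfy the non-negativity
    # contract; exp is monotone, so all rank-based expectations are unchanged
    arr = np.exp(np.asarray(arr, float))
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return FeatureMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                     columns=samples)
    )


class TestCorrelateDifferential:
    def test_identity_pairs(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 10))
        out = correlate_differential(_fm(x, "a"), _fm(x, "b"))
        diag = out[(out["feature_a"] == "a0") & (out["feature_b"] == "b0")]
        assert diag["spearman_r"].iloc[0] == pytest.approx(1.0)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(9)
        x = np.abs(rng.normal(size=(1, 12))) + 0.1
        y = rng.normal(size=(1, 12))
        r1 = correlate_differential(_fm(x, "a"), _fm(y, "b"))["spearman_r"].iloc[0]
        r2 = correlate_differential(_fm(np.exp(x), "a"), _fm(y, "b"))["spearman_r"].iloc[0]
        assert r1 == pytest.approx(r2)

    @pytest.mark.parametrize("y,expect_r", [
        ([3.0, 1.0, 2.0, 4.0, 5.0], 0.7),
        ([2.0, 1.0, 4.0, 3.0, 5.0], 0.8),
    ])
    def test_exact_permutation_p_small_n(self, y, expect_r):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        out = correlate_differential(_fm(x, "a"), _fm(np.array([y]), "b"))
        r = out["spearman_r"].iloc[0]
        assert r == pytest.approx(expect_r)
        # independent enumeration oracle over all 5! permutations
        yv = np.asarray(y)
        count = sum(
            abs(sps.spearmanr(x[0], yv[list(p)]).statistic) >= abs(r) - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert out["p_value"].iloc[0] == pytest.approx(count / 120)
        assert out["note"].iloc[0] == "exact permutation"

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(1, 20))
        y = rng.normal(size=(1, 20))
        out = correlate_differential(_fm(x, "a"), _fm(y, "b"))
        ref = sps.spearmanr(x[0], y[0])
        assert out["p_value"].iloc[0] == pytest.approx(ref.pvalue)

    def test_constant_vector_flagged(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        y = np.array([np.arange(10.0)])
        out = correlate_differential(_fm(x, "a"), _fm(y, "b"))
        bad = out[out["feature_a"] == "a0"]
        assert bad["note"].iloc[0] == "constant vector"
        assert np.isnan(bad["spearman_r"].iloc[0])
        assert np.isnan(bad["q_value"].iloc[0])

    def test_requires_shared_samples(self):
        a = _fm(np.ones((2, 4)), "a", samples=list("wxyz"))
        b = _fm(np.ones((2, 4)), "b", samples=list("mnop"))
        with pytest.raises(ValueError, match="shared samples"):
            correlate_differential(a, b)


def _planted_ko_world(seed, n_samples=30, member_r=0.9, link_sign=1,
                      n_kos=60, module_size=8):
    """KO matrix with one planted trait/eigenfeature-linked module."""
    rng = np.random.default_rng(seed)
    driver = rng.normal(size=n_samples)
    trait = driver + 0.4 * rng.normal(size=n_samples)
    cov = rng.normal(size=n_samples)
    lam = np.sqrt(member_r)
    x = rng.normal(size=(n_kos, n_samples))
    for i in range(module_size):
        x[i] = link_sign * (lam * driver + np.sqrt(1 - member_r) * rng.normal(size=n_samples))
    ko = _fm(x, "K")
    module_map = KoModuleMap(
        {"M00001": {f"K{i}" for i in range(module_size)},
         "M00002": {f"K{i}" for i in range(module_size, 2 * module_size)}},
    )
    return ko, module_map, trait, cov, driver


class TestKoPhenotypeModuleTest:
    def test_planted_module_selected_monte_carlo(self):
        hits = 0
        for seed in range(50):
            ko, mm, trait, _, _ = _planted_ko_world(seed)
            out = ko_phenotype_module_test(ko, trait, mm)
            if out.loc["M00001", "selected"] and out.loc["M00001", "direction"] == 1:
                hits += 1
        assert hits >= 48  # >= 95% of 50 seeds

    def test_null_selection_rate(self):
        # member_r = 0 gives i.i.d. KOs: member and background correlations
        # are exchangeable, which is the regime the Wilcoxon test calibrates
        # in (a co-correlated module shares one r value and is legitimately
        # non-exchangeable under permutation)
        ko, mm, trait, _, _ = _planted_ko_world(0, member_r=0.0)
        rng = np.random.default_rng(123)
        selections = 0
        total = 0
        for _ in range(100):
            perm = rng.permutation(len(trait))
            out = ko_phenotype_module_test(ko, trait[perm], mm)
            selections += int(out["selected"].sum())
            total += len(out)
        assert selections / total <= 0.07

    def test_all_ko_module_is_error(self):
        ko, _, trait, _, _ = _planted_ko_world(1)
        mm = KoModuleMap({"M99999": set(ko.feature_ids)})
        with pytest.raises(ValueError, match="empty background"):
            ko_phenotype_module_test(ko, trait, mm)

    def test_small_module_skipped(self):
        ko, _, trait, _, _ = _planted_ko_world(2)
        mm = KoModuleMap({"M00010": {"K0"}, "M00011": {"K1", "K2", "K3"}})
        out = ko_phenotype_module_test(ko, trait, mm)
        assert not out.loc["M00010", "selected"]
        assert "fewer than 2" in out.loc["M00010", "note"]
        assert np.isnan(out.loc["M00010", "p_value"])


class TestCrossdomainMap:
    @staticmethod
    def _run(seed, link_sign=1, member_r=0.8):
        ko, mm, trait, cov, driver = _planted_ko_world(
            seed, member_r=member_r, link_sign=link_sign
        )
        # metabolite cluster eigenfeature tracks the same driver
        rng = np.random.default_rng(10_000 + seed)
        e = driver + 0.3 * rng.normal(size=len(driver))
        e = (e - e.mean()) / e.std(ddof=0)
        eig = pd.DataFrame([e], index=["MEturquoise"], columns=ko.sample_ids)
        return crossdomain_map(ko, eig, mm, trait, covariate=cov), ko, mm

    def test_planted_link_recovered(self):
        effects, marks = [], []
        for seed in range(20):
            out, _, _ = self._run(seed)
            assert out["status"] == "ok"
            cmap = out["map"].set_index("kegg_module")
            assert "M00001" in cmap.index
            effects.append(cmap.loc["M00001", "scc_bg_adj"])
            marks.append(cmap.loc["M00001", "mark"])
        assert np.mean(effects) == pytest.approx(0.8, abs=0.1)
        assert all(m != "none" for m in marks)

    def test_negative_link_sign_recovery(self):
        for seed in range(20):
            out, _, _ = self._run(seed, link_sign=-1)
            cmap = out["map"].set_index("kegg_module")
            if "M00001" in cmap.index:
                assert cmap.loc["M00001", "scc_bg_adj"] < 0

    def test_null_mark_rate(self):
        # no planted link anywhere: cells marked at q < 0.1 are rare
        marked = 0
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(40_000 + seed)
            n = 30
            trait = rng.normal(size=n)
            ko = _fm(rng.normal(size=(40, n)), "K")
            mm = KoModuleMap({f"M{m:05d}": {f"K{i}" for i in range(4 * m, 4 * m + 4)}
                              for m in range(5)})
            e = rng.normal(size=n)
            eig = pd.DataFrame([e], index=["MEblue"], columns=ko.sample_ids)
            # alpha = 1 forces every module/cluster cell to be populated, so
            # the mark-rate estimate rests on hundreds of cells rather than
            # the handful that survive selection by chance
            out = crossdomain_map(ko, eig, mm, trait, covariate=None,
                                  require_partial=False, alpha=1.0)
            if len(out["map"]):
                total += len(out["map"])
                marked += int((out["map"]["mark"] != "none").sum())
        assert total >= 100
        assert marked / total <= 0.1

    def test_empty_selection_status(self):
        rng = np.random.default_rng(11)
        n = 20
        ko = _fm(rng.normal(size=(20, n)), "K")
        mm = KoModuleMap({"M00001": {"K0", "K1", "K2", "K3"}})
        eig = pd.DataFrame([rng.normal(size=n)], index=["MEred"],
                           columns=ko.sample_ids)
        out = crossdomain_map(ko, eig, mm, rng.normal(size=n))
        # with everything independent, selection is (almost surely) empty
        if out["status"] != "ok":
            assert out["map"].empty
            assert "no selected" in out["status"]

    def test_marks_consistent_with_q(self):
        out, _, _ = self._run(0)
        for _, row in out["map"].iterrows():
            q = row["fdr_q"]
            if q < 0.01:
                assert row["mark"] == "q<0.01"
            elif q < 0.05:
                assert row["mark"] == "q<0.05"
            elif q < 0.1:
                assert row["mark"] == "q<0.1"
            else:
                assert row["mark"] == "none"
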