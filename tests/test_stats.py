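"""Tests for the along-tract statistics: pruning, PCA, residualization,
Hotelling T^2, AES association, permutation cluster FWE, demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractoflux.stats import (BundleProfile, aes_analysis, association_along_tract,
                              clusters_from_pvalues, contingency_chi2, cohens_d,
                              fit_pca, group_analysis, group_test_along_tract,
                              hotelling_t2, permutation_fwe, prune_correlated,
                              residualize)
from tractoflux.synthetic import ProfileSimSpec, gen_profiles


def _profile_from_pooled(pooled, metric_names, n_subjects=20):
    n_obs, m = pooled.shape
    nodes = n_obs // n_subjects
    data = pooled[: n_subjects * nodes].reshape(n_subjects, nodes, m)
    return BundleProfile(data=data, subject_ids=[f"s{i}" for i in range(n_subjects)],
                         metric_names=metric_names)


class TestPrune:
    def test_high_pair_drops_one(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=4000)
        a = 0.9 * b + np.sqrt(1 - 0.81) * rng.normal(size=4000)
        prof = _profile_from_pooled(np.column_stack([a, b]), ("A", "B"))
        retained, corr = prune_correlated(prof, threshold=0.8)
        assert len(retained) == 1
        assert abs(corr.loc["A", "B"]) > 0.85

    def test_all_below_threshold_noop(self):
        rng = np.random.default_rng(1)
        pooled = rng.normal(size=(4000, 3))
        prof = _profile_from_pooled(pooled, ("A", "B", "C"))
        retained, _ = prune_correlated(prof, threshold=0.8)
        assert retained == ("A", "B", "C")

    def test_hub_metric_removed(self):
        """A correlates strongly with both B and C; B~C weak. Greedy
        max-mean-|r| removal drops A and keeps B and C. (Oracle: final
        matrix checked exhaustively below.)"""
        target = np.array([[1.0, 0.95, 0.85],
                           [0.95, 1.0, 0.68],
                           [0.85, 0.68, 1.0]])
        chol = np.linalg.cholesky(target)
        rng = np.random.default_rng(2)
        pooled = rng.normal(size=(20000, 3)) @ chol.T
        prof = _profile_from_pooled(pooled, ("A", "B", "C"))
        retained, corr = prune_correlated(prof, threshold=0.8)
        assert retained == ("B", "C")
        sub = corr.loc[list(retained), list(retained)].to_numpy()
        off = sub[~np.eye(len(retained), dtype=bool)]
        assert np.all(np.abs(off) <= 0.8)

    def test_everything_pruned_is_error(self):
        rng = np.random.default_rng(3)
        prof = _profile_from_pooled(rng.normal(size=(100, 1)), ("A",))
        with pytest.raises(ValueError):
            prune_correlated(prof)


class TestPca:
    def test_single_metric(self):
        rng = np.random.default_rng(0)
        prof = _profile_from_pooled(rng.normal(size=(2000, 1)), ("FW",))
        model, scores = fit_pca(prof)
        assert model.L == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert scores.shape[-1] == 1

    def test_perfectly_correlated_pair_gives_one_component(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        prof = _profile_from_pooled(np.column_stack([a, 2 * a + 1]), ("A", "B"))
        model, _ = fit_pca(prof)
        assert model.L == 1

    def test_two_factor_structure_recovered(self):
        """Data built from two orthogonal latent factors with population
        variance shares 0.70 and 0.20. Oracle: eigenvalues of the analytic
        population correlation matrix."""
        col1 = np.full(5, np.sqrt(0.7))
        col2 = np.sqrt(0.25) * np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        load = np.column_stack([col1, col2])
        noise_sd = np.sqrt(1.0 - (load**2).sum(axis=1))
        pop_corr = load @ load.T + np.diag(noise_sd**2)
        expected_ratios = np.sort(np.linalg.eigvalsh(pop_corr))[::-1] / 5.0

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            f = rng.normal(size=(6000, 2))
            pooled = f @ load.T + rng.normal(size=(6000, 5)) * noise_sd
            prof = _profile_from_pooled(pooled, ("m1", "m2", "m3", "m4", "m5"))
            model, _ = fit_pca(prof, var_target=0.80)
            if model.L == 2:
                hits += 1
                np.testing.assert_allclose(model.explained_variance_ratio,
                                           expected_ratios[:2], atol=0.03)
        assert hits >= 18

    def test_loadings_orthonormal_and_ratios_monotone(self):
        profile, _, _ = gen_profiles(ProfileSimSpec(seed=5))
        model, _ = fit_pca(profile)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.L), atol=1e-10)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-12
        assert np.cumsum(evr)[-1] >= 0.80

    def test_sign_convention(self):
        profile, _, _ = gen_profiles(ProfileSimSpec(seed=6))
        model, _ = fit_pca(profile)
        for c in range(model.L):
            col = model.loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0


class TestResidualize:
    @staticmethod
    def _meta(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"age": rng.normal(75, 6, n),
                             "sex": rng.choice(["M", "F"], n),
                             "center": rng.choice(["A", "B"], n)})

    def test_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        meta = self._meta(40, 1)
        scores = rng.normal(size=(40, 10, 2))
        scores[:, :, 0] += 0.5 * meta["age"].to_numpy()[:, None]
        resid = residualize(scores, meta)
        for node in range(10):
            for pc in range(2):
                r = np.corrcoef(resid[:, node, pc], meta["age"])[0, 1]
                assert abs(r) < 1e-10

    def test_perfect_fit_gives_zero_residuals(self):
        meta = self._meta(30, 2)
        scores = np.repeat((2.0 * meta["age"].to_numpy())[:, None, None], 4, axis=1)
        resid = residualize(scores, meta)
        assert np.abs(resid).max() < 1e-9

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        meta = self._meta(25, 3)
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(25, 3, 2))
        resid = residualize(scores, meta)
        X = sm.add_constant(pd.get_dummies(meta, drop_first=True, dtype=float))
        oracle = sm.OLS(scores[:, 1, 1], X).fit().resid.to_numpy()
        np.testing.assert_allclose(resid[:, 1, 1], oracle, atol=1e-10)

    def test_collinear_design_rejected(self):
        meta = self._meta(20, 5)
        meta["center"] = meta["sex"]  # perfectly collinear dummies
        with pytest.raises(ValueError, match="rank"):
            residualize(np.zeros((20, 2, 1)), meta)


class TestHotelling:
    def test_reduces_to_squared_t_for_one_variable(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(4, 30, size=2)
            x = rng.normal(size=(n1, 1))
            y = rng.normal(loc=rng.normal(), size=(n2, 1))
            t2, _, p = hotelling_t2(x, y)
            t, pt = sps.ttest_ind(x[:, 0], y[:, 0])
            assert abs(t2 - t**2) < 1e-10
            assert p == pytest.approx(pt, abs=1e-12)

    def test_small_integer_example_matches_direct_formula(self):
        """Oracle: explicit evaluation with a hand-coded 2x2 inverse."""
        x = np.array([[1.0, 2], [2, 3], [3, 5]])
        y = np.array([[2.0, 1], [4, 2], [3, 3]])
        d = x.mean(0) - y.mean(0)
        cx, cy = x - x.mean(0), y - y.mean(0)
        S = (cx.T @ cx + cy.T @ cy) / 4
        a, b_, c_, dd = S[0, 0], S[0, 1], S[1, 0], S[1, 1]
        Sinv = np.array([[dd, -b_], [-c_, a]]) / (a * dd - b_ * c_)
        expected = (3 * 3 / 6) * d @ Sinv @ d
        t2, _, _ = hotelling_t2(x, y)
        assert t2 == pytest.approx(expected, abs=1e-12)

    def test_equal_groups_give_near_zero(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 2))
        t2, _, p = hotelling_t2(base, base + 1e-9 * rng.normal(size=(10, 2)))
        assert t2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(15, 3)) + 0.4
        t2, f, p = hotelling_t2(x, y)
        res = pg.multivariate_ttest(x, y)
        assert t2 == pytest.approx(float(res["T2"].iloc[0]), rel=1e-10)
        assert p == pytest.approx(float(res["pval"].iloc[0]), rel=1e-10)

    def test_singular_covariance_rejected(self):
        x = np.ones((5, 2))
        y = np.ones((5, 2)) * 2
        with pytest.raises(ValueError, match="singular|PC"):
            hotelling_t2(x, y)


class TestGroupTest:
    def test_identical_groups_give_zero_statistic(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(6, 10, 2))
        scores = np.concatenate([block, block])
        labels = np.array(["a"] * 6 + ["b"] * 6)
        t2, p, d = group_test_along_tract(scores, labels)
        np.testing.assert_allclose(t2, 0.0, atol=1e-20)
        np.testing.assert_allclose(d, 0.0, atol=1e-20)

    def test_too_small_group_rejected(self):
        scores = np.zeros((5, 4, 1))
        labels = np.array(["a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="3 subjects"):
            group_test_along_tract(scores, labels)

    def test_type_one_error_calibration(self):
        """Per-node false-positive fraction across null simulations ~ alpha."""
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(100):
            scores = rng.normal(size=(24, 40, 2))
            labels = np.array(["a"] * 10 + ["b"] * 14)
            _, p, _ = group_test_along_tract(scores, labels)
            fracs.append(np.mean(p < 0.05))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.012)

    def test_planted_shift_dominates_smallest_pvalues(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(56, 100, 2))
        scores[35:, 40:60, 0] += 1.0  # d = 1.0 on nodes 40..59 of PC1
        labels = np.array(["HC"] * 35 + ["LLD"] * 21)
        _, p, d = group_test_along_tract(scores, labels)
        top = np.argsort(p)[:10]
        assert np.mean((top >= 40) & (top < 60)) >= 0.9
        assert np.median(np.abs(d[40:60, 0])) > 0.5


class TestAssociation:
    @staticmethod
    def _meta(n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"age": rng.normal(75, 6, n),
                             "sex": rng.choice(["M", "F"], n),
                             "center": rng.choice(["A", "B"], n)})

    def test_perfect_linear_association(self):
        rng = np.random.default_rng(0)
        n = 30
        meta = self._meta(n, 0)
        scores = rng.normal(size=(n, 5, 1))
        aes = 40 + 3.0 * scores[:, 2, 0]
        f, p, r = association_along_tract(scores, aes, meta)
        assert p[2] < 1e-12
        assert r[2] == pytest.approx(1.0, abs=1e-6)

    def test_negative_slope_gives_negative_r(self):
        rng = np.random.default_rng(1)
        n = 35
        meta = self._meta(n, 1)
        scores = rng.normal(size=(n, 5, 2))
        aes = 42 - 2.5 * scores[:, 3, 0] + rng.normal(scale=0.5, size=n)
        _, p, r = association_along_tract(scores, aes, meta)
        assert r[3] < -0.8
        assert p[3] < 1e-6

    def test_null_pvalues_uniform(self):
        """Kolmogorov-Smirnov on pooled null p-values across simulations."""
        rng = np.random.default_rng(2)
        pooled = []
        for seed in range(100):
            n = 30
            meta = self._meta(n, 100 + seed)
            scores = rng.normal(size=(n, 10, 2))
            aes = rng.normal(42, 8, size=n)
            _, p, _ = association_along_tract(scores, aes, meta)
            pooled.extend(p.tolist())
        stat, ks_p = sps.kstest(pooled, "uniform")
        assert ks_p > 0.01

    def test_missing_aes_rejected(self):
        meta = self._meta(10, 3)
        aes = np.full(10, np.nan)
        with pytest.raises(ValueError, match="AES"):
            association_along_tract(np.zeros((10, 3, 1)), aes, meta)


class TestClusters:
    def test_runs_and_nan_gaps(self):
        p = np.array([0.01, 0.02, 0.5, 0.01, np.nan, 0.01, 0.01])
        clusters, mask = clusters_from_pvalues(p, alpha=0.05)
        assert clusters == [(0, 2), (3, 1), (5, 2)]
        assert mask.sum() == 5


class TestPermutationFwe:
    def test_exhaustive_matches_independent_enumeration(self):
        """On a 4-vs-3 design the permutation p of the max cluster equals
        the brute-force enumeration computed here from scratch."""
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(7, 12, 1))
        scores[:4, 4:7, 0] += 2.5
        labels = np.array(["a"] * 4 + ["b"] * 3)

        def pfn(lab):
            _, p, _ = group_test_along_tract(scores, lab, alpha=0.05)
            return p

        thr, sig, forming, null_max, cluster_p = permutation_fwe(
            pfn, labels, n_perm=0, alpha=0.05, seed=0, exhaustive=True)
        assert len(null_max) == 35  # C(7,4)

        # independent enumeration
        obs_clusters, _ = clusters_from_pvalues(pfn(labels), 0.05)
        obs_max = max(ln for _, ln in obs_clusters)
        maxima = []
        for pos in itertools.combinations(range(7), 4):
            lab = np.array(["b"] * 7, dtype=object)
            for i in pos:
                lab[i] = "a"
            cl, _ = clusters_from_pvalues(pfn(lab), 0.05)
            maxima.append(max((ln for _, ln in cl), default=0))
        expected_p = (1 + sum(m >= obs_max for m in maxima)) / (1 + 35)
        assert cluster_p == pytest.approx(expected_p, abs=1e-12)

    def test_significant_mask_respects_threshold(self):
        profile, meta, mask = gen_profiles(
            ProfileSimSpec(seed=9, effects=(("group", 0, (40, 60), 1.5),)))
        res, _ = group_analysis(profile, meta, n_perm=300, seed=1)
        assert np.all(res.significant_mask <= res.cluster_forming_mask)
        clusters, _ = clusters_from_pvalues(
            np.where(res.significant_mask, 0.0, 1.0), 0.5)
        for _, length in clusters:
            assert length >= res.fwe_cluster_size

    def test_few_permutations_warns(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(10, 5, 1))
        labels = np.array(["a"] * 5 + ["b"] * 5)

        def pfn(lab):
            _, p, _ = group_test_along_tract(scores, lab)
            return p

        with pytest.warns(UserWarning, match="permutations"):
            permutation_fwe(pfn, labels, n_perm=50, seed=0)

    def test_determinism(self):
        profile, meta, _ = gen_profiles(ProfileSimSpec(seed=11))
        res1, _ = group_analysis(profile, meta, n_perm=200, seed=4)
        res2, _ = group_analysis(profile, meta, n_perm=200, seed=4)
        np.testing.assert_array_equal(res1.pvalues, res2.pvalues)
        np.testing.assert_array_equal(res1.null_max_cluster, res2.null_max_cluster)
        assert res1.fwe_cluster_size == res2.fwe_cluster_size


class TestContingency:
    def test_cohort_demographics_table(self):
        chi2, p = contingency_chi2([[9, 26], [5, 16]])
        assert round(chi2, 2) == 0.03
        assert p > 0.8

    def test_proportional_table_gives_zero(self):
        chi2, _ = contingency_chi2([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_against_direct_formula(self):
        """Oracle: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
        a, b, c, d = 20, 0, 0, 20
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = contingency_chi2([[a, b], [c, d]])
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert expected == 40

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chi2([[0, 0], [5, 16]])


class TestFullAnalyses:
    def test_group_analysis_recovers_planted_interval(self):
        spec = ProfileSimSpec(seed=21, effects=(("group", 0, (40, 60), 1.2),))
        profile, meta, effect_mask = gen_profiles(spec)
        res, model = group_analysis(profile, meta, n_perm=300, seed=2)
        assert (res.significant_mask & effect_mask).any()
        assert model.L >= 1

    def test_aes_analysis_negative_direction(self):
        spec = ProfileSimSpec(seed=22, effects=(("aes", 0, (20, 35), -0.8),))
        profile, meta, _ = gen_profiles(spec)
        res, _ = aes_analysis(profile, meta, n_perm=300, seed=3)
        assert np.nanmedian(res.effect_size[20:35]) < 0

    def test_cohens_d_magnitude(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 1)) + 1.0
        y = rng.normal(size=(200, 1))
        assert cohens_d(x, y)[0] == pytest.approx(1.0, abs=0.15)
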