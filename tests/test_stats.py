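import itertools
import math

import numpy as np
import pytest
from scipy import ndimage
from scipy import stats as sps

from petquant import (PSFModel, ancova_group_age, bonferroni_alpha,
                      cluster_fwe, load_reference_cohort, mann_whitney,
                      pearson_r2, smooth_cohort, voxelwise_glm_t)
from conftest import make_mask, make_volume


# ---------------------------------------------------------------------------
# Mann-Whitney

def _oracle_u(x, y):
    """Independent U oracle via mid-ranks (rank-sum identity)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _oracle_exact_p(x, y):
    """Exhaustive two-sided p over all group assignments (oracle)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    us = [_oracle_u(pooled[list(c)],
                    np.delete(pooled, list(c)))
          for c in itertools.combinations(range(len(pooled)), n)]
    us = np.asarray(us)
    u_obs = _oracle_u(x, y)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_reference_cohort_gm_suvt(self):
        """GM SUVt of the 6-vs-6 reference cohort: U = 34 and exact
        two-sided p = 8/924 by full enumeration."""
        tab = load_reference_cohort()
        res = mann_whitney(tab[tab.group == "MS"].gm_suvt,
                           tab[tab.group == "HV"].gm_suvt, mode="exact")
        assert res.statistic == 34
        assert res.p_two_sided == pytest.approx(8 / 924, rel=1e-12)

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_two_sided == pytest.approx(1.0)

    def test_complete_separation_six_vs_six(self):
        res = mann_whitney(np.arange(6) + 100.0, np.arange(6), mode="exact")
        assert res.statistic == 36
        assert res.p_two_sided == pytest.approx(2 / 924, rel=1e-12)

    @pytest.mark.parametrize("n,m", [(2, 3), (4, 4), (5, 5), (3, 7)])
    def test_exact_matches_enumeration_oracle(self, n, m, rng):
        for _ in range(5):
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=m), 1)
            res = mann_whitney(x, y, mode="exact")
            assert res.statistic == pytest.approx(_oracle_u(x, y))
            assert res.p_two_sided == pytest.approx(_oracle_exact_p(x, y),
                                                    rel=1e-12)

    def test_normal_approx_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(loc=0.7, size=25)
        res = mann_whitney(x, y, mode="normal_approx")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_beyond_limit_directs_to_normal(self, rng):
        with pytest.raises(ValueError, match="normal_approx"):
            mann_whitney(rng.normal(size=10), rng.normal(size=10), mode="exact")


def test_bonferroni_threshold():
    assert bonferroni_alpha(0.05, 9) == pytest.approx(0.005556, abs=1e-6)
    assert bonferroni_alpha(0.05, 1) == 0.05
    ms = [bonferroni_alpha(0.05, m) for m in range(1, 10)]
    assert all(a > b for a, b in zip(ms, ms[1:]))


# ---------------------------------------------------------------------------
# ANCOVA

class TestAncova:
    def test_reference_cohort_wm_suvt_significant(self):
        """Age-adjusted WM SUVt difference on the 12 reference subjects is
        strongly significant (cross-checked against statsmodels OLS)."""
        tab = load_reference_cohort()
        res = ancova_group_age(tab.wm_suvt, tab.group, tab.age)
        assert res.df == 9
        assert res.statistic > 0          # MS > HV
        assert res.p_two_sided < 0.01

        import statsmodels.api as sm
        X = sm.add_constant(np.column_stack(
            [(tab.group == "MS").astype(float), tab.age]))
        fit = sm.OLS(tab.wm_suvt.to_numpy(), X).fit()
        assert res.statistic == pytest.approx(fit.tvalues[1], rel=1e-10)
        assert res.p_two_sided == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_orthogonal_covariate_reduces_to_two_sample_t(self):
        """With age centred and orthogonal to both group and outcome, the
        group coefficient and its standard-error structure match the
        pooled two-sample t exactly, up to the residual-df bookkeeping
        (df = n-3 instead of n-2)."""
        y = np.array([3.0, 3.0, 5.0, 5.0, 4.0, 4.0, 7.0, 7.0])
        group = [1, 1, 1, 1, 0, 0, 0, 0]
        age = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert age @ y == 0 and age.sum() == 0
        res = ancova_group_age(y, group, age)
        t2 = sps.ttest_ind(y[:4], y[4:]).statistic
        n = len(y)
        assert res.statistic == pytest.approx(
            t2 * math.sqrt((n - 3) / (n - 2)), rel=1e-10)
        assert res.effect_summary["group_coefficient"] == pytest.approx(
            y[:4].mean() - y[4:].mean(), rel=1e-10)

    def test_perfect_separation_reports_tiny_p(self):
        y = np.array([1.0, 1, 1, 0, 0, 0])
        res = ancova_group_age(y, [1, 1, 1, 0, 0, 0],
                               [40.0, 50, 60, 45, 55, 65])
        assert res.p_two_sided < 1e-12

    def test_rank_deficiency_named(self):
        with pytest.raises(ValueError, match="age"):
            ancova_group_age([1.0, 2, 3, 4], [1, 1, 0, 0],
                             [50.0, 50, 50, 50])
        with pytest.raises(ValueError, match="group"):
            ancova_group_age([1.0, 2, 3, 4], [1, 1, 1, 1],
                             [50.0, 51, 52, 53])


# ---------------------------------------------------------------------------
# Pearson

class TestPearson:
    def test_perfect_line(self):
        x = np.arange(8.0)
        res = pearson_r2(x, 2 * x + 1)
        assert res.effect_summary["r2"] == pytest.approx(1.0)
        assert res.p_two_sided == 0.0

    def test_orthogonal_gives_zero_r(self):
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        res = pearson_r2(x, y)
        assert res.effect_summary["r"] == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_scipy_on_random_points(self, rng):
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        res = pearson_r2(x, y)
        ref = sps.pearsonr(x, y)
        assert res.effect_summary["r"] == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-8)
        assert res.effect_summary["r2"] == pytest.approx(
            res.effect_summary["r"] ** 2, abs=1e-15)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1, 1, 1], [1.0, 2, 3, 4])


# ---------------------------------------------------------------------------
# voxel-wise GLM and cluster inference

def _cohort_vols(rng, n=12, shape=(8, 8, 8), effect=0.0, blob=None):
    group = [1] * (n // 2) + [0] * (n // 2)
    age = rng.normal(50, 8, size=n)
    vols = []
    for i in range(n):
        data = rng.normal(0, 1, size=shape)
        if blob is not None and group[i] == 1:
            data[blob] += effect
        vols.append(make_volume(data))
    return vols, group, age


class TestVoxelwiseGlm:
    def test_single_voxel_equals_scalar_ancova(self):
        """A voxel whose 12 subject values are the reference-cohort WM
        SUVt numbers reproduces the scalar ANCOVA t exactly."""
        tab = load_reference_cohort()
        vols = [make_volume(np.full((3, 3, 3), v)) for v in tab.wm_suvt]
        # non-constant background so only voxel (1,1,1) carries the data
        for v, val in zip(vols, np.random.default_rng(0).normal(size=12)):
            v.data[0, 0, 0] = val
        mask = make_mask(np.ones((3, 3, 3)))
        tmap = voxelwise_glm_t(vols, tab.group.tolist(), tab.age.tolist(), mask)
        ref = ancova_group_age(tab.wm_suvt, tab.group, tab.age)
        assert abs(tmap.vol.data[1, 1, 1] - ref.statistic) < 1e-10
        assert tmap.df == 9

    def test_subject_order_permutation_invariance(self, rng):
        vols, group, age = _cohort_vols(rng)
        mask = make_mask(np.ones((8, 8, 8)))
        t1 = voxelwise_glm_t(vols, group, age, mask).vol.data
        perm = rng.permutation(12)
        t2 = voxelwise_glm_t([vols[i] for i in perm],
                             [group[i] for i in perm],
                             [age[i] for i in perm], mask).vol.data
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_orthogonal_age_matches_two_sample_t_oracle(self, rng):
        """With a centred age column orthogonal to group, the map equals
        the closed-form pooled two-sample t map up to the df-3 residual
        scaling."""
        n = 8
        group = [1, 1, 1, 1, 0, 0, 0, 0]
        age = [1.0, -1, 1, -1, 1, -1, 1, -1]
        vols = [make_volume(rng.normal(size=(5, 5, 5))) for _ in range(n)]
        # force outcome orthogonal to age: make pairs share values
        for a, b in ((0, 1), (2, 3), (4, 5), (6, 7)):
            vols[b] = make_volume(vols[a].data.copy())
        mask = make_mask(np.ones((5, 5, 5)))
        tmap = voxelwise_glm_t(vols, group, age, mask).vol.data
        Y = np.stack([v.data for v in vols])
        m1, m0 = Y[:4].mean(axis=0), Y[4:].mean(axis=0)
        ss = ((Y[:4] - m1) ** 2).sum(axis=0) + ((Y[4:] - m0) ** 2).sum(axis=0)
        t_pooled = (m1 - m0) / np.sqrt(ss / (n - 2) * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(
            tmap, t_pooled * math.sqrt((n - 3) / (n - 2)), atol=1e-8)

    def test_contrast_directions_are_negations(self, rng):
        vols, group, age = _cohort_vols(rng)
        mask = make_mask(np.ones((8, 8, 8)))
        t_ms = voxelwise_glm_t(vols, group, age, mask).vol.data
        t_hv = voxelwise_glm_t(vols, [1 - g for g in group], age, mask).vol.data
        np.testing.assert_allclose(t_ms, -t_hv, atol=1e-10)

    def test_zero_variance_voxels_flagged(self):
        vols = [make_volume(np.zeros((4, 4, 4))) for _ in range(8)]
        for i, v in enumerate(vols):
            v.data[0, 0, 0] = float(i)  # only one voxel varies
        mask = make_mask(np.ones((4, 4, 4)))
        tmap = voxelwise_glm_t(vols, [1, 1, 1, 1, 0, 0, 0, 0],
                               [40.0, 45, 50, 55, 42, 47, 52, 57], mask)
        assert tmap.n_zero_variance >= 63
        assert np.all(np.isfinite(tmap.vol.data))


class TestClusterFwe:
    def test_three_vs_three_matches_exhaustive_oracle(self, rng):
        """Permutation cluster p values agree with a brute-force loop over
        all 20 group relabelings of a 3-vs-3 cohort."""
        shape = (8, 8, 8)
        blob = (slice(2, 6), slice(2, 6), slice(2, 6))
        group = [1, 1, 1, 0, 0, 0]
        age = [40.0, 55, 48, 44, 60, 52]
        vols = [make_volume(rng.normal(0, 1, shape)) for _ in range(6)]
        for i in range(3):
            vols[i].data[blob] += 4.0
        mask = make_mask(np.ones(shape))
        forming_p = 0.05
        tmap = voxelwise_glm_t(vols, group, age, mask)
        cs = cluster_fwe(tmap, forming_p=forming_p, n_perm=100, seed=1,
                         connectivity=18)
        assert cs.exhaustive and cs.n_permutations == 20
        assert cs.clusters, "planted blob should form a cluster"

        # oracle: independent OLS + labeling per relabeling
        Y = np.stack([v.data.reshape(-1) for v in vols])
        thr = sps.t.isf(forming_p, 3)
        struct = ndimage.generate_binary_structure(3, 2)

        def max_size(g):
            X = np.column_stack([np.ones(6), g, age])
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            resid = Y - X @ beta
            s2 = (resid ** 2).sum(axis=0) / 3
            cov = np.linalg.inv(X.T @ X)[1, 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                t = beta[1] / np.sqrt(s2 * cov)
            lab, ncl = ndimage.label((np.nan_to_num(t) > thr).reshape(shape),
                                     structure=struct)
            return np.bincount(lab.ravel())[1:].max() if ncl else 0

        null = [max_size(np.isin(np.arange(6), c).astype(float))
                for c in itertools.combinations(range(6), 3)]
        for cl in cs.clusters:
            p_oracle = np.mean(np.asarray(null) >= cl.voxel_count)
            assert cl.p_fwe_cluster == pytest.approx(p_oracle, abs=1e-12)

    def test_p_fwe_nonincreasing_with_size(self, rng):
        vols, group, age = _cohort_vols(rng, effect=3.0,
                                        blob=(slice(1, 5), slice(1, 5),
                                              slice(1, 5)))
        mask = make_mask(np.ones((8, 8, 8)))
        tmap = voxelwise_glm_t(vols, group, age, mask)
        cs = cluster_fwe(tmap, forming_p=0.05, n_perm=1000, seed=3)
        sizes = [c.voxel_count for c in cs.clusters]
        ps = [c.p_fwe_cluster for c in cs.clusters]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert s1 >= s2 and p1 <= p2

    def test_too_few_groups_error(self, rng):
        vols, group, age = _cohort_vols(rng, n=4)
        mask = make_mask(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="2 subjects"):
            voxelwise_glm_t(vols[:3], [1, 0, 0], age[:3], mask)


def test_smooth_cohort_constants_and_mass(rng):
    const = make_volume(np.full((20, 20, 20), 2.0), spacing=(2, 2, 2))
    out = smooth_cohort([const], fwhm_mm=12.0)
    assert np.allclose(out[0].data, 2.0, atol=1e-6)
    blob = np.zeros((40, 40, 40))
    blob[17:23, 17:23, 17:23] = 1.0
    vol = make_volume(blob, spacing=(2, 2, 2))
    sm = smooth_cohort([vol], fwhm_mm=12.0)[0]
    assert abs(sm.data.sum() / blob.sum() - 1) < 0.005
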