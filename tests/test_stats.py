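import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from _oracles import brute_anova_f, brute_permanova_exact
from gutdiv.beta import DistanceMatrix, distance_matrix, pcoa
from gutdiv.stats import (anova_tukey, dispersion_test, loglinear_regression,
                          multivariate_variance, permanova)


def euclidean_dm(points, ids=None):
    ids = ids or [str(i) for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids)


class TestPermanova:
    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        dm = euclidean_dm(pts)
        x = rng.normal(size=5)
        res = permanova(dm, x, method="exact")
        f_oracle, p_oracle = brute_permanova_exact(dm.data, x)
        assert res.F == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 120

    def test_euclidean_ss_matches_coordinate_regression(self):
        # with Euclidean distances, the distance-based SS decomposition
        # equals the classical multivariate regression SS on the coordinates
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 4))
        x = rng.normal(size=10)
        dm = euclidean_dm(pts)
        res = permanova(dm, x, n_perm=99, seed=0)
        X = np.column_stack([np.ones(10), x])
        h = X @ np.linalg.pinv(X.T @ X) @ X.T
        yc = pts - pts.mean(axis=0)
        ss_model = np.trace((h @ yc) @ (h @ yc).T)
        ss_resid = np.trace(((np.eye(10) - h) @ yc) @
                            ((np.eye(10) - h) @ yc).T)
        f_expected = (ss_model / 1) / (ss_resid / 8)
        r2_expected = ss_model / (ss_model + ss_resid)
        assert res.F == pytest.approx(f_expected, abs=1e-8)
        assert res.R2 == pytest.approx(r2_expected, abs=1e-8)

    def test_smallest_attainable_p(self):
        rng = np.random.default_rng(6)
        x = np.arange(8.0)
        pts = x[:, None] * np.ones((1, 2))  # distances fully explained
        dm = euclidean_dm(pts + rng.normal(scale=1e-6, size=pts.shape))
        res = permanova(dm, x, n_perm=999, seed=1)
        assert res.p == pytest.approx(1 / 1000)

    def test_affine_covariate_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 3))
        dm = euclidean_dm(pts)
        x = rng.normal(size=9)
        a = permanova(dm, x, n_perm=199, seed=5)
        b = permanova(dm, 3.0 * x - 17.0, n_perm=199, seed=5)
        assert a.F == pytest.approx(b.F, rel=1e-10)
        assert a.R2 == pytest.approx(b.R2, rel=1e-10)
        assert a.p == b.p

    def test_constant_covariate_error(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, np.ones(5))


class TestDispersion:
    def test_translated_identical_clouds_f_near_zero(self):
        rng = np.random.default_rng(11)
        cloud = rng.normal(size=(6, 2))
        pts = np.vstack([cloud, cloud + 50.0])
        dm = euclidean_dm(pts)
        res = dispersion_test(dm, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.9

    def test_detects_unequal_dispersion(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for i in range(40):
            a = rng.normal(scale=1.0, size=(6, 2))
            b = rng.normal(scale=4.0, size=(6, 2))
            dm = euclidean_dm(np.vstack([a, b]))
            res = dispersion_test(dm, ["a"] * 6 + ["b"] * 6, n_perm=199,
                                  seed=i)
            rejections += res.p <= 0.05
        assert rejections / 40 > 0.5  # far above the 5% nominal rate

    def test_exact_enumeration_matches_anova_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(6, 2))
        labels = ["a"] * 3 + ["b"] * 3
        dm = euclidean_dm(pts)
        res = dispersion_test(dm, labels, method="exact")
        codes = np.array([0, 0, 0, 1, 1, 1])
        f_oracle = brute_anova_f(res.distances.to_numpy(), codes, 2)
        assert res.F == pytest.approx(f_oracle, rel=1e-10)
        # exact p over the 20 label arrangements (3+3 groups)
        assert res.n_perm == 20

    def test_group_of_one_error(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="size 1"):
            dispersion_test(dm, ["a", "b", "b", "b"])

    def test_variances_match_centroid_formula(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        dm = euclidean_dm(pts)
        res = dispersion_test(dm, labels, n_perm=99, seed=0)
        for g, sel in (("a", slice(0, 4)), ("b", slice(4, 8))):
            sub = pts[sel] - pts[sel].mean(axis=0)
            expected = (sub ** 2).sum() / 3
            assert res.group_variances[g] == pytest.approx(expected,
                                                           rel=1e-8)


class TestMultivariateVariance:
    def test_two_points_hand_geometry(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        v = multivariate_variance(coords, ["s1", "s2"], ["g", "g"])
        assert v["g"] == pytest.approx(2.0)  # delta=1: (1+1)/1

    def test_identical_points_zero(self):
        coords = np.ones((3, 2))
        v = multivariate_variance(coords, list("abc"), ["g"] * 3)
        assert v["g"] == pytest.approx(0.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(15)
        coords = rng.normal(size=(6, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T + np.array([5.0, -3.0])
        ids = list("abcdef")
        groups = ["g1"] * 3 + ["g2"] * 3
        a = multivariate_variance(coords, ids, groups)
        b = multivariate_variance(moved, ids, groups)
        pd.testing.assert_series_equal(a, b, rtol=1e-10)


class TestAnovaTukey:
    def test_two_groups_matches_t_test(self):
        rng = np.random.default_rng(16)
        a = rng.normal(size=8)
        b = rng.normal(loc=1.0, size=8)
        res = anova_tukey(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 8)
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.p == pytest.approx(t_p, rel=1e-6)
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(t_p, abs=2e-3)

    def test_extreme_separation(self):
        rng = np.random.default_rng(17)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(10, 1, 6),
                               rng.normal(20, 1, 6)])
        res = anova_tukey(vals, ["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        assert res.p < 1e-3
        assert (res.tukey["p_adj"] < 0.05).all()

    def test_null_calibration(self):
        rng = np.random.default_rng(18)
        pvals = []
        for _ in range(100):
            vals = rng.normal(size=12)
            res = anova_tukey(vals, ["a", "b", "c"] * 4)
            pvals.append(res.p)
        # omnibus p uniform under the null
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.005
        assert np.mean(np.array(pvals) <= 0.05) <= 0.12

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])


class TestLoglinearRegression:
    def test_exact_line_recovery(self):
        x = np.array([4.0, 10.0, 27.0, 4.0, 10.0, 27.0])
        y = 10 ** (0.1 * x)
        res = loglinear_regression(pd.Series(y), x)
        assert res.slope == pytest.approx(0.1, rel=1e-12)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_x_error(self):
        with pytest.raises(ValueError, match="constant"):
            loglinear_regression(pd.Series([1.0, 2.0, 3.0]),
                                 np.array([4.0, 4.0, 4.0]))

    def test_nonpositive_ratio_names_sample(self):
        y = pd.Series({"s1": 1.0, "s2": 0.0, "s3": 2.0})
        with pytest.raises(ValueError, match="s2"):
            loglinear_regression(y, np.array([4.0, 10.0, 27.0]))

    def test_slope_recovery_within_3se(self):
        rng = np.random.default_rng(19)
        x = np.tile([4.0, 10.0, 27.0], 4)
        slopes = []
        for _ in range(200):
            y = 10 ** (-2.8 + 0.107 * x + rng.normal(0, 0.3, size=12))
            slopes.append(loglinear_regression(pd.Series(y), x).slope)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.107) < 3 * se


class TestVeganCrossValidation:
    """Independent oracle: the reference R implementations (vegan)."""

    def _run_r(self, script, tmp_path):
        import subprocess
        p = tmp_path / "check.R"
        p.write_text(script)
        out = subprocess.run(["Rscript", "--vanilla", str(p)],
                             capture_output=True, text=True, check=True)
        return out.stdout

    def test_permanova_matches_adonis2(self, tmp_path):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 5))
        d = squareform(pdist(pts))
        x = np.tile([4.0, 10.0, 27.0], 4)
        np.savetxt(tmp_path / "d.txt", d)
        np.savetxt(tmp_path / "x.txt", x)
        res = permanova(DistanceMatrix(d, [str(i) for i in range(12)]), x,
                        n_perm=99, seed=0)
        out = self._run_r(f"""
suppressMessages(library(vegan))
d <- as.dist(as.matrix(read.table("{tmp_path}/d.txt")))
x <- scan("{tmp_path}/x.txt")
res <- adonis2(d ~ x, permutations=99)
cat(res$F[1], res$R2[1], "\n")
""", tmp_path)
        f_vegan, r2_vegan = map(float, out.split())
        assert res.F == pytest.approx(f_vegan, rel=1e-6)
        assert res.R2 == pytest.approx(r2_vegan, rel=1e-6)

    def test_dispersion_matches_betadisper_centroid(self, tmp_path):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        np.savetxt(tmp_path / "d.txt", d)
        res = dispersion_test(
            DistanceMatrix(d, [str(i) for i in range(12)]),
            ["a"] * 4 + ["b"] * 4 + ["c"] * 4, n_perm=99, seed=0)
        out = self._run_r(f"""
suppressMessages(library(vegan))
d <- as.dist(as.matrix(read.table("{tmp_path}/d.txt")))
g <- factor(rep(c("a","b","c"), each=4))
bd <- betadisper(d, g, type="centroid")
pt <- permutest(bd, permutations=99)
cat(pt$tab$F[1], "\n")
cat(bd$distances, "\n")
""", tmp_path)
        lines = out.strip().splitlines()
        f_vegan = float(lines[0])
        d_vegan = np.array(list(map(float, lines[1].split())))
        assert res.F == pytest.approx(f_vegan, rel=1e-6)
        np.testing.assert_allclose(res.distances.to_numpy(), d_vegan,
                                   rtol=1e-6)
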