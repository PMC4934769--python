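"""Group-level shape/size inference tests: PCA, allometry, MANOVA, CVA, NJ."""

import numpy as np
import pytest
from scipy import stats

from morphodiet.procrustes_core import ShapeSet, gpa_align
from morphodiet.shape_statistics import test_allometry as allometry_test
from morphodiet.shape_statistics import (
    confidence_ellipse,
    cva,
    manova_test,
    nj_phenogram,
    remove_allometry,
    select_pc_count,
    shape_pca,
    size_summary,
)


def make_shapeset(flat: np.ndarray, sizes: np.ndarray) -> ShapeSet:
    """Wrap flattened (n, 2k) coordinates as a minimal aligned ShapeSet."""
    n, p = flat.shape
    aligned = flat.reshape(n, p // 2, 2)
    return ShapeSet(
        aligned=aligned,
        centroid_sizes=np.asarray(sizes, dtype=float),
        consensus=aligned.mean(axis=0),
        ids=[f"s{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestShapePca:
    def test_identical_shapes_zero_eigenvalues(self):
        x = np.tile(np.arange(6.0), (5, 1))
        res = shape_pca(x)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_variance_conservation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 8))
        res = shape_pca(x)
        cov = np.cov(x.T)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), abs=1e-10)

    def test_dense_eigen_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 6))
        res = shape_pca(x)
        cov = np.cov(x.T)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, np.clip(evals, 0, None),
                                   atol=1e-10)
        # scores reproduce projections on the same eigenvectors
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        recon = res.scores @ res.eigenvectors.T + res.mean
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_too_few_specimens(self):
        with pytest.raises(ValueError):
            shape_pca(np.zeros((2, 4)))


# ---------------------------------------------------------------------------
# Size summaries
# ---------------------------------------------------------------------------

class TestSizeSummary:
    def test_identical_groups_f_zero(self):
        res = size_summary([5.0, 5.0, 5.0, 5.0], ["a", "a", "b", "b"])
        assert res.anova_F == 0.0

    def test_textbook_anova(self):
        res = size_summary([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.anova_F == pytest.approx(13.5, abs=1e-10)
        f_ref, p_ref = stats.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.anova_p == pytest.approx(p_ref, abs=1e-12)

    def test_notch_formula(self):
        # group of n=4 with IQR exactly 2 -> notch half-width 1.58
        res = size_summary([1.0, 2.0, 3.0, 4.0, 9.0, 9.0], ["g", "g", "g", "g", "h", "h"])
        row = res.table[res.table["group"] == "g"].iloc[0]
        assert row["q3"] - row["q1"] == pytest.approx(1.5)
        # direct formula instance with a constructed IQR=2, n=4 group
        vals = [0.0, 1.0, 3.0, 4.0]
        res2 = size_summary(vals + [9.0, 9.0], ["g"] * 4 + ["h"] * 2)
        row2 = res2.table[res2.table["group"] == "g"].iloc[0]
        iqr = row2["q3"] - row2["q1"]
        assert row2["notch_half_width"] == pytest.approx(1.58 * iqr / 2.0)

    def test_single_group_no_f(self):
        res = size_summary([1.0, 2.0, 3.0], ["a", "a", "a"])
        assert res.anova_F is None and res.anova_p is None
        assert res.table.iloc[0]["median"] == 2.0


# ---------------------------------------------------------------------------
# Allometry test
# ---------------------------------------------------------------------------

class TestAllometry:
    def test_perfect_signal(self):
        rng = np.random.default_rng(2)
        sizes = np.exp(rng.normal(4.0, 0.3, size=30))
        field = rng.normal(size=8)
        field /= np.linalg.norm(field)
        flat = np.outer(np.log(sizes), field)
        shapes = make_shapeset(flat, sizes)
        res = allometry_test(shapes, n_perm=99, seed=0)
        assert res.pct_variance_predicted == pytest.approx(100.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_p_never_zero(self):
        rng = np.random.default_rng(3)
        flat = rng.normal(size=(15, 6))
        shapes = make_shapeset(flat, np.exp(rng.normal(4, 0.2, 15)))
        res = allometry_test(shapes, n_perm=49, seed=1)
        assert res.p_value >= 1.0 / 50.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        flat = rng.normal(size=(12, 6))
        shapes = make_shapeset(flat, np.exp(rng.normal(4, 0.2, 12)))
        a = allometry_test(shapes, n_perm=99, seed=7)
        b = allometry_test(shapes, n_perm=99, seed=7)
        assert a.p_value == b.p_value

    def test_n_perm_validation(self, two_group_shapes):
        shapes, _ = two_group_shapes
        with pytest.raises(ValueError):
            allometry_test(shapes, n_perm=0)

    def test_statistic_bounds(self, two_group_shapes):
        shapes, _ = two_group_shapes
        res = allometry_test(shapes, n_perm=99, seed=0)
        assert 0.0 <= res.pct_variance_predicted <= 100.0
        assert 0.0 < res.p_value <= 1.0


# ---------------------------------------------------------------------------
# Allometry correction
# ---------------------------------------------------------------------------

class TestRemoveAllometry:
    def test_zero_allometry_residuals_unchanged(self):
        """With shape exactly orthogonal to size, residuals equal the input."""
        rng = np.random.default_rng(5)
        n = 16
        x = rng.normal(4.0, 0.3, n)
        flat = rng.normal(size=(n, 6))
        # project out the within-sample size direction column by column
        xc = x - x.mean()
        flat = flat - np.outer(xc, (xc @ flat) / (xc @ xc))
        shapes = make_shapeset(flat, np.exp(x))
        res = remove_allometry(shapes, ["g"] * n)
        np.testing.assert_allclose(res.pooled_slope, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.residuals, flat, atol=1e-10)

    def test_pooled_orthogonality_exact(self, two_group_shapes):
        shapes, truth = two_group_shapes
        groups = np.asarray(truth["labels"])
        res = remove_allometry(shapes, groups)
        x = np.log(shapes.centroid_sizes)
        # within-group center both residuals and sizes, then pooled dot = 0
        xc = x.copy()
        rc = res.residuals.copy()
        for g in np.unique(groups):
            m = groups == g
            xc[m] -= xc[m].mean()
            rc[m] -= rc[m].mean(axis=0)
        np.testing.assert_allclose(xc @ rc, 0.0, atol=1e-8)

    def test_slope_recovery(self):
        """Planted common within-group slope is recovered."""
        rng = np.random.default_rng(6)
        field = rng.normal(size=10)
        field /= np.linalg.norm(field)
        beta = 0.05
        flats, sizes, groups = [], [], []
        for gi, (mu, n) in enumerate([(4.0, 40), (4.4, 40)]):
            logs = rng.normal(mu, 0.3, n)
            base = rng.normal(0, 0.001, size=(n, 10))
            offset = np.zeros(10)
            offset[gi] = 0.5
            flats.append(base + offset + np.outer(logs, beta * field))
            sizes.append(np.exp(logs))
            groups += [f"g{gi}"] * n
        shapes = make_shapeset(np.vstack(flats), np.concatenate(sizes))
        res = remove_allometry(shapes, groups)
        np.testing.assert_allclose(res.pooled_slope, beta * field, atol=5e-3)

    def test_group_means_preserved(self, two_group_shapes):
        shapes, truth = two_group_shapes
        groups = np.asarray(truth["labels"])
        res = remove_allometry(shapes, groups)
        flat = shapes.flat()
        for g in np.unique(groups):
            m = groups == g
            # removing a within-group centered component keeps the group mean
            np.testing.assert_allclose(
                res.residuals[m].mean(axis=0), flat[m].mean(axis=0), atol=1e-10
            )

    def test_singleton_group_excluded(self):
        rng = np.random.default_rng(7)
        flat = rng.normal(size=(5, 4))
        shapes = make_shapeset(flat, np.exp(rng.normal(4, 0.2, 5)))
        with pytest.warns(UserWarning, match="size 1"):
            res = remove_allometry(shapes, ["a", "a", "a", "a", "lone"])
        assert res.excluded_groups == ["lone"]
        assert res.keep_mask.sum() == 4


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

class TestManova:
    def test_two_group_hotelling_relation(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(0.8, 1, (25, 3))])
        g = ["a"] * 20 + ["b"] * 25
        res = manova_test(x, g)
        # with two groups there is one nonzero eigenvalue lambda:
        # pillai = lambda/(1+lambda), wilks = 1/(1+lambda) => they sum to 1
        assert res["pillai"] + res["wilks"] == pytest.approx(1.0, abs=1e-10)
        # and both F approximations coincide with Hotelling's T2 F-test
        assert res["pillai_F"] == pytest.approx(res["wilks_F"], rel=1e-8)
        assert res["pillai_p"] == pytest.approx(res["wilks_p"], rel=1e-6)

    def test_statsmodels_oracle(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(9)
        x = np.vstack(
            [rng.normal(i * 0.5, 1, (15, 4)) for i in range(3)]
        )
        g = np.repeat(["a", "b", "c"], 15)
        res = manova_test(x, g)
        sm = MANOVA(x, np.column_stack([np.ones(45), g == "b", g == "c"]).astype(float))
        tbl = sm.mv_test(hypotheses=[("group", np.array([[0, 1, 0], [0, 0, 1]]))])
        frame = tbl.results["group"]["stat"]
        assert res["wilks"] == pytest.approx(
            float(frame.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert res["pillai"] == pytest.approx(
            float(frame.loc["Pillai's trace", "Value"]), abs=1e-8
        )
        assert res["wilks_F"] == pytest.approx(
            float(frame.loc["Wilks' lambda", "F Value"]), rel=1e-6
        )
        assert res["pillai_F"] == pytest.approx(
            float(frame.loc["Pillai's trace", "F Value"]), rel=1e-6
        )

    def test_huge_separation_wilks_to_zero(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(50, 1, (15, 2))])
        g = ["a"] * 15 + ["b"] * 15
        res = manova_test(x, g)
        assert res["wilks"] < 1e-3
        assert res["pillai"] > 0.999

    def test_singular_within_advises_reduction(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(20, 2))
        x = np.column_stack([base, base[:, 0] + base[:, 1]])  # exact collinearity
        g = ["a"] * 10 + ["b"] * 10
        with pytest.raises(np.linalg.LinAlgError, match="principal components"):
            manova_test(x, g)

    def test_null_calibration(self):
        """Rejection rate under identical group distributions is near alpha."""
        rej = 0
        n_sim = 200
        for i in range(n_sim):
            rng = np.random.default_rng(40_000 + i)
            x = rng.normal(size=(30, 3))
            g = ["a"] * 15 + ["b"] * 15
            res = manova_test(x, g)
            rej += res["pillai_p"] <= 0.05
        # 95% binomial band around 0.05 at n=200: [0.02, 0.08]
        assert 0.02 <= rej / n_sim <= 0.08


# ---------------------------------------------------------------------------
# PC-count selection
# ---------------------------------------------------------------------------

class TestSelectPcCount:
    def test_signal_on_pc1(self):
        rng = np.random.default_rng(12)
        n = 40
        scores = rng.normal(size=(n, 5)) * 0.2
        g = np.array(["a"] * 20 + ["b"] * 20)
        scores[g == "b", 0] += 5.0
        assert select_pc_count(scores, g, n_boot=20, seed=0) == 1

    def test_pure_noise_small_count(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(30, 6))
        g = np.array(["a"] * 15 + ["b"] * 15)
        k = select_pc_count(scores, g, n_boot=20, seed=0)
        assert 1 <= k <= 6

    def test_cap_at_min_group_minus_one(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=(24, 10))
        g = np.array(["a"] * 20 + ["b"] * 4)
        k = select_pc_count(scores, g, n_boot=10, seed=0)
        assert k <= 3  # n_min - 1

    def test_small_group_flagged(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=(22, 4))
        g = np.array(["a"] * 10 + ["b"] * 10 + ["tiny"] * 2)
        with pytest.warns(UserWarning, match="tiny"):
            select_pc_count(scores, g, n_boot=10, seed=0)

    def test_balanced_resampling_contract(self):
        # with badly unbalanced groups selection still runs on equal draws;
        # indirectly verified by the cap test; here check the error path
        rng = np.random.default_rng(16)
        scores = rng.normal(size=(5, 3))
        g = np.array(["a"] * 3 + ["b", "b"])
        with pytest.raises(ValueError, match="at least 2 groups"):
            with pytest.warns(UserWarning):
                select_pc_count(scores, g, n_boot=5, seed=0)


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------

class TestCva:
    def test_identical_groups_zero_eigenvalue(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(20, 3))
        x = np.vstack([base, base])
        g = ["a"] * 20 + ["b"] * 20
        res = cva(x, g)
        assert res.eigenvalues[0] < 1e-10

    def test_two_gaussian_recovery(self):
        rng = np.random.default_rng(18)
        x = np.vstack(
            [rng.normal(0, 1, (150, 4)), rng.normal([10, 0, 0, 0], 1, (150, 4))]
        )
        g = ["a"] * 150 + ["b"] * 150
        res = cva(x, g)
        assert res.cv_accuracy == 1.0
        assert res.mahalanobis.loc["a", "b"] == pytest.approx(10.0, abs=0.8)

    def test_pooled_within_covariance_identity(self, two_group_shapes):
        shapes, truth = two_group_shapes
        g = np.asarray(truth["labels"])
        pca = shape_pca(shapes.flat())
        res = cva(pca.scores, g, n_pc=4)
        s = res.scores
        w = np.zeros((s.shape[1], s.shape[1]))
        for lab in np.unique(g):
            sc = s[g == lab] - s[g == lab].mean(axis=0)
            w += sc.T @ sc
        w /= len(g) - len(np.unique(g))
        np.testing.assert_allclose(w, np.eye(s.shape[1]), atol=1e-6)

    def test_mahalanobis_matrix_invariants(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(60, 4))
        x[:20] += [1, 0, 0, 0]
        x[40:] += [0, 2, 0, 0]
        g = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        res = cva(x, g)
        m = res.mahalanobis.values
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0)
        assert (m >= 0).all()
        assert res.eigenvalues[0] >= res.eigenvalues[-1]

    def test_linear_transform_invariance(self):
        """Full-rank Mahalanobis distances are invariant to invertible maps."""
        rng = np.random.default_rng(20)
        x = rng.normal(size=(50, 3))
        x[25:] += [1.5, 0.5, 0]
        g = ["a"] * 25 + ["b"] * 25
        a = rng.normal(size=(3, 3)) + np.eye(3) * 2
        res1 = cva(x, g)
        res2 = cva(x @ a.T, g)
        assert res1.mahalanobis.loc["a", "b"] == pytest.approx(
            res2.mahalanobis.loc["a", "b"], rel=1e-8
        )

    def test_axis_shape_changes(self):
        rng = np.random.default_rng(21)
        flat = rng.normal(size=(40, 8))
        flat[20:, 0] += 3.0
        pca = shape_pca(flat)
        g = ["a"] * 20 + ["b"] * 20
        res = cva(pca.scores, g, n_pc=4, shape_coords=flat)
        assert res.axis_shape_changes.shape == (8, 1)
        # regression of shape on scores: predicted change tracks the planted axis
        assert abs(res.axis_shape_changes[0, 0]) > abs(
            res.axis_shape_changes[1:, 0]
        ).max()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            cva(np.random.default_rng(0).normal(size=(5, 2)),
                ["a", "a", "a", "a", "b"])

    def test_n_pc_too_large(self):
        with pytest.raises(ValueError, match="n_pc"):
            cva(np.zeros((10, 3)), ["a"] * 5 + ["b"] * 5, n_pc=4)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _patristic(newick: str):
    """Taxon-to-taxon path lengths from a Newick string (via dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


def _random_additive_matrix(rng, n):
    """Distance matrix of a random binary tree with positive branch lengths.

    Built by repeatedly splitting a random leaf's pendant branch and hanging a
    new leaf off the split point, so the matrix is additive by construction.
    ``pendant[i]`` tracks the distance from leaf i to its attachment node.
    """
    d = np.zeros((n, n))
    pendant = list(rng.uniform(0.5, 2.0, size=3))
    for i in range(3):
        for j in range(3):
            if i != j:
                d[i, j] = pendant[i] + pendant[j]
    for k in range(3, n):
        host = int(rng.integers(0, k))
        s = rng.uniform(0.1, 0.9) * pendant[host]  # split point, from the leaf
        p = rng.uniform(0.5, 2.0)                  # new pendant length
        for j in range(k):
            if j == host:
                d[k, j] = d[j, k] = s + p
            else:
                d[k, j] = d[j, k] = d[host, j] - s + p
        pendant[host] = s
        pendant.append(p)
    return d


class TestNjPhenogram:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        newick = nj_phenogram(d, ["A", "B", "C"])
        pat = _patristic(newick)
        assert pat[frozenset(("A", "B"))] == pytest.approx(2.0)
        assert pat[frozenset(("A", "C"))] == pytest.approx(4.0)
        assert pat[frozenset(("B", "C"))] == pytest.approx(4.0)
        # pendant lengths a=1, b=1, c=3 appear verbatim
        assert "A:1" in newick and "B:1" in newick and "C:3" in newick

    def test_five_taxon_additive_round_trip(self):
        rng = np.random.default_rng(22)
        d = _random_additive_matrix(rng, 5)
        labels = list("ABCDE")
        pat = _patristic(nj_phenogram(d, labels))
        for i in range(5):
            for j in range(i + 1, 5):
                assert pat[frozenset((labels[i], labels[j]))] == pytest.approx(
                    d[i, j], abs=1e-8
                )

    def test_taxon_order_invariance(self):
        import dendropy

        rng = np.random.default_rng(23)
        d = _random_additive_matrix(rng, 6)
        labels = list("ABCDEF")
        perm = [3, 1, 5, 0, 2, 4]
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nj_phenogram(d, labels), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nj_phenogram(d2, labels2), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_negative_branch_clamped(self):
        d = np.array(
            [[0.0, 1.0, 1.0], [1.0, 0.0, 5.0], [1.0, 5.0, 0.0]]
        )
        with pytest.warns(UserWarning, match="clamped"):
            newick = nj_phenogram(d, ["A", "B", "C"])
        assert ":0," in newick or ":0)" in newick or ":-0" not in newick

    def test_input_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_phenogram(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), "ABC")
        with pytest.raises(ValueError, match="diagonal"):
            nj_phenogram(np.array([[1, 1, 2], [1, 0, 1], [2, 1, 0.0]]), "ABC")
        with pytest.raises(ValueError, match="3 taxa"):
            nj_phenogram(np.array([[0, 1], [1, 0.0]]), "AB")


# ---------------------------------------------------------------------------
# Confidence ellipses
# ---------------------------------------------------------------------------

class TestConfidenceEllipse:
    def test_isotropic_radius(self):
        rng = np.random.default_rng(24)
        pts = rng.normal(size=(200_00, 2))
        ell = confidence_ellipse(pts, level=0.9)
        expected = np.sqrt(stats.chi2.ppf(0.9, 2))
        assert expected == pytest.approx(2.146, abs=0.001)
        np.testing.assert_allclose(ell.semi_axes, expected, rtol=0.03)

    def test_level_zero_degenerate(self):
        rng = np.random.default_rng(25)
        ell = confidence_ellipse(rng.normal(size=(10, 2)), level=0.0)
        assert ell.degenerate
        np.testing.assert_allclose(ell.semi_axes, 0.0)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(26)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=100_000)
        ell = confidence_ellipse(pts, level=0.9)
        coverage = ell.contains(pts).mean()
        assert coverage == pytest.approx(0.9, abs=0.005)

    def test_rank_deficient_flagged(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t])
        ell = confidence_ellipse(pts, level=0.9)
        assert ell.degenerate

    def test_validation(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((5, 2)), level=1.0)
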