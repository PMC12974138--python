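import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import microstab as ms
from microstab.errors import ZeroSumSampleError


class TestAlpha:
    @pytest.mark.parametrize(
        "counts, expected",
        [([1, 1, 1, 1], np.log(4)), ([10, 0, 0], 0.0), ([2, 1, 1], 1.0397207708399179)],
    )
    def test_shannon_values(self, counts, expected):
        assert ms.shannon(np.array(counts)) == pytest.approx(expected, abs=1e-9)

    def test_shannon_log2_flag(self):
        assert ms.shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_chao1_formula(self):
        counts = [1] * 4 + [2] * 2 + [5] * 4  # S_obs=10, F1=4, F2=2
        assert ms.chao1(counts) == pytest.approx(12.0)

    def test_chao1_all_singletons(self):
        assert ms.chao1([1] * 5) == pytest.approx(15.0)  # 5 + 5*4/2

    def test_chao1_no_rare_taxa(self):
        assert ms.chao1([3] * 7) == pytest.approx(7.0)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30)
           .filter(lambda v: sum(v) > 0))
    @settings(deadline=None, max_examples=100)
    def test_chao1_at_least_observed_richness(self, counts):
        assert ms.chao1(counts) >= (np.array(counts) > 0).sum() - 1e-12

    @given(st.integers(min_value=2, max_value=20), st.integers(min_value=1, max_value=100))
    @settings(deadline=None, max_examples=50)
    def test_shannon_maximal_at_uniform(self, s, c):
        # any non-uniform composition with the same richness scores lower
        uniform = np.full(s, c)
        rng = np.random.default_rng(s * 100 + c)
        skewed = rng.dirichlet(np.ones(s)) + 1e-9  # same support size
        assert ms.shannon(uniform) >= ms.shannon(skewed) - 1e-12

    def test_zero_vector_rejected(self):
        for fn in (ms.shannon, ms.chao1):
            with pytest.raises(ZeroSumSampleError):
                fn(np.zeros(3))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = ms.CountTable(np.array([[3, 4, 5], [3, 4, 5]]), ["a", "b"], list("xyz"))
        assert ms.bray_curtis(t).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = ms.CountTable(np.array([[5, 0], [0, 7]]), ["a", "b"], ["x", "y"])
        assert ms.bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        t = ms.CountTable(np.array([[2, 2, 0], [0, 2, 2]]), ["a", "b"], list("xyz"))
        assert ms.bray_curtis(t).data[0, 1] == pytest.approx(0.5)  # 1 - 2*2/8

    def test_matches_minimum_formula_on_random_tables(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 50, size=(6, 10))
        counts[:, 0] += 1
        t = ms.CountTable(counts, [f"s{i}" for i in range(6)], [f"t{j}" for j in range(10)])
        d = ms.bray_curtis(t).data
        for i in range(6):
            for j in range(6):
                x, y = counts[i], counts[j]
                expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_collinear_points_recover_distances(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        ord_ = ms.pcoa(ms.DistanceMatrix(["a", "b", "c"], d), n_axes=3)
        assert (ord_.eigenvalues > 1e-9).sum() == 1
        x = ord_.coordinates["PC1"].to_numpy()
        np.testing.assert_allclose(np.abs(x[:, None] - x[None, :]), d, atol=1e-9)

    def test_all_zero_distances(self):
        ord_ = ms.pcoa(ms.DistanceMatrix(["a", "b"], np.zeros((2, 2))), n_axes=2)
        assert ord_.coordinates.shape[1] == 0

    def test_planar_points_exact_embedding(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ord_ = ms.pcoa(ms.DistanceMatrix([str(i) for i in range(8)], d), n_axes=2)
        assert ord_.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalue_sum_equals_gower_trace(self, small_study):
        dm = ms.bray_curtis(small_study.table)
        ord_ = ms.pcoa(dm)
        n = dm.data.shape[0]
        j = np.eye(n) - 1 / n
        b = -0.5 * j @ (dm.data**2) @ j
        assert ord_.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_sign_convention(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ord_ = ms.pcoa(ms.DistanceMatrix(list("abcdef"), d), n_axes=3)
        for col in ord_.coordinates.columns:
            v = ord_.coordinates[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, size=(7, 12))
        t = ms.CountTable(counts, [f"s{i}" for i in range(7)], [f"t{j}" for j in range(12)])
        dm = ms.bray_curtis(t)
        ours = ms.pcoa(dm, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, dm.sample_ids), number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-6)


class TestPermanova:
    def test_separated_clouds_minimum_p(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(100, 1, (8, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = ms.DistanceMatrix([f"s{i}" for i in range(16)], d)
        f, p = ms.permanova(dm, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_balanced_duplication_preserves_f(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        d1 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        f1, _ = ms.permanova(ms.DistanceMatrix([f"s{i}" for i in range(10)], d1),
                             labels, n_perm=9, seed=0)
        pts2 = np.vstack([pts, pts])
        d2 = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=-1)
        f2, _ = ms.permanova(ms.DistanceMatrix([f"s{i}" for i in range(20)], d2),
                             labels + labels, n_perm=9, seed=0)
        # doubling every point scales both among and within sums consistently;
        # F changes only through its degrees of freedom ratio
        ss_ratio1 = f1 * (2 - 1) / (10 - 2)
        ss_ratio2 = f2 * (2 - 1) / (20 - 2)
        assert ss_ratio1 == pytest.approx(ss_ratio2, rel=1e-9)

    def test_matches_skbio_pseudo_f(self, small_study):
        skbio = pytest.importorskip("skbio")
        dm = ms.bray_curtis(small_study.table)
        grouping = small_study.metadata.df.loc[dm.sample_ids, "treatment"]
        f, _ = ms.permanova(dm, grouping, n_perm=9, seed=0)
        res = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.sample_ids), grouping.to_numpy(),
            permutations=9)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_single_sample_group_rejected(self):
        d = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]).astype(float)
        with pytest.raises(ValueError):
            ms.permanova(ms.DistanceMatrix(list("abc"), d), ["x", "x", "y"], 9, 0)


class TestFbRatio:
    def _phylum_table(self, f, b, other=10):
        return ms.CountTable(np.array([[f, b, other]]), ["s"],
                             ["Firmicutes", "Bacteroidetes", "Proteobacteria"])

    def test_basic_ratio(self):
        assert ms.fb_ratio(self._phylum_table(60, 30)).iloc[0] == pytest.approx(2.0)

    def test_equal_counts(self):
        assert ms.fb_ratio(self._phylum_table(30, 30)).iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero Bacteroidetes"):
            r = ms.fb_ratio(self._phylum_table(30, 0))
        assert np.isnan(r.iloc[0])

    def test_synonym_bacteroidota(self):
        t = ms.CountTable(np.array([[40, 20]]), ["s"], ["Firmicutes", "Bacteroidota"])
        assert ms.fb_ratio(t).iloc[0] == pytest.approx(2.0)

    def test_neither_phylum_present(self):
        t = ms.CountTable(np.array([[40, 20]]), ["s"], ["Proteobacteria", "Spirochaetota"])
        with pytest.raises(KeyError):
            ms.fb_ratio(t)
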