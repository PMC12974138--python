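import itertools

import numpy as np
import pytest

import microstab as ms
from microstab.errors import SingularSystemError


class TestEstimateFractions:
    def test_deterministic_symmetry(self):
        t = ms.CountTable(np.array([[0, 0]]), ["s"], ["a", "b"])
        np.testing.assert_allclose(ms.estimate_fractions(t, 0)[0], [[0.5, 0.5]])

    def test_deterministic_pseudocount_formula(self):
        t = ms.CountTable(np.array([[9, 0]]), ["s"], ["a", "b"])
        np.testing.assert_allclose(ms.estimate_fractions(t, 0)[0], [[10 / 11, 1 / 11]])

    def test_dirichlet_mean_matches_posterior(self):
        t = ms.CountTable(np.array([[3, 1]]), ["s"], ["a", "b"])
        draws = np.array([d[0, 0] for d in ms.estimate_fractions(t, 2000, seed=0)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 4 / 6) < 3 * se

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ms.estimate_fractions(ms.CountTable(np.zeros((0, 0), dtype=int), [], []), 1)


class TestVariationMatrix:
    def test_proportional_taxa_have_zero_variation(self):
        f = np.array([[0.1, 0.2, 0.7], [0.2, 0.4, 0.4], [0.3, 0.6, 0.1]])
        t = ms.variation_matrix(f)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)  # f2 = 2*f1 everywhere

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(5), size=10)
        t = ms.variation_matrix(f)
        np.testing.assert_allclose(t, t.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(t), 0.0)

    def test_hand_computed_example(self):
        f = np.array([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]])
        logratio = np.log(f[:, 0] / f[:, 1])  # ln .25, ln 1, ln 4
        expected = np.var(logratio, ddof=1)
        assert ms.variation_matrix(f)[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            ms.variation_matrix(np.array([[0.0, 1.0], [0.5, 0.5]]))


def _lognormal_fractions(rng, n, cov):
    d = cov.shape[0]
    logs = rng.multivariate_normal(np.zeros(d), cov, size=n)
    a = np.exp(logs)
    return a / a.sum(axis=1, keepdims=True)


class TestBasisCorrelations:
    def test_brute_force_oracle_d4(self):
        # assemble and solve the 4-taxon linear system by hand (no exclusions)
        rng = np.random.default_rng(7)
        f = _lognormal_fractions(rng, 50, np.eye(4))
        t = ms.variation_matrix(f)
        m = np.ones((4, 4)) + 2 * np.eye(4)
        omega2 = np.linalg.solve(m, t.sum(axis=1))
        omega = np.sqrt(omega2)
        expected = np.clip(
            (omega2[:, None] + omega2[None, :] - t) / (2 * np.outer(omega, omega)), -1, 1)
        np.fill_diagonal(expected, 1.0)
        got = ms.basis_correlations(t, exclusion_threshold=1.0)  # nothing excluded
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_independent_taxa_near_zero(self):
        rng = np.random.default_rng(1)
        f = _lognormal_fractions(rng, 2000, np.eye(20))
        rho = ms.basis_correlations(ms.variation_matrix(f))
        off = rho[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_perfectly_correlated_pair_recovered(self):
        rng = np.random.default_rng(2)
        cov = np.eye(20)
        cov[0, 1] = cov[1, 0] = 0.999
        f = _lognormal_fractions(rng, 2000, cov)
        rho = ms.basis_correlations(ms.variation_matrix(f))
        assert rho[0, 1] > 0.9

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        f = _lognormal_fractions(rng, 100, np.eye(8))
        rho = ms.basis_correlations(ms.variation_matrix(f))
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert np.abs(rho).max() <= 1.0 + 1e-12

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            ms.basis_correlations(np.zeros((3, 3)))

    def test_degenerate_system_fails_loudly(self):
        # single-factor data (x_i = s_i * z) keeps every pair maximally
        # correlated, so exclusions exhaust the 4-taxon linear system; the
        # singular solve must surface as a named error, not garbage output
        rng = np.random.default_rng(0)
        z = rng.normal(size=500)
        logf = np.outer(z, np.array([1.0, 2.0, 3.0, 4.0]))
        f = np.exp(logf)
        f /= f.sum(axis=1, keepdims=True)
        t = ms.variation_matrix(f)
        with pytest.raises(SingularSystemError), pytest.warns(UserWarning):
            ms.basis_correlations(t, exclusion_threshold=0.1, max_exclusions=10)


class TestSparccPipeline:
    def test_closure_invariance_deterministic_mode(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(50, 500, size=(30, 8))
        t1 = ms.CountTable(counts, [f"s{i}" for i in range(30)], [f"t{j}" for j in range(8)])
        scaled = counts.copy()
        scaled[0] *= 7  # rescale one sample's library size
        t2 = ms.CountTable(scaled, t1.sample_ids, t1.taxon_ids)
        r1 = ms.sparcc(t1, n_inner=0, pseudocount=0).r.to_numpy()
        r2 = ms.sparcc(t2, n_inner=0, pseudocount=0).r.to_numpy()
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_reproducible_from_seed(self, small_study):
        a = ms.sparcc(small_study.table, n_inner=3, seed=5).r
        b = ms.sparcc(small_study.table, n_inner=3, seed=5).r
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_planted_pairs_rank_top(self):
        cfg = ms.SimulationConfig(n_subjects_per_arm=60, timepoints=("T0",), n_taxa=20,
                                  depth_mean=20000, depth_dispersion=0.0,
                                  n_correlated_pairs=3, pair_rho=0.8, subject_sd=0.0, seed=9)
        table, _, truth = ms.simulate_counts(cfg)
        r = ms.sparcc(table, n_inner=5, seed=1).r.to_numpy()
        pairs = sorted(
            ((abs(r[i, j]), (i, j)) for i, j in itertools.combinations(range(20), 2)),
            reverse=True)
        top3 = {p for _, p in pairs[:3]}
        assert top3 == truth.correlated_index_pairs()


@pytest.fixture(scope="module")
def planted():
    cfg = ms.SimulationConfig(n_subjects_per_arm=50, timepoints=("T0",), n_taxa=12,
                              depth_mean=20000, n_correlated_pairs=1, pair_rho=0.9,
                              subject_sd=0.0, seed=17)
    table, _, truth = ms.simulate_counts(cfg)
    res = ms.sparcc(table, n_inner=5, seed=3)
    res.p = ms.sparcc_pvalues(table, res.r, n_null=24, seed=4, n_inner=5)
    return table, truth, res


class TestPvaluesAndNetwork:

    def test_p_range_respects_add_one_rule(self, planted):
        _, _, res = planted
        p = res.p.to_numpy()
        off = p[~np.eye(p.shape[0], dtype=bool)]
        assert off.min() >= 1 / 25 - 1e-12 and off.max() <= 1.0

    def test_planted_pair_gets_minimum_p(self, planted):
        _, truth, res = planted
        (i, j) = next(iter(truth.correlated_index_pairs()))
        assert res.p.iloc[i, j] == pytest.approx(1 / 25)

    def test_build_network_joint_threshold(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.6
        r[0, 2] = r[2, 0] = 0.6
        r[1, 2] = r[2, 1] = 0.4
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 0.01
        p[0, 2] = p[2, 0] = 0.2
        p[1, 2] = p[2, 1] = 0.01
        import pandas as pd
        taxa = ["a", "b", "c"]
        res = ms.SparccResult(r=pd.DataFrame(r, index=taxa, columns=taxa),
                              p=pd.DataFrame(p, index=taxa, columns=taxa))
        g = ms.build_network(res)
        assert set(map(frozenset, g.edges)) == {frozenset({"a", "b"})}
        assert g.number_of_nodes() == 3  # isolates retained
        assert ms.build_network(res, keep_isolates=False).number_of_nodes() == 2

    def test_r_threshold_one_gives_empty_edges(self, planted):
        _, _, res = planted
        assert ms.build_network(res, r_threshold=1.0).number_of_edges() == 0

    def test_edge_count_monotone_in_threshold(self, planted):
        _, _, res = planted
        counts = [ms.build_network(res, r_threshold=th).number_of_edges()
                  for th in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold_rejected(self, planted):
        _, _, res = planted
        with pytest.raises(ValueError):
            ms.build_network(res, r_threshold=1.5)
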