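"""Group statistics: t-maps, cluster permutation, FDR, partial Spearman."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as ss

from tcdeeg.stats import (AdjacencyGraph, bh_fdr, channel_adjacency,
                          cluster_permutation, partial_spearman,
                          scalp_band_bonferroni, two_sample_tmap)


def chain_graph(n):
    nbrs = [set() for _ in range(n)]
    for i in range(n - 1):
        nbrs[i].add(i + 1)
        nbrs[i + 1].add(i)
    return AdjacencyGraph(n, tuple(nbrs))


def bh_stepup_oracle(p, q):
    """Literal step-up definition: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    rej = np.zeros(m, bool)
    rej[order[:k_max]] = True
    return rej


class TestTMap:
    def test_identical_groups_zero(self, rng):
        x = rng.standard_normal((4, 6))
        t = two_sample_tmap(x, x.copy())
        assert np.allclose(t, 0.0)

    def test_zero_variance_location_warns_and_zeroes(self):
        a = np.full((3, 2), 1.0)
        b = np.full((4, 2), 1.0)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t = two_sample_tmap(a, b)
        assert np.allclose(t, 0.0)

    def test_hand_computed_value(self):
        t = two_sample_tmap(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert t[0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert t[0] == pytest.approx(-3.6742346, abs=1e-6)

    def test_label_swap_negates(self, rng):
        a = rng.standard_normal((5, 8))
        b = rng.standard_normal((7, 8))
        assert np.allclose(two_sample_tmap(a, b), -two_sample_tmap(b, a),
                           atol=1e-12)

    def test_matches_scipy_pooled_ttest(self, rng):
        a = rng.standard_normal((6, 10))
        b = rng.standard_normal((9, 10))
        want = ss.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(two_sample_tmap(a, b), want, atol=1e-12)


class TestClusterPermutation:
    def test_seeded_determinism(self, rng):
        a = rng.standard_normal((8, 12))
        b = rng.standard_normal((8, 12))
        g = chain_graph(12)
        r1 = cluster_permutation(a, b, g, n_perm=200, seed=5)
        r2 = cluster_permutation(a, b, g, n_perm=200, seed=5)
        assert np.array_equal(r1.t_map, r2.t_map)
        assert [c.p_value for c in r1.clusters] == \
               [c.p_value for c in r2.clusters]

    def test_exact_enumeration_for_tiny_groups(self, rng):
        a = rng.standard_normal((3, 5)) + 2.0
        b = rng.standard_normal((3, 5))
        res = cluster_permutation(a, b, chain_graph(5), n_perm=2000, seed=0)
        assert res.exact
        assert res.n_permutations == 20         # C(6,3)
        for c in res.clusters:
            assert c.p_value >= 1.0 / 21

    def test_reported_clusters_are_connected(self, rng):
        a = rng.standard_normal((10, 30))
        a[:, 5:9] += 3.0
        a[:, 20:23] += 3.0
        b = rng.standard_normal((10, 30))
        g = chain_graph(30)
        res = cluster_permutation(a, b, g, n_perm=100, seed=1)
        assert res.clusters
        for c in res.clusters:
            members = set(c.members)
            # BFS connectivity check under the chain adjacency
            seen = {c.members[0]}
            frontier = [c.members[0]]
            while frontier:
                v = frontier.pop()
                for w in g.neighbors[v]:
                    if w in members and w not in seen:
                        seen.add(w)
                        frontier.append(w)
            assert seen == members

    def test_planted_effect_detected(self, rng):
        a = rng.standard_normal((15, 40))
        a[:, 10:20] += 1.5
        b = rng.standard_normal((15, 40))
        res = cluster_permutation(a, b, chain_graph(40), n_perm=500, seed=2)
        top = res.clusters[0]
        assert top.p_value < 0.05
        assert set(range(11, 19)) <= set(top.members)

    def test_adjacency_must_cover_locations(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation(rng.standard_normal((4, 6)),
                                rng.standard_normal((4, 6)),
                                chain_graph(5), n_perm=50)


class TestFDR:
    def test_worked_example(self):
        res = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert np.allclose(res.p_adjusted, [0.04, 0.04, 0.04, 0.5])
        assert res.rejected.tolist() == [True, True, True, False]

    def test_all_ones_no_rejections(self):
        res = bh_fdr(np.ones(5), q=0.05)
        assert not res.rejected.any()

    def test_single_p_identity(self):
        res = bh_fdr(np.array([0.04]), q=0.05)
        assert res.p_adjusted[0] == pytest.approx(0.04)
        assert res.rejected[0]

    def test_adjusted_monotone_in_raw_order(self, rng):
        p = rng.uniform(1e-6, 1, 25)
        res = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.p_adjusted[order]) >= -1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_stepup_oracle(self, p, q):
        res = bh_fdr(np.array(p), q=q)
        assert np.array_equal(res.rejected, bh_stepup_oracle(p, q))

    def test_empty_input(self):
        res = bh_fdr(np.array([]))
        assert res.p_adjusted.size == 0


class TestScalpBonferroni:
    def test_band_thresholding(self):
        ps = {b: p for b, p in zip(
            ["delta", "theta", "alpha1", "alpha2", "beta", "gamma1", "gamma2"],
            [0.006, 0.01, 0.5, 0.2, 0.9, 0.0071, 0.05])}
        rep = scalp_band_bonferroni(ps)
        assert rep["delta"]["significant"]
        assert not rep["theta"]["significant"]     # 0.01 > 0.05/7
        assert rep["gamma1"]["significant"]        # 0.0071 < 0.05/7 = 0.00714..

    def test_band_count_enforced(self):
        with pytest.raises(ValueError):
            scalp_band_bonferroni({"theta": 0.01})


class TestPartialSpearman:
    def test_independent_covariate_leaves_rho(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        cov = rng.standard_normal(n)
        rho_p, _ = partial_spearman(x, y, cov)
        rho_plain = ss.spearmanr(x, y).statistic
        assert abs(rho_p - rho_plain) < 0.05

    def test_confound_fully_removed(self, rng):
        n = 500
        cov = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = cov + 0.1 * rng.standard_normal(n)     # y almost purely confound
        rho_p, _ = partial_spearman(x, y, cov)
        assert abs(rho_p) < 0.05

    def test_variable_identical_to_covariate_degrades_to_zero(self, rng):
        cov = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="coincides"):
            rho, p = partial_spearman(rng.standard_normal(100), cov.copy(),
                                      cov)
        assert rho == 0.0 and p == 1.0

    def test_perfect_correlation_clipped_and_flagged(self, rng):
        x = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="degenerate"):
            rho, p = partial_spearman(x, x, rng.standard_normal(20) * 0 + 1.0)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_covariate_falls_back(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="constant covariate"):
            rho, _ = partial_spearman(x, y, np.ones(30))
        assert rho == pytest.approx(ss.spearmanr(x, y).statistic, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 60
        cov = rng.standard_normal(n)
        x = 0.5 * cov + rng.standard_normal(n)
        y = -0.4 * cov + rng.standard_normal(n)
        rho, p = partial_spearman(x, y, cov)
        df = pd.DataFrame({"x": x, "y": y, "z": cov})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestAdjacency:
    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            AdjacencyGraph(2, (frozenset({1}), frozenset()))

    def test_channel_adjacency_reasonable(self, montage):
        g = channel_adjacency(montage.positions)
        assert g.n_locations == 32
        degrees = [len(s) for s in g.neighbors]
        assert min(degrees) >= 1
        assert g.n_components == 1
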