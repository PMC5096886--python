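import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from hubvuln.connectivity import AssociationMatrix
from hubvuln.network_stats import (
    StrengthVector,
    bonferroni,
    connection_strength,
    define_hubs,
    fdr_bh,
    fluency_covariance,
    groupwise_strength_test,
    mean_hub_strength,
    pearson_permutation,
    proportional_loss,
)


def _mat(z, ids=None):
    z = np.asarray(z, dtype=float)
    ids = np.arange(1, len(z) + 1) if ids is None else np.asarray(ids)
    return AssociationMatrix(z_values=z, scale=2, filter_name="d4", region_ids=ids)


def _sv(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = np.arange(1, len(values) + 1) if ids is None else np.asarray(ids)
    return StrengthVector(values=values, region_ids=ids)


def bh_oracle(p):
    """Independent step-up oracle: adj_(k) = min_{j>=k} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


class TestConnectionStrength:
    def test_hand_computed(self):
        z = np.array([[0.0, 0.5, -0.2], [0.5, 0.0, 0.1], [-0.2, 0.1, 0.0]])
        s = connection_strength(_mat(z))
        assert np.allclose(s.values, [0.3, 0.6, -0.1])

    def test_zero_matrix(self):
        assert np.all(connection_strength(_mat(np.zeros((4, 4)))).values == 0.0)

    def test_permutation_equivariance(self, rng):
        z = rng.standard_normal((5, 5))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        perm = np.array([2, 0, 4, 3, 1])
        s = connection_strength(_mat(z))
        sp = connection_strength(_mat(z[np.ix_(perm, perm)]))
        assert np.allclose(sp.values, s.values[perm])


class TestDefineHubs:
    def test_hand_computed_threshold(self):
        # strengths [1,1,1,1,10]: mean 2.8, sd 4.0249 -> theta ~ 8.84
        hubs = define_hubs(_sv([1, 1, 1, 1, 10]))
        assert hubs.region_ids == frozenset({5})
        assert hubs.threshold == pytest.approx(2.8 + 1.5 * np.std([1, 1, 1, 1, 10], ddof=1))

    def test_equal_strengths_no_hubs(self):
        with pytest.warns(UserWarning, match="zero strength variance"):
            hubs = define_hubs(_sv([2.0, 2.0, 2.0]))
        assert hubs.region_ids == frozenset()

    def test_k_zero_reduces_to_above_mean(self):
        hubs = define_hubs(_sv([1.0, 2.0, 3.0, 4.0]), k=0.0)
        assert hubs.region_ids == frozenset({3, 4})


class TestProportionalLoss:
    def test_arithmetic(self):
        out = proportional_loss(_sv([2.0]), _sv([1.5]))
        assert out.values[0] == pytest.approx(0.25)

    def test_no_change_zero_loss(self):
        out = proportional_loss(_sv([3.0, 1.0]), _sv([3.0, 1.0]))
        assert np.allclose(out.values, 0.0)

    def test_nonpositive_control_excluded(self):
        out = proportional_loss(_sv([-0.1, 2.0]), _sv([0.0, 1.0]))
        assert out.excluded_regions == (1,)
        assert list(out.region_ids) == [2]


class TestMeanHubStrength:
    def test_single_hub(self):
        hubs = define_hubs(_sv([1, 1, 1, 1, 10]))
        assert mean_hub_strength(_sv([5, 6, 7, 8, 9]), hubs) == 9.0

    def test_two_hub_mean(self):
        from hubvuln.network_stats import HubSet

        hubs = HubSet(frozenset({1, 2}), threshold=0.0, k=1.5)
        assert mean_hub_strength(_sv([2.0, 4.0, 100.0]), hubs) == 3.0

    def test_empty_hub_set_errors(self):
        from hubvuln.network_stats import HubSet

        with pytest.raises(ValueError, match="empty hub set"):
            mean_hub_strength(_sv([1.0]), HubSet(frozenset(), 0.0, 1.5))

    def test_non_hub_edge_edit_leaves_hub_strengths(self, rng):
        z = rng.standard_normal((6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        z2 = z.copy()
        z2[3, 4] += 1.0  # edge between two non-hub regions
        z2[4, 3] += 1.0
        s1 = connection_strength(_mat(z)).values
        s2 = connection_strength(_mat(z2)).values
        assert np.allclose(s1[[0, 1, 2, 5]], s2[[0, 1, 2, 5]])
        assert not np.allclose(s1[[3, 4]], s2[[3, 4]])


class TestPearsonPermutation:
    def test_maximal_statistic_minimal_p(self, rng):
        x = rng.standard_normal(50)
        res = pearson_permutation(x, x, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_constant_input_errors(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_permutation(rng.standard_normal(20), np.ones(20))

    def test_p_on_add_one_lattice(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        res = pearson_permutation(x, y, n_perm=200, seed=1)
        k = res.p_value * 201
        assert abs(k - round(k)) < 1e-9
        assert 1.0 / 201.0 <= res.p_value <= 1.0

    def test_reproducible_given_seed(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a = pearson_permutation(x, y, n_perm=500, seed=9)
        b = pearson_permutation(x, y, n_perm=500, seed=9)
        assert a.p_value == b.p_value


class TestFdrBh:
    def test_worked_example(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1.0, size=10)
        assert np.all(fdr_bh(p) >= p - 1e-12)

    def test_matches_oracle_exhaustively(self, rng):
        for m in range(1, 13):
            for _ in range(20):
                p = rng.uniform(1e-6, 1.0, size=m)
                assert np.allclose(fdr_bh(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(1e-6, 1.0, size=12)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_bh(p), adj)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


class TestBonferroni:
    def test_two_gene_correction(self):
        assert bonferroni(0.0007, 2) == pytest.approx(0.0014)

    def test_capped_at_one(self):
        assert bonferroni(0.6, 2) == 1.0

    def test_identity_at_m1(self):
        assert bonferroni(0.123, 1) == pytest.approx(0.123)

    def test_m_too_small_errors(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_matches_brute_force(self, rng):
        for m in range(1, 13):
            p = rng.uniform(1e-6, 1.0, size=m)
            expected = np.array([min(1.0, v * m) for v in p])
            assert np.allclose(bonferroni(p, m), expected)


class TestGroupwiseStrengthTest:
    def test_label_swap_flips_t(self, rng):
        a = rng.standard_normal((6, 8))
        b = rng.standard_normal((7, 8)) + 0.5
        r1 = groupwise_strength_test(a, b, np.arange(1, 9), n_perm=50, seed=0)
        r2 = groupwise_strength_test(b, a, np.arange(1, 9), n_perm=50, seed=0)
        assert np.allclose(r1.t_values, -r2.t_values)

    def test_identical_groups_no_rejections(self, rng):
        a = rng.standard_normal((10, 12))
        res = groupwise_strength_test(a, a.copy(), np.arange(1, 13), n_perm=200, seed=0)
        assert np.all(res.p_fdr > 0.05)

    def test_planted_attenuation_enriches_hub_regions(self, rng):
        # hub columns 0-2 attenuated in group b -> enriched among significant
        hits = 0
        runs = 15
        for run in range(runs):
            r = np.random.default_rng(run)
            base = r.standard_normal((15, 20)) * 0.3 + 2.0
            a = base + r.standard_normal((15, 20)) * 0.3
            b = base + r.standard_normal((15, 20)) * 0.3
            b[:, :3] -= 2.0
            res = groupwise_strength_test(a, b, np.arange(1, 21), n_perm=300, seed=run)
            sig = res.p_fdr <= 0.05
            hub = np.zeros(20, dtype=bool)
            hub[:3] = True
            odds_sig = (sig & hub).sum() * (~sig & ~hub).sum()
            odds_not = (sig & ~hub).sum() * (~sig & hub).sum()
            hits += odds_sig > odds_not
        assert hits / runs >= 0.85


class TestFluencyCovariance:
    def _data(self, slope, noise_sd, seed, n=20):
        r = np.random.default_rng(seed)
        groups = np.array(["PD"] * n + ["PSP"] * n, dtype=object)
        strength = np.r_[r.normal(10, 2, n), r.normal(8, 2, n)]
        intercept = np.where(groups == "PD", 34.3, 14.1)
        fluency = intercept + slope * strength + r.normal(0, noise_sd, 2 * n)
        return strength, fluency, groups

    def test_strong_slope_recovered(self):
        detected = 0
        for seed in range(20):
            s, f, g = self._data(slope=2.0, noise_sd=2.0, seed=seed)
            res = fluency_covariance(s, f, g, n_perm=200, seed=seed)
            detected += (res.main_p < 0.05) and all(
                r.statistic > 0 for r in res.per_group.values()
            )
        assert detected >= 19

    def test_constant_within_group_fluency(self):
        s, _, g = self._data(slope=0.0, noise_sd=1.0, seed=0)
        fluency = np.where(g == "PD", 34.3, 14.1).astype(float)
        res = fluency_covariance(s, fluency, g, n_perm=100, seed=0)
        assert res.main_F == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_named(self):
        s = np.ones(20)
        f = np.random.default_rng(0).normal(size=20)
        g = np.array(["PD"] * 10 + ["PSP"] * 10, dtype=object)
        with pytest.raises(ValueError, match="strength"):
            fluency_covariance(s, f, g)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError, match="at least 5"):
            fluency_covariance(
                np.arange(6.0),
                np.arange(6.0),
                np.array(["a", "a", "a", "a", "b", "b"], dtype=object),
            )
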