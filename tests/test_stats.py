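"""Behavioural indices, effect sizes, and the cluster permutation machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from repstab.montage import default_montage
from repstab.stats import (cell_adjacency, cluster_permutation, cohens_d,
                           cohens_d_from_summary, correlation_map, dprime,
                           group_compare, icv)

ADJ = default_montage().adjacency_matrix()


class TestDprime:
    @pytest.mark.parametrize("hit,fa,expected", [
        (0.5, 0.5, 0.0),
        (0.84, 0.84, 0.0),
        (0.84, 0.16, ss.norm.ppf(0.84) - ss.norm.ppf(0.16)),
    ])
    def test_values(self, hit, fa, expected):
        assert dprime(hit, fa) == pytest.approx(expected, abs=1e-9)

    def test_quantile_oracle_value(self):
        assert dprime(0.84, 0.16) == pytest.approx(1.989, abs=2e-3)

    def test_extreme_rates_need_counts(self):
        with pytest.raises(ValueError):
            dprime(1.0, 0.2)
        corrected = dprime(1.0, 0.2, n_targets=24)
        assert corrected == pytest.approx(
            ss.norm.ppf(1 - 1 / 48) - ss.norm.ppf(0.2))


class TestICV:
    def test_constant_rts_give_zero(self):
        assert icv([500.0, 500.0, 500.0]) == 0.0

    def test_hand_computed_sample_sd(self):
        assert icv([400.0, 500.0, 600.0]) == pytest.approx(0.2)

    def test_scale_invariance(self, rng):
        rts = rng.uniform(300, 900, 40)
        assert icv(rts) == pytest.approx(icv(2.0 * rts))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            icv([500.0])
        with pytest.raises(ValueError):
            icv([1.0, -3.0])


class TestCohensD:
    def test_recognition_hit_rate_effect_size(self):
        """Printed group summaries reproduce d ~ 0.68 (ASR vs NSD hit rate)."""
        es = cohens_d_from_summary(0.68, 0.11, 14, 0.59, 0.15, 13)
        assert es.d == pytest.approx(0.68, abs=0.015)

    def test_false_alarm_effect_size(self):
        es = cohens_d_from_summary(44.7, 19.0, 13, 38.8, 10.9, 14)
        assert es.d == pytest.approx(0.38, abs=0.015)

    def test_identical_groups(self, rng):
        x = rng.normal(0, 1, 12)
        es = cohens_d(x, x.copy(), n_boot=200, seed=0)
        assert es.d == 0.0
        assert es.cl == pytest.approx(0.5)

    def test_sign_convention_and_ci_brackets_d(self, rng):
        a = rng.normal(1.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        es = cohens_d(a, b, n_boot=2000, seed=1)
        assert es.d > 0
        assert es.ci_95[0] <= es.d <= es.ci_95[1]
        flipped = cohens_d(b, a, n_boot=2000, seed=1)
        assert flipped.d == pytest.approx(-es.d)


class TestGroupCompare:
    def test_identical_samples_adjusted_to_one(self, rng):
        x = rng.normal(size=10)
        res = group_compare(x, x.copy(), n_tests=3)
        assert res["p_adjusted"] == 1.0

    def test_fully_separated_groups_are_extreme(self):
        res = group_compare(np.arange(1.0, 11.0), np.arange(11.0, 21.0))
        assert res["p"] < 1e-3

    def test_nonnormal_data_takes_rank_path(self, rng):
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3 + 1.0
        res = group_compare(a, b)
        assert res["test"] == "mannwhitney"
        assert res["p"] == pytest.approx(
            ss.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    def test_normal_data_takes_t_path(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.2, 1, 60)
        res = group_compare(a, b)
        assert res["test"] == "t"

    def test_bonferroni_cap(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = group_compare(a, b, n_tests=5)
        assert res["p_adjusted"] == min(1.0, res["p"] * 5)


class TestCorrelationMap:
    def test_self_covariate_gives_unit_r(self, rng):
        maps = rng.normal(size=(8, 2, 5))
        cov = maps[:, 1, 3]
        r, z = correlation_map(maps, cov)
        assert r[1, 3] == pytest.approx(1.0, abs=1e-6)

    def test_negating_covariate_negates_map(self, rng):
        maps = rng.normal(size=(10, 3, 6))
        cov = rng.normal(size=10)
        r1, _ = correlation_map(maps, cov)
        r2, _ = correlation_map(maps, -cov)
        np.testing.assert_allclose(r1, -r2, atol=1e-12)

    def test_independent_covariate_near_zero(self, rng):
        maps = rng.normal(size=(24, 6, 40))
        cov = rng.normal(size=24)
        r, _ = correlation_map(maps, cov)
        se = 1 / np.sqrt(24 - 3) / np.sqrt(r.size)
        assert abs(np.nanmean(r)) < 4 * se


# --------------------------------------------------------------------------
# independent brute-force cluster oracle


def brute_force_two_group(maps, is_a, region_adj, threshold_p):
    """Reference implementation: scipy t-tests + BFS clustering."""
    n_sub, n_reg, n_bins = maps.shape
    t = np.empty((n_reg, n_bins))
    for r in range(n_reg):
        for b in range(n_bins):
            t[r, b] = ss.ttest_ind(maps[is_a, r, b], maps[~is_a, r, b]).statistic
    crit = ss.t.ppf(1 - threshold_p / 2, n_sub - 2)
    supra = np.abs(t) > crit

    def neighbours(r, b):
        for bb in (b - 1, b + 1):
            if 0 <= bb < n_bins:
                yield r, bb
        for rr in range(n_reg):
            if region_adj[r, rr]:
                yield rr, b

    seen = set()
    masses = []
    for r in range(n_reg):
        for b in range(n_bins):
            if not supra[r, b] or (r, b) in seen:
                continue
            sign = np.sign(t[r, b])
            stack, comp = [(r, b)], []
            seen.add((r, b))
            while stack:
                cell = stack.pop()
                comp.append(cell)
                for nb in neighbours(*cell):
                    if nb not in seen and supra[nb] and np.sign(t[nb]) == sign:
                        seen.add(nb)
                        stack.append(nb)
            masses.append(sum(t[c] for c in comp))
    return t, masses


class TestClusterPermutation:
    def test_exhaustive_small_n_matches_brute_force_enumeration(self, rng):
        """n=4+4: corrected p over all 70 splits equals an independent oracle."""
        maps = rng.normal(size=(8, 3, 8))
        maps[:4] += 0.9  # make a real effect so clusters exist
        groups = np.array(["A"] * 4 + ["B"] * 4)
        adj = ADJ[:3, :3]
        res = cluster_permutation(maps, "two_group", adj, threshold_p=0.05,
                                  seed=0, groups=groups, exhaustive=True)
        assert res.n_perm == 70
        # oracle: enumerate every split, max cluster mass each
        null = []
        for combo in itertools.combinations(range(8), 4):
            is_a = np.zeros(8, dtype=bool)
            is_a[list(combo)] = True
            _, masses = brute_force_two_group(maps, is_a, adj, 0.05)
            null.append(max((abs(m) for m in masses), default=0.0))
        null = np.array(null)
        _, obs_masses = brute_force_two_group(maps, groups == "A", adj, 0.05)
        obs_sorted = sorted((abs(m) for m in obs_masses), reverse=True)
        res_sorted = sorted((abs(c.mass) for c in res.clusters), reverse=True)
        np.testing.assert_allclose(res_sorted, obs_sorted, atol=1e-10)
        for c in res.clusters:
            assert c.p_corrected == pytest.approx(np.mean(null >= abs(c.mass) - 1e-12))

    def test_planted_block_recovered(self, rng):
        """A 1.5 SD shift in one region x 10-bin block should come out on top."""
        hits = 0
        for i in range(10):
            r2 = np.random.default_rng(100 + i)
            maps = r2.standard_normal((27, 6, 40))
            maps[:13, 2, 10:20] += 1.5
            groups = np.array(["A"] * 13 + ["B"] * 14)
            res = cluster_permutation(maps, "two_group", ADJ, n_perm=300,
                                      seed=i, groups=groups)
            if res.clusters and res.clusters[0].p_corrected < 0.05:
                cells = set(res.clusters[0].cells)
                planted = {(2, b) for b in range(10, 20)}
                if len(cells & planted) >= 5:
                    hits += 1
        assert hits >= 8

    def test_p_floor_and_reproducibility(self, rng):
        maps = rng.standard_normal((14, 6, 40))
        maps[:7] += 2.0
        groups = np.array(["A"] * 7 + ["B"] * 7)
        res1 = cluster_permutation(maps, "two_group", ADJ, n_perm=200, seed=3,
                                   groups=groups)
        res2 = cluster_permutation(maps, "two_group", ADJ, n_perm=200, seed=3,
                                   groups=groups)
        assert [c.p_corrected for c in res1.clusters] == \
               [c.p_corrected for c in res2.clusters]
        for c in res1.clusters:
            assert c.p_corrected >= 1 / 201

    def test_correlation_design_detects_planted_covariate_effect(self, rng):
        cov = rng.normal(size=20)
        maps = rng.standard_normal((20, 6, 40))
        maps[:, 4, 5:15] += 0.8 * cov[:, None]
        res = cluster_permutation(maps, "correlation", ADJ, n_perm=300, seed=5,
                                  covariate=cov)
        assert res.clusters
        top = res.clusters[0]
        assert top.p_corrected < 0.05
        assert top.sign > 0
        assert {(4, b) for b in range(5, 15)} & set(top.cells)

    def test_no_suprathreshold_cells_gives_empty_list(self, rng):
        maps = rng.standard_normal((14, 6, 40))
        groups = np.array(["A"] * 7 + ["B"] * 7)
        res = cluster_permutation(maps, "two_group", ADJ, threshold_p=1e-9,
                                  n_perm=50, seed=1, groups=groups)
        assert res.clusters == []

    def test_cell_adjacency_symmetry(self):
        adj = cell_adjacency(ADJ, 5)
        assert (adj != adj.T).nnz == 0
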