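"""Penetration-level tests, laminar ANOVA, consistency, cluster permutation."""

import numpy as np
import pytest

from lamflow import (
    cluster_permutation,
    compartment_anova,
    paired_test,
    profile_consistency,
    unpaired_test,
)


class TestPairedTest:
    def test_uniform_shift_gives_minimal_one_sided_p(self):
        a = np.arange(10, dtype=float)
        b = a + 1.0
        res = paired_test(b, a, alternative="greater")
        # every difference positive: the one-sided exact p is 1/2^n
        assert np.isclose(res.p, 2.0**-10)

    def test_bonferroni_factor(self):
        a = np.arange(10, dtype=float)
        res1 = paired_test(a + 1, a, alternative="greater")
        res3 = paired_test(a + 1, a, alternative="greater", n_comparisons=3)
        assert np.isclose(res3.p, min(1.0, 3 * res1.p))

    def test_zero_differences_rejected(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="zero"):
            paired_test(a, a)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="5"):
            paired_test([1.0, 2.0], [0.0, 1.0])

    def test_type_i_error_calibrated(self, rng):
        # iid pairs with no true difference: rejection rate ~ attained size
        n_sims, n = 600, 10
        rej = sum(
            paired_test(rng.standard_normal(n), rng.standard_normal(n)).p <= 0.05
            for _ in range(n_sims)
        )
        rate = rej / n_sims
        # exact attained size at n=10 is 0.0488; allow 3 MC SE
        assert abs(rate - 0.0488) < 3 * np.sqrt(0.0488 * 0.9512 / n_sims)


def test_unpaired_rank_sum_detects_shift(rng):
    a = rng.standard_normal(30)
    b = rng.standard_normal(30) + 2.0
    assert unpaired_test(a, b).p < 1e-4
    assert unpaired_test(a, a + 0.0 * a).test == "wilcoxon-rank-sum"


class TestCompartmentAnova:
    def test_detects_laminar_effect(self, rng):
        n = 24
        base = rng.standard_normal(n) * 0.05  # shared penetration offsets
        data = np.column_stack(
            [base + 0.30, base + 0.10, base + 0.30]
        ) + 0.03 * rng.standard_normal((n, 3))
        res = compartment_anova(data, posthoc=True)
        assert res.p < 1e-4
        assert res.posthoc[("deep", "layer4")].p < 0.01
        assert res.posthoc[("layer4", "superficial")].p < 0.01

    def test_epsilon_reported_and_df_reduced_when_corrected(self, rng):
        # strongly non-spherical data: one compartment far noisier
        n = 20
        data = rng.standard_normal((n, 3))
        data[:, 2] *= 8.0
        res = compartment_anova(data, gg_mode="always")
        assert 0.5 <= res.epsilon < 1.0
        assert res.df1 < 2.0

    def test_gg_modes(self, rng):
        data = rng.standard_normal((12, 3))
        always = compartment_anova(data, gg_mode="always")
        gated = compartment_anova(data, gg_mode="mauchly")
        assert gated.p_uncorrected == always.p_uncorrected
        # sample epsilon < 1 almost surely, so "always" shrinks the dfs
        assert always.epsilon < 1.0 and always.df1 < 2.0
        # the gated variant either corrects identically or not at all
        assert gated.p in (always.p, gated.p_uncorrected)
        with pytest.raises(ValueError, match="gg_mode"):
            compartment_anova(data, gg_mode="sometimes")

    def test_too_few_penetrations(self):
        with pytest.raises(ValueError, match="3"):
            compartment_anova(np.zeros((2, 3)))


class TestProfileConsistency:
    def test_within_task_pair_count(self, rng):
        profiles = [rng.standard_normal(20) for _ in range(4)]
        res = profile_consistency(profiles)
        assert res.n_pairs == 6  # N(N-1)/2 with N=4

    def test_identical_profiles_all_r_one(self, rng):
        p = rng.standard_normal(20)
        res = profile_consistency([p.copy() for _ in range(5)])
        assert np.allclose(res.r_values, 1.0)
        assert res.mean_r == 1.0

    def test_between_task_uses_matched_pairs(self, rng):
        a = [rng.standard_normal(20) for _ in range(6)]
        b = [x + 0.1 * rng.standard_normal(20) for x in a]
        res = profile_consistency(a, mode="between_task", other=b)
        assert res.n_pairs == 6
        assert res.mean_r > 0.9

    def test_shuffle_control_destroys_consistency(self, rng):
        base = rng.standard_normal(24)
        profiles = [base + 0.2 * rng.standard_normal(24) for _ in range(8)]
        real = profile_consistency(profiles)
        means = [
            profile_consistency(profiles, shuffle=True, seed=i).mean_r
            for i in range(200)
        ]
        assert real.mean_r > 0.8
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 4 * se + 0.02

    def test_constant_profile_skipped_with_warning(self, rng):
        profiles = [rng.standard_normal(10), np.zeros(10), rng.standard_normal(10)]
        with pytest.warns(UserWarning, match="constant"):
            res = profile_consistency(profiles)
        assert res.n_pairs == 1


class TestClusterPermutation:
    def test_all_zero_maps_have_no_clusters(self):
        maps = np.zeros((8, 10, 12))
        res = cluster_permutation(maps, n_perm=100, seed=0)
        assert len(res.cluster_masses) == 0
        assert res.p_values.size == 0

    def test_strong_localized_effect_found_in_its_band(self, rng):
        # effect confined to channels 2-4: significant clusters live there
        maps = 0.5 * rng.standard_normal((10, 12, 30))
        maps[:, 2:5, 10:25] += 3.0
        res = cluster_permutation(maps, n_perm=300, seed=1)
        sig = np.flatnonzero(res.significant)
        assert sig.size >= 1
        union = np.zeros((12, 30), bool)
        for i in sig:
            union |= res.clusters[i]
        chans = np.flatnonzero(union.any(axis=1))
        assert set(chans) <= {1, 2, 3, 4, 5}
        assert {2, 3, 4} <= set(chans)

    def test_seed_determinism(self, rng):
        maps = rng.standard_normal((9, 8, 20))
        r1 = cluster_permutation(maps, n_perm=150, seed=7)
        r2 = cluster_permutation(maps, n_perm=150, seed=7)
        assert np.array_equal(r1.p_values, r2.p_values)
        assert np.array_equal(r1.t_map, r2.t_map)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError, match="8"):
            cluster_permutation(rng.standard_normal((5, 4, 6)), n_perm=100)
        with pytest.raises(ValueError, match="100"):
            cluster_permutation(rng.standard_normal((9, 4, 6)), n_perm=50)
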