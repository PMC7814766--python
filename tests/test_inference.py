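"""Center-paired permutation machinery, FDR, regionwise tests, correlations."""

import numpy as np
import pandas as pd
import pytest

from scnet.graphmetrics import HubProfile
from scnet.inference import (
    center_paired_shuffle,
    correlate_structure_centrality,
    fdr_correct,
    permutation_test,
    regionwise_group_test,
    unstratified_shuffle,
)
from scnet.preprocess import region_columns
from scnet.synthetic import SyntheticConfig, generate_cohort


def labelled(sites_counts):
    """Group and site label arrays from {site: (nA, nB)}."""
    groups, sites = [], []
    for site, (n_a, n_b) in sites_counts.items():
        groups += ["A"] * n_a + ["B"] * n_b
        sites += [site] * (n_a + n_b)
    return np.array(groups), np.array(sites)


class TestCenterPairedShuffle:
    def test_per_site_counts_preserved_always(self):
        groups, sites = labelled({"s1": (3, 3), "s2": (2, 2)})
        rng = np.random.default_rng(0)
        for _ in range(200):
            permuted = center_paired_shuffle(groups, sites, seed=rng)
            for site in ("s1", "s2"):
                original = groups[sites == site]
                new = permuted[sites == site]
                assert sorted(original) == sorted(new)

    def test_two_subject_site_arrangements_uniform(self):
        """Both arrangements of a 2-subject site appear ~50% of the time."""
        groups, sites = labelled({"s1": (1, 1)})
        rng = np.random.default_rng(1)
        flipped = sum(
            center_paired_shuffle(groups, sites, seed=rng)[0] == "B"
            for _ in range(10_000)
        )
        assert abs(flipped / 10_000 - 0.5) < 0.02

    def test_unstratified_can_concentrate_a_site_but_stratified_never(self):
        groups, sites = labelled({"s1": (2, 2), "s2": (2, 2)})
        rng = np.random.default_rng(2)
        concentrated = 0
        for _ in range(500):
            plain = unstratified_shuffle(groups, seed=rng)
            if len(set(plain[sites == "s1"])) == 1:
                concentrated += 1
            paired = center_paired_shuffle(groups, sites, seed=rng)
            assert len(set(paired[sites == "s1"])) == 2
        assert concentrated > 0

    def test_single_group_site_rejected(self):
        groups, sites = labelled({"s1": (4, 0), "s2": (2, 2)})
        with pytest.raises(ValueError, match="one group"):
            center_paired_shuffle(groups, sites, seed=0)

    def test_double_shuffle_is_still_valid_stratified_labeling(self):
        """Within-site exchangeability: shuffles compose to valid shuffles."""
        groups, sites = labelled({"s1": (3, 2), "s2": (1, 4)})
        once = center_paired_shuffle(groups, sites, seed=3)
        twice = center_paired_shuffle(once, sites, seed=4)
        for site in ("s1", "s2"):
            assert sorted(twice[sites == site]) == sorted(groups[sites == site])


def small_residuals(seed=0, n=12):
    config = SyntheticConfig(
        n_regions=6,
        module_labels=np.ones(6, dtype=int),
        per_site_counts={"s1": n // 2, "s2": n // 2},
        rho_within=0.2,
        rho_between=0.2,
        seed=seed,
    )
    return generate_cohort(config)


class TestPermutationTest:
    def test_null_median_statistic_gives_p_near_one(self):
        table = small_residuals()

        def constant_stat(a, b):
            return 0.0

        result = permutation_test(table, constant_stat, n_perm=99, seed=0)
        assert result.p[0] == 1.0

    def test_add_one_correction_bounds_p(self):
        table = small_residuals()

        def extreme_stat(a, b):
            return a.mean() - b.mean() + 100.0  # observed far beyond any null

        # null values also contain the +100 offset, so this stays a sanity
        # check that p can never be 0
        result = permutation_test(table, extreme_stat, n_perm=50, seed=1)
        assert result.p[0] >= 1 / 51

    def test_vector_statistic_and_ci_shapes(self):
        table = small_residuals()

        def mean_diff_vector(a, b):
            return a.mean(axis=0) - b.mean(axis=0)

        result = permutation_test(table, mean_diff_vector, n_perm=60, seed=2)
        assert result.observed.shape == (6,)
        assert result.null.shape == (60, 6)
        assert np.all(result.ci_low <= result.ci_high)
        assert np.all((result.p > 0) & (result.p <= 1))

    def test_failing_statistic_aborts_with_diagnostics(self):
        """Failures on permuted splits are tolerated up to 1%, then abort."""
        table = small_residuals()
        regions = region_columns(table)
        original_a = table[table["group"] == "A"][regions].to_numpy(float)

        def fails_off_observed(a, b):
            if a.shape != original_a.shape or not np.allclose(a, original_a):
                raise ValueError("degenerate pseudo-group")
            return 0.0

        with pytest.raises(RuntimeError, match="degenerate"):
            permutation_test(table, fails_off_observed, n_perm=50, seed=3)

    def test_reproducible(self):
        table = small_residuals()

        def stat(a, b):
            return float(a.std() - b.std())

        r1 = permutation_test(table, stat, n_perm=40, seed=9)
        r2 = permutation_test(table, stat, n_perm=40, seed=9)
        np.testing.assert_array_equal(r1.null, r2.null)


class TestFdr:
    def test_all_ones_no_rejections(self):
        q, reject = fdr_correct([1.0] * 5)
        assert not reject.any()

    def test_all_tiny_all_rejected(self):
        q, reject = fdr_correct([0.001] * 10)
        assert reject.all()

    def test_hand_computed_bh(self):
        # p sorted: 0.01*4/1? BH: q_i = min over j>=i of p_j * m / j
        q, reject = fdr_correct([0.01, 0.02, 0.03, 0.2], q_level=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.2])
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 20)
        q, _ = fdr_correct(p)
        assert np.all(q >= p - 1e-12)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])


class TestRegionwise:
    def test_single_region_family_q_equals_p(self):
        config = SyntheticConfig(
            n_regions=2,
            module_labels=np.ones(2, dtype=int),
            per_site_counts={"s1": 10},
            rho_within=0.0,
            rho_between=0.0,
            seed=4,
        )
        table = generate_cohort(config)[
            ["subject_id", "site", "group", "age", "sex", "fiq", "region_001"]
        ]
        result = regionwise_group_test(table, n_perm=200, seed=0)
        assert result.q[0] == pytest.approx(result.p[0])

    def test_null_rejection_fraction_nominal(self):
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(20):
            table = small_residuals(seed=int(rng.integers(2**31)), n=40)
            result = regionwise_group_test(table, n_perm=200, seed=int(rng.integers(2**31)))
            rates.append(np.mean(result.p < 0.05))
        assert np.mean(rates) < 0.10

    def test_shifted_region_detected(self):
        """A 2-pooled-SD shift in one region is found with high probability."""
        rng = np.random.default_rng(6)
        hits = 0
        n_sims = 10
        for _ in range(n_sims):
            table = small_residuals(seed=int(rng.integers(2**31)), n=150)
            regions = region_columns(table)
            pooled_sd = table[regions[0]].std()
            table.loc[table["group"] == "B", regions[0]] += 2 * pooled_sd
            result = regionwise_group_test(table, n_perm=500, seed=int(rng.integers(2**31)))
            hits += bool(result.q[0] < 0.05)
        assert hits >= 9


class TestStructureCentralityCorrelation:
    def make_profile(self, z):
        z = np.asarray(z, float)
        return HubProfile(
            regions=[f"region_{i + 1:03d}" for i in range(len(z))],
            mean_centrality=z,
            z_scores=z,
            group="A",
        )

    def test_perfectly_aligned_vectors(self):
        table = small_residuals(n=20)
        regions = region_columns(table)
        mean_structure = (
            table[table["group"] == "A"][regions].to_numpy(float).mean(axis=0)
        )
        r, p = correlate_structure_centrality(table, self.make_profile(mean_structure))
        assert r == pytest.approx(1.0)

    def test_sign_convention(self):
        table = small_residuals(n=20)
        rng = np.random.default_rng(8)
        profile = self.make_profile(rng.normal(size=6))
        r_pos, _ = correlate_structure_centrality(table, profile)
        negated = table.copy()
        negated[region_columns(table)] *= -1
        r_neg, _ = correlate_structure_centrality(negated, profile)
        assert r_neg == pytest.approx(-r_pos)

    def test_null_calibration(self):
        """Independent structure and centrality: p < .05 about 5% of the time."""
        rng = np.random.default_rng(9)
        n_regions, n_sims = 148, 1000
        regions = [f"region_{i + 1:03d}" for i in range(n_regions)]
        rejections = 0
        for _ in range(n_sims):
            table = pd.DataFrame(
                rng.normal(size=(10, n_regions)), columns=regions
            )
            table.insert(0, "group", "A")
            table.insert(0, "site", "s1")
            profile = self.make_profile(rng.normal(size=n_regions))
            _, p = correlate_structure_centrality(table, profile)
            rejections += p < 0.05
        assert 0.03 < rejections / n_sims < 0.07

    def test_zero_variance_rejected(self):
        table = small_residuals(n=20)
        table[region_columns(table)] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_structure_centrality(table, self.make_profile(np.arange(6.0)))
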