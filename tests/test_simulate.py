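"""Simulator contracts: neutral SFS, Watterson counts, selection dynamics."""

import numpy as np
import pytest
from scipy import stats as sps

from sweepscan.simulate import (SimParams, evolve, neutral_source,
                                sample_haplotypes, split_populations)


class TestParams:
    def test_desk_scaling_preserves_population_rates(self, desk_params):
        full = SimParams()
        assert desk_params.theta_region == pytest.approx(full.theta_region)
        assert desk_params.rho_region == pytest.approx(full.rho_region)
        assert desk_params.N_e * desk_params.s == pytest.approx(full.N_e * full.s)
        assert desk_params.scale_time(700) == 70

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(N_e=1)
        with pytest.raises(ValueError):
            SimParams(mu=-1e-9)


N_SFS_REPS = 200


@pytest.fixture(scope="module")
def replicate_sfs(desk_params):
    """Census SFS (one row per replicate) over independent neutral sources."""
    n_hap = 2 * desk_params.N_e
    out = np.zeros((N_SFS_REPS, n_hap), dtype=np.int64)
    for rep in range(N_SFS_REPS):
        pop = neutral_source(desk_params, seed=1_000 + rep)
        out[rep] = np.bincount(pop.allele_counts(), minlength=n_hap)[:n_hap]
    return out


class TestNeutralSource:
    def test_sfs_proportional_to_theta_over_f(self, replicate_sfs, desk_params):
        """Goodness of fit of the binned SFS against the neutral
        expectation E[#alleles at derived count i] = theta/i.

        Linked sites share genealogies, so pooled counts are heavily
        overdispersed relative to Poisson; the valid test compares the
        replicate-mean bin counts to expectation with the empirical
        between-replicate covariance (Hotelling's T-squared)."""
        n_hap = replicate_sfs.shape[1]
        i = np.arange(1, n_hap)
        edges = [1, 2, 3, 4, 6, 9, 14, 25, 50, 100, n_hap]
        X = np.stack([
            replicate_sfs[:, 1:][:, (i >= lo) & (i < hi)].sum(axis=1)
            for lo, hi in zip(edges[:-1], edges[1:])], axis=1).astype(float)
        expected = np.array([
            (desk_params.theta_region / i[(i >= lo) & (i < hi)]).sum()
            for lo, hi in zip(edges[:-1], edges[1:])])
        R, k = X.shape
        d = X.mean(axis=0) - expected
        t2 = R * d @ np.linalg.solve(np.cov(X.T), d)
        f_stat = (R - k) / (k * (R - 1)) * t2
        p = sps.f.sf(f_stat, k, R - k)
        assert p > 0.01

    def test_singleton_doubleton_ratio(self, replicate_sfs):
        pooled = replicate_sfs.sum(axis=0)
        assert pooled[1] / pooled[2] == pytest.approx(2.0, rel=0.10)

    def test_watterson_segregating_sites(self, replicate_sfs, desk_params):
        """E[S] = theta * sum_{i<2N} 1/i, within Monte-Carlo tolerance."""
        n_hap = replicate_sfs.shape[1]
        expected = desk_params.theta_region * np.sum(1.0 / np.arange(1, n_hap))
        assert replicate_sfs.sum() / len(replicate_sfs) == pytest.approx(
            expected, rel=0.05)

    def test_zero_mutation_rate_is_monomorphic(self, desk_params):
        import dataclasses
        p = dataclasses.replace(desk_params, mu=0.0)
        assert neutral_source(p, seed=5).n_sites == 0

    def test_forward_burnin_route_matches_watterson(self):
        """The forward burn-in alternative reaches the same equilibrium
        scale of diversity (checked loosely at a small population)."""
        p = SimParams(N_e=30, mu=2e-5, r=0.0, s=0.0, L=5_000)
        n_hap = 2 * p.N_e
        expected = p.theta_region * np.sum(1.0 / np.arange(1, n_hap))
        sites = [neutral_source(p, seed=50 + r, method="forward").n_sites
                 for r in range(25)]
        assert np.mean(sites) == pytest.approx(expected, rel=0.25)


class TestSplit:
    def test_deterministic_given_seed(self, desk_params):
        src = neutral_source(desk_params, seed=3)
        a = split_populations(src, np.random.default_rng(42))
        b = split_populations(src, np.random.default_rng(42))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.haplotypes, y.haplotypes)

    def test_monomorphic_source_stays_monomorphic(self, desk_params, rng):
        import dataclasses
        src = neutral_source(dataclasses.replace(desk_params, mu=0.0), seed=5)
        for pop in split_populations(src, rng):
            assert pop.n_sites == 0

    def test_post_split_frequency_noise_is_binomial(self, desk_params, rng):
        """Immediately after a with-replacement split, a common allele's
        frequency varies around the source value with ~binomial s.d."""
        src = neutral_source(desk_params, seed=7)
        counts = src.allele_counts()
        j = int(np.argmin(np.abs(counts - src.n_hap // 2)))
        p0 = counts[j] / src.n_hap
        pos = src.positions[j]
        devs = []
        for _ in range(120):
            (daughter,) = split_populations(src, rng, n_populations=1)
            k = np.searchsorted(daughter.positions, pos)
            freq = daughter.haplotypes[:, k].mean() if (
                k < daughter.n_sites and daughter.positions[k] == pos) else \
                round(p0)  # lost or fixed in the daughter
            devs.append(freq - p0)
        sd = np.std(devs)
        expected_sd = np.sqrt(p0 * (1 - p0) / src.n_hap)
        assert sd == pytest.approx(expected_sd, rel=0.3)


class TestEvolve:
    def test_neutral_drift_is_a_martingale(self, desk_params, rng):
        """Under s=0 the mean frequency change across replicates ~ 0."""
        import dataclasses
        p = dataclasses.replace(desk_params, s=0.0)
        src = neutral_source(p, seed=11)
        counts = src.allele_counts()
        j = int(np.argmin(np.abs(counts - src.n_hap // 2)))
        p0 = counts[j] / src.n_hap
        pos = src.positions[j]
        changes = []
        for _ in range(100):
            (pop,) = split_populations(src, rng, n_populations=1)
            out = evolve(pop, p, 20, selected=False, rng=rng)
            k = np.searchsorted(out.positions, pos)
            # absorption of a ~50% allele within 20 generations is
            # vanishingly rare at N_e=100; skip the replicate if it happens
            if k < out.n_sites and out.positions[k] == pos:
                changes.append(out.haplotypes[:, k].mean() - p0)
        assert len(changes) > 90
        assert abs(np.mean(changes)) < 3 * np.std(changes) / np.sqrt(len(changes)) + 0.02

    def test_selection_fixes_the_beneficial_allele(self, desk_params, rng):
        """s=0.2 (scaled 2Ns=40), tau=150: fixed in >=95% of survivors."""
        fixed = 0
        reps = 40
        for _ in range(reps):
            src = neutral_source(desk_params, seed=int(rng.integers(1, 2**31 - 1)))
            (pop,) = split_populations(src, rng, n_populations=1)
            out = evolve(pop, desk_params, 150, selected=True, rng=rng)
            fixed += out.selected_fixed_at is not None
        assert fixed / reps >= 0.95

    def test_complete_hitchhiking_without_recombination(self, rng):
        """r=0, mu=0: at fixation every haplotype is identical at the
        sites present when the beneficial allele arose."""
        p = SimParams(N_e=50, mu=2e-5, r=0.0, s=0.3, L=5_000)
        src = neutral_source(p, seed=17)
        (pop,) = split_populations(src, rng, n_populations=1)
        import dataclasses
        frozen = dataclasses.replace(p, mu=0.0)
        out = evolve(pop, frozen, 120, selected=True, rng=rng)
        assert out.selected_fixed_at is not None
        assert out.n_sites == 0  # everything hitchhiked to fixation or was lost

    def test_restart_counter_records_conditioning(self, desk_params, rng):
        restarts = []
        for _ in range(10):
            src = neutral_source(desk_params, seed=int(rng.integers(1, 2**31 - 1)))
            (pop,) = split_populations(src, rng, n_populations=1)
            out = evolve(pop, desk_params, 30, selected=True, rng=rng)
            restarts.append(out.restarts)
        assert all(r >= 0 for r in restarts)
        assert any(r > 0 for r in restarts)  # single-copy loss is common


class TestSampling:
    def test_census_returns_exact_population_frequencies(self, desk_params, rng):
        pop = neutral_source(desk_params, seed=23)
        pos, counts = sample_haplotypes(pop, pop.n_hap, rng)
        np.testing.assert_array_equal(counts, pop.allele_counts())

    def test_oversampling_rejected(self, desk_params, rng):
        pop = neutral_source(desk_params, seed=23)
        with pytest.raises(ValueError):
            sample_haplotypes(pop, pop.n_hap + 1, rng)

    def test_seed_determinism(self, desk_params):
        pop = neutral_source(desk_params, seed=23)
        a = sample_haplotypes(pop, 12, np.random.default_rng(9))
        b = sample_haplotypes(pop, 12, np.random.default_rng(9))
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_sample_spread_matches_binomial_ci(self, desk_params, rng):
        """Sampling n=12 of an allele at ~0.5: the central 95% spread of
        observed frequencies matches the exact binomial half-width used
        by the prioritization threshold (~0.25)."""
        from sweepscan.prioritize import sampling_ci_threshold
        pop = neutral_source(desk_params, seed=29)
        counts = pop.allele_counts()
        j = int(np.argmin(np.abs(counts - pop.n_hap // 2)))
        f = counts[j] / pop.n_hap
        obs = []
        for _ in range(400):
            _, c = sample_haplotypes(pop, 12, rng)
            obs.append(c[j] / 12)
        lo, hi = np.quantile(obs, [0.025, 0.975])
        half = max(f - lo, hi - f)
        assert half == pytest.approx(sampling_ci_threshold(12, f), abs=0.09)
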