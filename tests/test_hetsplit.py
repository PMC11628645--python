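"""Beta-binomial segmentation: MLE, split scan, hierarchy, permutation test.

The heavier checks compare the implementation against independent oracles:
a lattice grid search for the beta-binomial MLE, a naive re-scan with
scipy.stats.betabinom for the best split, and exhaustive multinomial
enumeration for the permutation p-value.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invscan.hetsplit import (
    _sliding3_variance,
    best_split,
    betabin_loglik,
    bh_adjust,
    fit_betabin,
    het_observations,
    hierarchical_split,
    split_cluster_test,
)

from conftest import make_table


def _simulate_betabin(rng, m, n_per, mu, rho):
    n = np.full(m, n_per)
    if rho > 0:
        p = rng.beta(mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho, size=m)
    else:
        p = np.full(m, mu)
    return rng.binomial(n, p), n


class TestFitBetabin:
    def test_single_observation_mle_at_proportion(self):
        fit = fit_betabin(np.array([5]), np.array([10]))
        assert fit.mu == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_counts_pins_mu_at_boundary(self):
        fit = fit_betabin(np.zeros(20), np.full(20, 30))
        assert fit.mu <= 1e-4

    def test_all_n_zero_raises(self):
        with pytest.raises(ValueError):
            fit_betabin(np.zeros(3), np.zeros(3))

    def test_recovery_against_grid_oracle(self, rng):
        """MLE recovers (mu, rho) and beats every point of a lattice oracle."""
        k, n = _simulate_betabin(rng, 500, 40, mu=0.2, rho=0.05)
        fit = fit_betabin(k, n)
        assert fit.mu == pytest.approx(0.2, abs=0.02)
        assert fit.rho == pytest.approx(0.05, abs=0.03)
        # independent oracle: dense grid evaluated with scipy.stats.betabinom
        best_grid = -np.inf
        for mu in np.linspace(0.05, 0.5, 46):
            for rho in np.linspace(0.005, 0.2, 40):
                nu = (1 - rho) / rho
                ll = stats.betabinom.logpmf(k, n, mu * nu, (1 - mu) * nu).sum()
                best_grid = max(best_grid, ll)
        assert fit.loglik >= best_grid - 1e-6

    def test_loglik_matches_scipy(self, rng):
        k, n = _simulate_betabin(rng, 50, 30, mu=0.3, rho=0.1)
        mu, rho = 0.27, 0.08
        nu = (1 - rho) / rho
        expected = stats.betabinom.logpmf(k, n, mu * nu, (1 - mu) * nu).sum()
        assert betabin_loglik(k, n, mu, rho) == pytest.approx(expected)


def _scan_oracle(cm, k, n, cands):
    """Naive best-split search: per candidate, maximize the split likelihood
    over a dense-then-refined grid with scipy.stats.betabinom only."""

    def seg_ll(kk, nn, mu, rho):
        nu = (1 - rho) / rho
        return stats.betabinom.logpmf(kk, nn, mu * nu, (1 - mu) * nu).sum()

    best_c, best_ll = None, -np.inf
    for c in cands:
        left = cm < c
        ll_c = -np.inf
        for rho in np.linspace(0.002, 0.3, 25):
            mus_l = np.linspace(0.01, 0.99, 99)
            ll_l = max(seg_ll(k[left], n[left], m, rho) for m in mus_l)
            ll_r = max(seg_ll(k[~left], n[~left], m, rho) for m in mus_l)
            ll_c = max(ll_c, ll_l + ll_r)
        if ll_c > best_ll:
            best_ll, best_c = ll_c, c
    return best_c, best_ll


class TestBestSplit:
    def test_step_data_recovers_boundary(self, rng):
        cm = (np.arange(40) + 0.5) * 0.25  # 40 contigs over 10 cM
        n = np.full(40, 60)
        mu = np.where(cm < 5, 0.1, 0.4)
        k = rng.binomial(n, mu)
        scan = best_split(cm, k, n)
        assert scan.split_cm == pytest.approx(5.0, abs=1.0)
        assert scan.significant

    def test_matches_naive_scan_oracle(self, rng):
        cm = (np.arange(24) + 0.5) * 0.5  # 24 contigs over 12 cM
        n = np.full(24, 40)
        k = rng.binomial(n, np.where(cm < 7, 0.15, 0.35))
        scan = best_split(cm, k, n)
        oracle_c, oracle_ll = _scan_oracle(cm, k, n, scan.candidates["cm"].to_numpy())
        assert scan.split_cm == oracle_c
        # full likelihood must dominate the oracle's coarse grid
        assert scan.candidates["loglik"].max() >= oracle_ll - 1e-6

    def test_nesting_ll1_ge_ll0(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            cm = (np.arange(20) + 0.5) * 0.5
            k, n = _simulate_betabin(r, 20, 30, mu=0.25, rho=0.05)
            scan = best_split(cm, k, n)
            assert (scan.candidates["loglik"] >= scan.null_fit.loglik - 1e-6).all()
            assert (scan.candidates["lrt"] >= 0).all()

    def test_single_window_returns_none(self):
        cm = np.array([0.2, 0.4, 0.6])
        assert best_split(cm, np.array([1, 2, 1]), np.array([10, 10, 10])) is None

    def test_type_one_error_controlled(self):
        """Homogeneous heterozygosity: no significant split in >=95% of replicates."""
        hits = 0
        reps = 100
        cm = (np.arange(40) + 0.5) * 0.125  # 40 contigs over 5 cM
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            k, n = _simulate_betabin(r, 40, 50, mu=0.2, rho=0.05)
            scan = best_split(cm, k, n)
            hits += scan is not None and scan.significant
        assert hits / reps <= 0.05


class TestHierarchicalSplit:
    def test_homogeneous_single_segment(self, rng):
        cm = (np.arange(30) + 0.5) * 0.25
        k, n = _simulate_betabin(rng, 30, 40, mu=0.2, rho=0.03)
        seg = hierarchical_split(cm, k, n)
        assert seg.n_segments == 1
        assert seg.splits == []

    def test_three_changepoints_recovered(self, rng):
        """Nested steps at 5, 10, 15 cM -> 4 segments, splits within 1 cM."""
        cm = (np.arange(80) + 0.5) * 0.25  # 80 contigs over 20 cM
        n = np.full(80, 80)
        mu = np.select(
            [cm < 5, cm < 10, cm < 15], [0.05, 0.2, 0.45], default=0.25
        )
        k = rng.binomial(n, mu)
        seg = hierarchical_split(cm, k, n, lg_start=0.0, lg_end=20.0)
        assert seg.n_segments == 4
        for true, got in zip([5.0, 10.0, 15.0], seg.splits):
            assert got == pytest.approx(true, abs=1.0)

    def test_segments_tile_lg_and_means_are_mles(self, rng):
        cm = (np.arange(60) + 0.5) * 0.25
        n = np.full(60, 60)
        k = rng.binomial(n, np.where(cm < 8, 0.1, 0.35))
        seg = hierarchical_split(cm, k, n, lg_start=0.0, lg_end=15.0)
        bounds = [seg.segments[0][0]] + [s[1] for s in seg.segments]
        assert bounds[0] == 0.0 and bounds[-1] == 15.0
        assert bounds == sorted(bounds)
        for lo, hi, h in seg.segments:
            m = (cm >= lo) & (cm < hi) if hi < 15.0 else (cm >= lo) & (cm <= hi)
            assert h == pytest.approx(fit_betabin(k[m], n[m]).mu, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_at_most_eight_segments(self, seed):
        """Three split levels bound any segmentation at 8 segments."""
        r = np.random.default_rng(seed)
        m = int(r.integers(4, 40))
        cm = np.sort(r.uniform(0, r.integers(3, 25), size=m))
        n = r.integers(1, 60, size=m)
        k = r.binomial(n, r.uniform(0, 1, size=m))
        seg = hierarchical_split(cm, k, n)
        assert 1 <= seg.n_segments <= 8
        assert len(seg.splits) == seg.n_segments - 1


def test_het_observations_counts_hand_checked():
    g = np.array(
        [
            [1, 0, 1, -1],
            [2, 1, -1, 1],
        ],
        dtype=np.int8,
    )
    table = make_table(g, cms=[0.5, 0.5, 2.5, 2.5], contigs=["c1", "c1", "c2", "c2"])
    obs = het_observations(table)
    row = obs.set_index(["individual", "contig"])
    assert row.loc[("ind0", "c1"), "k"] == 1 and row.loc[("ind0", "c1"), "n"] == 2
    assert row.loc[("ind0", "c2"), "k"] == 1 and row.loc[("ind0", "c2"), "n"] == 1
    assert row.loc[("ind1", "c2"), "k"] == 1 and row.loc[("ind1", "c2"), "n"] == 1


class TestSplitClusterTest:
    def test_sliding_variance_hand_computed(self):
        counts = np.array([2.0, 0, 1, 0, 0, 3])
        # 3-window sums: [3, 1, 1, 3]; population variance = 1
        assert _sliding3_variance(counts) == pytest.approx(1.0)

    def test_concentrated_splits_minimal_p(self):
        res = split_cluster_test(
            np.full(12, 4.0), eligible_windows=np.arange(10), reps=2000, seed=0
        )
        assert res.p_emp == pytest.approx(1 / 2001)

    def test_uniform_splits_large_p(self):
        splits = np.arange(10) + 0.5  # one split per window
        res = split_cluster_test(splits, np.arange(10), reps=2000, seed=0)
        assert res.p_emp > 0.5

    def test_zero_splits_degenerate(self):
        res = split_cluster_test(np.array([]), np.arange(5), reps=100, seed=0)
        assert res.p_emp == 1.0 and res.degenerate

    def test_needs_three_windows(self):
        with pytest.raises(ValueError):
            split_cluster_test(np.array([1.5]), np.arange(2), reps=10, seed=0)

    def test_against_exhaustive_enumeration(self):
        """Small case (6 windows, 6 splits): empirical p matches the exact
        multinomial tail probability."""
        splits = np.array([0.5, 0.5, 1.5, 3.5, 3.5, 5.5])
        windows = np.arange(6)
        res = split_cluster_test(splits, windows, reps=20_000, seed=1)
        # exact: enumerate all compositions of 6 splits into 6 windows
        obs_counts = np.zeros(6)
        for s in splits:
            obs_counts[int(np.floor(s))] += 1
        obs_var = _sliding3_variance(obs_counts)
        exact = 0.0
        for comp in itertools.product(range(7), repeat=6):
            if sum(comp) != 6:
                continue
            prob = stats.multinomial.pmf(comp, n=6, p=np.full(6, 1 / 6))
            if _sliding3_variance(np.array(comp, float)) >= obs_var - 1e-12:
                exact += prob
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert res.p_emp == pytest.approx(exact, abs=3 * se + 1e-4)

    def test_super_uniform_under_null(self):
        """p-values simulated under the multinomial null never exceed uniform
        rejection rates by more than Monte-Carlo error."""
        rng = np.random.default_rng(3)
        windows = np.arange(12)
        pvals = []
        for _ in range(300):
            counts = rng.multinomial(15, np.full(12, 1 / 12))
            splits = np.concatenate([np.full(c, w + 0.5) for w, c in enumerate(counts)])
            res = split_cluster_test(splits, windows, reps=400, seed=rng)
            pvals.append(res.p_emp)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            rate = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / 300)
            assert rate <= alpha + 3 * se


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # step-up: [0.01*3/1, 0.02*3/2, 0.03*3/3] -> monotone -> [0.03, 0.03, 0.03]
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_singleton_unchanged(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_dominates_input_and_capped(self, rng):
        p = rng.uniform(0, 1, size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
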