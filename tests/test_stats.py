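import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculomet.stats import (bh_adjust, compare_edss_subgroups, mannwhitney,
                            spearman, spearman_with_fdr)


def bh_reject_bruteforce(pvals, alpha):
    """Independent step-up oracle: largest k with p_(k) <= k*alpha/m,
    rejecting the k smallest p-values."""
    p = np.sort(np.asarray(pvals))
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[k - 1] <= k * alpha / m + 1e-12:
            k_star = k
    thresh = p[k_star - 1] if k_star else -1.0
    return np.asarray(pvals) <= thresh


def bh_adjust_bruteforce(pvals):
    """Adjusted p = smallest alpha at which the hypothesis is rejected,
    searching over every alpha where the step-up decision can change."""
    out = np.empty(len(pvals))
    m = len(pvals)
    alphas = np.unique(np.concatenate([
        np.sort(np.asarray(pvals)) * m / (np.arange(m) + 1.0), [1.0]]))
    alphas = np.clip(alphas, 0, 1)
    for i in range(len(pvals)):
        rejected = [a for a in alphas if bh_reject_bruteforce(pvals, a)[i]]
        out[i] = min(rejected) if rejected else 1.0
    return out


class TestBenjaminiHochberg:
    def test_worked_example_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, 0.05, atol=1e-12)
        assert bh_reject_bruteforce(p, 0.05).all()

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = rng.integers(2, 12)
            p = np.round(rng.uniform(0, 1, m), 3)
            np.testing.assert_allclose(bh_adjust(p), bh_adjust_bruteforce(p),
                                       atol=1e-9)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_bh_rejects_at_least_as_many_as_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.uniform(0, 0.2, 20)
            bh = bh_adjust(p) < 0.05
            bonf = p < 0.05 / len(p)
            assert bh[bonf].all()


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        rho, p, n = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert n == 5

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _, _ = spearman(x, y)
        rho2, _, _ = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan, 12.0])
        rho, p, n = spearman(x, y)
        assert n == 4
        assert rho == pytest.approx(1.0)

    def test_exact_small_sample_p_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        rho, p, _ = spearman(x, y)
        # enumerate all 120 pairings
        from scipy.stats import spearmanr
        rhos = [spearmanr(x, np.array(perm)).statistic
                for perm in itertools.permutations(y)]
        expected = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged_nan(self):
        rho, p, n = spearman(np.ones(10), np.arange(10))
        assert np.isnan(rho)


class TestCorrelationGrid:
    def make_data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        sev = rng.uniform(0, 1, n)
        profiles = pd.DataFrame({
            "lat": 200 + 100 * sev + rng.normal(0, 5, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        outcomes = pd.DataFrame({"edss": 1 + 6 * sev + rng.normal(0, 0.3, n)})
        return profiles, outcomes

    def test_planted_coupling_significant_and_positive(self):
        profiles, outcomes = self.make_data(n=200, seed=3)
        res = spearman_with_fdr(profiles, outcomes)
        row = res[(res.parameter == "lat") & (res.outcome == "edss")].iloc[0]
        assert row.rho > 0.5
        assert row.significant
        assert row.p_adj >= row.p_raw - 1e-15

    def test_family_scope_is_per_outcome(self):
        profiles, outcomes = self.make_data()
        outcomes["msfc"] = -outcomes["edss"] + 0.1
        res = spearman_with_fdr(profiles, outcomes, family="per_outcome")
        assert len(res) == 6
        assert res.attrs["bh_family"] == "per_outcome"
        for _, grp in res.groupby("outcome"):
            np.testing.assert_allclose(
                grp["p_adj"].values, bh_adjust(grp["p_raw"].values),
                atol=1e-12)


class TestMannWhitney:
    def test_exact_p_on_separated_triplets(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/C(6,3) = 0.1."""
        u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)
        # full enumeration oracle
        pooled = [1, 2, 3, 4, 5, 6]
        stats = []
        for combo in itertools.combinations(range(6), 3):
            grp1 = [pooled[i] for i in combo]
            grp2 = [pooled[i] for i in range(6) if i not in combo]
            u12 = sum(a > b for a in grp1 for b in grp2)
            stats.append(min(u12, 9 - u12))
        observed = 0
        expected = np.mean([s <= observed for s in stats])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_p_one(self):
        u, p = mannwhitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)


class TestSubgroups:
    def make_profiles(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        edss = pd.Series(rng.choice(np.arange(2, 16) / 2, n))
        profiles = pd.DataFrame({
            "worse_with_edss": edss + rng.normal(0, 0.5, n),
            "unrelated": rng.normal(size=n),
        })
        return profiles, edss

    def test_boundary_membership(self):
        profiles, _ = self.make_profiles(6)
        edss = pd.Series([4.0, 4.0, 4.0, 4.5, 4.5, 4.5])
        res = compare_edss_subgroups(profiles, edss)
        assert (res.n_low == 3).all() and (res.n_high == 3).all()

    def test_zscores_relative_to_whole_cohort(self):
        profiles, edss = self.make_profiles()
        res = compare_edss_subgroups(profiles, edss)
        row = res[res.parameter == "worse_with_edss"].iloc[0]
        n_low, n_high = row.n_low, row.n_high
        # weighted mean of subgroup mean-z equals 0 (whole-cohort centering)
        total = row.mean_z_low * n_low + row.mean_z_high * n_high
        assert total == pytest.approx(0.0, abs=1e-9)
        assert row.mean_z_high > row.mean_z_low

    def test_empty_subgroup_raises_with_cutoff(self):
        profiles, _ = self.make_profiles(4)
        edss = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="4"):
            compare_edss_subgroups(profiles, edss)


class TestNullCalibration:
    def test_bh_false_discovery_proportion_controlled(self):
        """No planted effects: mean FDP across replicate families stays
        within alpha + 2 Monte-Carlo SEs (reduced replicate count; the
        acceptance suite runs the full calibration)."""
        rng = np.random.default_rng(0)
        fdps = []
        for _ in range(200):
            p = rng.uniform(0, 1, 20)
            rej = bh_adjust(p) < 0.05
            fdps.append(rej.sum() / max(rej.sum(), 1) if rej.any() else 0.0)
        mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= 0.05 + 2 * mc_se + 0.02
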