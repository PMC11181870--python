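"""Differential screen: rank-sum p-values, fold changes, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nephropep.screen import (
    method_agreement_regression,
    spearman_slope_correlation,
    wilcoxon_screen,
)


def enumerate_rank_sum_p(u_vals, c_vals):
    """Brute-force two-sided rank-sum p: enumerate every assignment of the
    pooled (tie-free) values to the two groups and count statistics at least
    as extreme as observed (the U null is symmetric, so the symmetric-tail
    count equals the doubled one-sided tail)."""
    pooled = np.concatenate([u_vals, c_vals])
    n1 = len(u_vals)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * (len(pooled) - n1)
    obs_dev = abs(u_obs - n1n2 / 2)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - n1n2 / 2) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def _two_group(u_matrix, c_matrix):
    u_matrix = np.atleast_2d(np.asarray(u_matrix, float))
    c_matrix = np.atleast_2d(np.asarray(c_matrix, float))
    if u_matrix.shape[0] == 1:
        u_matrix, c_matrix = u_matrix.T, c_matrix.T
    n_u, n_c = u_matrix.shape[0], c_matrix.shape[0]
    samples = [f"U{i}" for i in range(n_u)] + [f"C{i}" for i in range(n_c)]
    mat = pd.DataFrame(
        np.vstack([u_matrix, c_matrix]),
        index=samples,
        columns=[f"p{j}" for j in range(u_matrix.shape[1])],
    )
    labels = pd.Series(["UNCONTROLLED"] * n_u + ["CONTROLLED"] * n_c, index=samples)
    return mat, labels


class TestWilcoxonScreen:
    def test_identical_groups_no_signal(self):
        mat, labels = _two_group([[1], [2], [3]], [[1], [2], [3]])
        out = wilcoxon_screen(mat, labels)
        assert out.loc["p0", "fold_change"] == pytest.approx(1.0)
        assert out.loc["p0", "p_value"] >= 0.99

    def test_extreme_separation_exact_p(self):
        # {1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 assignments, both tails
        mat, labels = _two_group([[1], [2], [3]], [[4], [5], [6]])
        out = wilcoxon_screen(mat, labels)
        assert out.loc["p0", "p_value"] == pytest.approx(0.1, abs=1e-12)
        assert out.loc["p0", "direction"] == "DOWN"

    def test_fold_change_from_raw_means(self):
        mat, labels = _two_group([[10], [10]], [[5], [5]])
        out = wilcoxon_screen(mat, labels)
        assert out.loc["p0", "fold_change"] == pytest.approx(2.0)
        assert out.loc["p0", "direction"] == "UP"

    def test_zero_controlled_mean_flagged_not_dropped(self):
        mat, labels = _two_group([[4], [5], [6]], [[0], [0], [0]])
        out = wilcoxon_screen(mat, labels)
        assert bool(out.loc["p0", "fold_undefined"])
        assert math.isnan(out.loc["p0", "fold_change"])
        assert out.loc["p0", "direction"] == "UP"

    def test_exact_p_matches_enumeration_on_random_pairs(self):
        """Implementation's exact rank-sum p equals full enumeration for 20
        random tie-free group pairs with combined size <= 10."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            u = rng.normal(size=n1)
            c = rng.normal(size=n2)
            mat, labels = _two_group(u[:, None], c[:, None])
            out = wilcoxon_screen(mat, labels)
            assert out.loc["p0", "p_value"] == pytest.approx(
                enumerate_rank_sum_p(u, c), abs=1e-12
            )

    def test_qvalues_are_metadata_bh(self):
        rng = np.random.default_rng(0)
        mat, labels = _two_group(rng.normal(5, 1, (6, 10)), rng.normal(5, 1, (6, 10)))
        out = wilcoxon_screen(mat, labels)
        assert np.all(out["q_value"] >= out["p_value"] - 1e-12)

    def test_small_groups_rejected(self):
        mat = pd.DataFrame({"p0": [1.0, 2.0, 3.0]}, index=["U0", "C0", "C1"])
        labels = pd.Series(["UNCONTROLLED", "CONTROLLED", "CONTROLLED"], index=mat.index)
        with pytest.raises(ValueError):
            wilcoxon_screen(mat, labels)


class TestSpearmanSlopeCorrelation:
    def test_perfect_monotone(self):
        slopes = pd.Series([-12.0, -8.0, -3.0, 0.0, 2.0], index=list("abcde"))
        mat = pd.DataFrame(
            {"up": slopes.values, "down": -slopes.values}, index=slopes.index
        )
        out = spearman_slope_correlation(mat, slopes)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_tied_values_use_average_ranks(self):
        slopes = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        x = np.array([10.0, 10.0, 30.0, 40.0, 50.0])  # one tie
        mat = pd.DataFrame({"pep": x}, index=slopes.index)
        out = spearman_slope_correlation(mat, slopes)
        # hand computation with average ranks: rx = (1.5 1.5 3 4 5)
        rx = np.array([1.5, 1.5, 3, 4, 5])
        ry = np.array([1, 2, 3, 4, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.loc["pep", "rho"] == pytest.approx(expected, rel=1e-12)

    def test_constant_peptide_recorded_missing(self):
        slopes = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        mat = pd.DataFrame({"pep": [7.0, 7.0, 7.0]}, index=slopes.index)
        out = spearman_slope_correlation(mat, slopes)
        assert math.isnan(out.loc["pep", "rho"])

    def test_too_few_finite_slopes_rejected(self):
        slopes = pd.Series([1.0, math.nan, math.nan], index=list("abc"))
        mat = pd.DataFrame({"pep": [1.0, 2.0, 3.0]}, index=slopes.index)
        with pytest.raises(ValueError):
            spearman_slope_correlation(mat, slopes)


class TestMethodAgreement:
    def _corr(self, rho, p):
        idx = [f"p{i}" for i in range(len(rho))]
        return pd.DataFrame({"rho": rho, "rho_p": p}, index=idx)

    def test_identical_profiles_r2_one(self):
        rng = np.random.default_rng(2)
        rho = rng.uniform(-0.9, 0.9, 50)
        a = self._corr(rho, np.full(50, 0.01))
        assert method_agreement_regression(a, a) == pytest.approx(1.0)

    def test_scaled_profile_with_noise_matches_analytic_r2(self):
        rng = np.random.default_rng(8)
        n = 4000
        rho_a = rng.uniform(-0.8, 0.8, n)
        noise = rng.normal(0, 0.1, n)
        rho_b = 0.8 * rho_a + noise
        a = self._corr(rho_a, np.full(n, 0.01))
        b = self._corr(rho_b, np.full(n, 0.01))
        var_a = np.var(rho_a)
        expected = (0.8**2 * var_a) / (0.8**2 * var_a + 0.01)
        assert method_agreement_regression(a, b) == pytest.approx(expected, rel=0.05)

    def test_permuted_null_near_zero(self):
        rng = np.random.default_rng(9)
        rho = rng.uniform(-0.8, 0.8, 200)
        a = self._corr(rho, np.full(200, 0.01))
        b = self._corr(rng.permutation(rho), np.full(200, 0.01))
        assert method_agreement_regression(a, b) < 0.1

    def test_too_few_after_cut_rejected(self):
        a = self._corr([0.5, 0.4, 0.3], [0.5, 0.5, 0.01])
        with pytest.raises(ValueError):
            method_agreement_regression(a, a)
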