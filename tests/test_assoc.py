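from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import gammaln

from tamspatial.assoc import (
    fisher_exact_rxc,
    holm_adjust,
    kruskal_wallis,
    spearman_ci,
    wilcoxon_ranksum,
)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_ci(x, x**3).estimate == pytest.approx(1.0)
        assert spearman_ci(x, -x - 2).estimate == pytest.approx(-1.0)

    def test_ci_width_matches_transform_formula(self):
        rng = np.random.default_rng(0)
        n = 443
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = spearman_ci(x, y)
        z = np.arctanh(res.estimate)
        se = 1 / np.sqrt(n - 3)
        assert res.ci_low == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-12)
        assert res.ci_high == pytest.approx(np.tanh(z + 1.959963984540054 * se), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1..6 split into two groups of 3: H = 27/7
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(27 / 7)

    def test_all_values_equal_convention(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_null_p_values_near_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(400):
            v = rng.normal(size=24)
            g = np.repeat(["a", "b", "c"], 8)
            ps.append(kruskal_wallis(v, g).p_raw)
        rej = np.mean(np.array(ps) < 0.05)
        assert rej <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)


def brute_force_fisher(table):
    """Exhaustive lattice enumeration oracle for small r x c tables."""
    tab = np.asarray(table)
    rm, cm, n = tab.sum(1), tab.sum(0), tab.sum()

    def log_prob(t):
        return float(gammaln(rm + 1).sum() + gammaln(cm + 1).sum() - gammaln(n + 1) - gammaln(np.asarray(t) + 1).sum())

    obs = log_prob(tab)
    total = 0.0
    r, c = tab.shape
    ranges = [range(min(rm[i], cm[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for combo in product(*ranges):
        t = np.zeros((r, c), dtype=int)
        it = iter(combo)
        for i in range(r - 1):
            for j in range(c - 1):
                t[i, j] = next(it)
        t[:-1, -1] = rm[:-1] - t[:-1, :-1].sum(1)
        t[-1, :] = cm - t[:-1, :].sum(0)
        if (t >= 0).all():
            lp = log_prob(t)
            if lp <= obs + 1e-9:
                total += np.exp(lp)
    return min(1.0, total)


class TestFisherExact:
    def test_2x2_enumeration_value(self):
        assert fisher_exact_rxc([[2, 0], [0, 2]]).p_raw == pytest.approx(1 / 3)

    def test_balanced_2x2(self):
        assert fisher_exact_rxc([[1, 1], [1, 1]]).p_raw == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = fisher_exact_rxc([[0, 0], [3, 2]])
        assert res.p_raw == 1.0 and res.extra.get("degenerate")

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1, 2], [0, 4, 1]],
            [[2, 2, 0], [1, 0, 3]],
            [[5, 1], [2, 2], [0, 4]],
        ],
    )
    def test_rxc_matches_brute_force_oracle(self, table):
        res = fisher_exact_rxc(table)
        assert not res.extra["simulated"]
        assert res.p_raw == pytest.approx(brute_force_fisher(table), abs=1e-10)

    def test_monte_carlo_close_to_enumeration(self):
        table = [[3, 1, 2], [0, 4, 1]]
        exact = brute_force_fisher(table)
        res = fisher_exact_rxc(table, max_enumeration=1, n_mc=20000, seed=5)
        assert res.extra["simulated"]
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert res.p_raw == pytest.approx(exact, abs=3 * se + 1e-4)


class TestWilcoxon:
    def test_identical_samples_central(self):
        res = wilcoxon_ranksum([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.p_raw > 0.5

    def test_fully_separated_exact_p(self):
        res = wilcoxon_ranksum([1.0, 2, 3], [10.0, 11, 12])
        assert res.p_raw == pytest.approx(0.1)

    def test_agreement_with_permutation_oracle_under_ties(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(1, 7, 35).astype(float)
        res = wilcoxon_ranksum(a, b)
        # permutation distribution of the tie-corrected statistic
        pooled = np.concatenate([a, b])
        obs = res.statistic
        count = 0
        reps = 3000
        mu = a.size * b.size / 2
        for _ in range(reps):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(perm[: a.size], perm[a.size :], alternative="two-sided").statistic
            if abs(u - mu) >= abs(obs - mu) - 1e-9:
                count += 1
        p_perm = count / reps
        assert res.p_raw == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / reps) + 0.01)


class TestHolm:
    @pytest.mark.parametrize(
        "p_in,p_out",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.03, 0.02, 0.01], [0.04, 0.04, 0.03]),
            ([0.2], [0.2]),
        ],
    )
    def test_worked_examples(self, p_in, p_out):
        np.testing.assert_allclose(holm_adjust(p_in), p_out, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_bounded(self, ps):
        adj = holm_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()

    @given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=6), st.integers(0, 5), st.floats(1.0, 2.0))
    def test_monotone_in_raw_p(self, ps, idx, factor):
        idx = idx % len(ps)
        bumped = list(ps)
        bumped[idx] = min(1.0, bumped[idx] * factor)
        a0, a1 = holm_adjust(ps), holm_adjust(bumped)
        assert (a1 >= a0 - 1e-12).all()
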