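import numpy as np
import pytest

from tamspatial.cutpoints import (
    NoSplit,
    bootstrap_cutpoint,
    combined_marker,
    dichotomize,
    logrank_scan,
    tree_cutpoint,
)


class TestLogrankScan:
    def test_matches_lifelines_on_random_splits(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(4)
        x = rng.integers(0, 10, 70).astype(float)
        t = np.round(rng.exponential(10, 70), 1)
        e = rng.random(70) < 0.6
        uniq = np.unique(x)
        mids = (uniq[:-1] + uniq[1:]) / 2
        chi2, u = logrank_scan(x, t, e, mids)
        for j in range(len(mids)):
            g = x > mids[j]
            ref = logrank_test(t[g], t[~g], e[g], e[~g]).test_statistic
            assert chi2[j] == pytest.approx(ref, abs=1e-8)

    def test_direction_sign(self):
        # high group has all the early events -> positive excess
        x = np.array([0.0, 0, 0, 1, 1, 1])
        t = np.array([10.0, 11, 12, 1, 2, 3])
        e = np.array([False, False, False, True, True, True])
        _, u = logrank_scan(x, t, e, np.array([0.5]))
        assert u[0] > 0


class TestTreeCutpoint:
    def test_exhaustive_logrank_selects_gap_midpoint(self, survival_toy):
        cp = tree_cutpoint(survival_toy["metric"], survival_toy["time"], survival_toy["event"], min_leaf=1, folds=0)
        assert cp.cutoff == 52.0 and cp.direction == "high"
        # oracle: evaluate every candidate split by two-sample log-rank
        from lifelines.statistics import logrank_test

        x, t, e = survival_toy["metric"], survival_toy["time"], survival_toy["event"]
        uniq = np.unique(x)
        mids = (uniq[:-1] + uniq[1:]) / 2
        stats = [logrank_test(t[x > m], t[x <= m], e[x > m], e[x <= m]).test_statistic for m in mids]
        assert mids[int(np.argmax(stats))] == 52.0

    def test_constant_metric_no_split(self):
        with pytest.raises(NoSplit):
            tree_cutpoint(np.ones(40), np.arange(1.0, 41), np.ones(40, bool))

    def test_duplicate_values_collapse_candidates(self):
        x = np.array([1.0, 1, 1, 2, 2, 2])
        t = np.array([10.0, 11, 12, 1, 2, 3])
        e = np.ones(6, bool)
        cp = tree_cutpoint(x, t, e, min_leaf=1, folds=0)
        assert cp.cutoff == 1.5  # only one unique midpoint

    def test_null_prunes_in_majority_of_runs(self):
        rng = np.random.default_rng(77)
        no_split = 0
        reps = 120
        for r in range(reps):
            n = 150
            x = rng.integers(0, 40, n).astype(float)
            t = rng.exponential(20, n)
            c = rng.uniform(5, 50, n)
            time, ev = np.minimum(t, c), t <= c
            try:
                tree_cutpoint(x, time, ev, seed=int(rng.integers(2**31)))
            except NoSplit:
                no_split += 1
        assert no_split > reps / 2

    def test_monotone_transform_maps_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 30, 200).astype(float)
        t = rng.exponential(20, 200) / np.exp(0.8 * (x > 14))
        e = np.ones(200, bool)
        cp1 = tree_cutpoint(x, t, e, folds=0)
        cp2 = tree_cutpoint(np.exp(x / 10), t, e, folds=0)
        # same induced partition: counts above threshold agree
        assert (x > cp1.cutoff).sum() == (np.exp(x / 10) > cp2.cutoff).sum()
        assert cp1.direction == cp2.direction


class TestBootstrapCutpoint:
    def test_recovers_strong_threshold(self, effect_cohort):
        patients, truth = effect_cohort
        res = bootstrap_cutpoint(
            patients["tam_count"].to_numpy(float),
            patients["pfs_months"].to_numpy(float),
            patients["progressed"].to_numpy(bool),
            B=60,
            seed=0,
        )
        lo, hi = res.ci90
        assert lo <= res.cutoff <= hi
        assert res.direction == "high"
        x = patients["tam_count"].to_numpy(float)
        assert x.min() < res.cutoff < x.max()
        # true threshold lies inside the bootstrap interval for this strong effect
        assert lo <= truth["true_cutpoint"] <= hi

    def test_b1_degenerates_to_single_resample(self, effect_cohort):
        patients, _ = effect_cohort
        res = bootstrap_cutpoint(
            patients["tam_count"].to_numpy(float),
            patients["pfs_months"].to_numpy(float),
            patients["progressed"].to_numpy(bool),
            B=1,
            seed=3,
        )
        assert res.bootstrap_cutoffs.size + res.n_failed == 1

    def test_seed_stream_extension(self, effect_cohort):
        """Doubling B with the same seed extends, not reshuffles, the stream."""
        patients, _ = effect_cohort
        args = (
            patients["tam_count"].to_numpy(float),
            patients["pfs_months"].to_numpy(float),
            patients["progressed"].to_numpy(bool),
        )
        r1 = bootstrap_cutpoint(*args, B=20, seed=9)
        r2 = bootstrap_cutpoint(*args, B=40, seed=9)
        np.testing.assert_array_equal(r1.bootstrap_cutoffs, r2.bootstrap_cutoffs[: r1.bootstrap_cutoffs.size])
        assert abs(np.median(r2.bootstrap_cutoffs) - np.median(r1.bootstrap_cutoffs)) <= 5.0

    def test_all_failures_raise(self):
        rng = np.random.default_rng(0)
        x = np.ones(50)
        with pytest.raises(NoSplit):
            bootstrap_cutpoint(x, rng.exponential(10, 50), np.ones(50, bool), B=5, seed=1)


class TestDichotomize:
    def test_strict_threshold(self):
        np.testing.assert_array_equal(dichotomize([60.0, 80.0], 70.0), [0, 1])
        np.testing.assert_array_equal(dichotomize([70.0], 70.0), [0])

    def test_direction_inversion_swaps(self):
        v = [60.0, 80.0]
        np.testing.assert_array_equal(dichotomize(v, 70.0, "low"), 1 - dichotomize(v, 70.0, "high"))

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dichotomize([1.0], np.inf)


class TestCombinedMarker:
    @pytest.mark.parametrize(
        "comm_high,nnd_low,expected",
        [(0, 0, 1), (0, 1, 2), (1, 0, 3), (1, 1, 3)],
    )
    def test_three_categories(self, comm_high, nnd_low, expected):
        assert combined_marker([comm_high], [nnd_low])[0] == expected

    def test_missing_propagates(self):
        out = combined_marker([np.nan, 0.0], [0.0, np.nan])
        assert np.isnan(out[0]) and np.isnan(out[1])
        # high communicating count determines category 3 regardless of NND
        assert combined_marker([1.0], [np.nan])[0] == 3
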