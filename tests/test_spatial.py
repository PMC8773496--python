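import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from tamspatial.core import CoreTable, Window
from tamspatial.spatial import (
    MarkedPointPattern,
    build_mmpp,
    compute_metric_suite,
    mean_count_within,
    metric_suite_from_arrays,
    nnd_set,
    summarize_nnd,
)


def _pattern(cancer, tams, neg=()):
    pts = np.array(list(cancer) + list(tams) + list(neg), float).reshape(-1, 2)
    marks = np.array(["cancer"] * len(cancer) + ["tam"] * len(tams) + ["stromal-"] * len(neg))
    return MarkedPointPattern(pts, marks, Window(0, 0, 600))


def _labelled_core(cancer, tams, neg=()):
    n = len(cancer) + len(tams) + len(neg)
    pts = np.array(list(cancer) + list(tams) + list(neg), float).reshape(-1, 2)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n).astype(str),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "compartment": ["cancer"] * len(cancer) + ["stromal"] * (len(tams) + len(neg)),
            "cd163": np.ones(n),
        }
    )
    core = CoreTable("c", "p", cells, Window(0, 0, 600))
    core.cells["tam"] = pd.array([False] * len(cancer) + [True] * len(tams) + [False] * len(neg), dtype="boolean")
    return core


class TestBuildMmpp:
    def test_mark_counts_match_labels(self):
        core = _labelled_core([(0, 0)] * 5, [(1, 1)] * 3, [(2, 2)] * 2)
        pat = build_mmpp(core)
        assert pat.mark_counts == {"cancer": 5, "tam": 3, "stromal-": 2}

    def test_zero_tams_valid(self):
        core = _labelled_core([(0, 0)], [], [(1, 1)])
        assert build_mmpp(core).mark_counts["tam"] == 0

    def test_unlabeled_stromal_raises(self):
        core = _labelled_core([(0, 0)], [(1, 1)])
        core.cells["tam"] = pd.array([pd.NA] * 2, dtype="boolean")
        with pytest.raises(RuntimeError, match="phenotyping"):
            build_mmpp(core)


class TestNndSet:
    def test_pythagoras(self):
        d = nnd_set(_pattern([(0, 0), (10, 0)], [(3, 4)]))
        assert d == pytest.approx([5.0, np.sqrt(65)])

    def test_coincident_distance_zero(self):
        d = nnd_set(_pattern([(0, 0)], [(0, 0)]))
        assert d[0] == 0.0

    def test_no_tams_gives_infinite_sentinel(self):
        d = nnd_set(_pattern([(0, 0), (1, 1)], []))
        assert np.isinf(d).all()

    def test_brute_force_oracle_random_patterns(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            nc, nt = rng.integers(1, 60), rng.integers(1, 60)
            cancer = rng.uniform(-250, 250, (nc, 2))
            tams = rng.uniform(-250, 250, (nt, 2))
            got = nnd_set(_pattern(cancer, tams))
            expected = cdist(cancer, tams).min(axis=1)
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestSummarizeNnd:
    def test_median_of_four(self):
        assert summarize_nnd(np.array([0.0, 10, 20, 30]))[2] == 15.0

    def test_p25_linear_interpolation(self):
        # h = (n-1)q = 0.75 -> 0 + 0.75*10
        assert summarize_nnd(np.array([0.0, 10, 20, 30]))[1] == 7.5

    def test_zero_tam_convention_truncates_all(self):
        p10, p25, p50 = summarize_nnd(np.full(7, np.inf))
        assert (p10, p25, p50) == (600.0, 600.0, 600.0)

    def test_caps_individual_distances(self):
        p10, p25, p50 = summarize_nnd(np.array([100.0, 700.0, 900.0]), truncation=600)
        assert p50 == 600.0 and p10 < 600

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_nnd(np.array([]))


class TestMeanCountWithin:
    def test_strict_radius_examples(self):
        pat = _pattern([(0, 0)], [(5, 0), (20, 0)])
        assert mean_count_within(pat, 12) == 1.0
        assert mean_count_within(pat, 250) == 2.0

    def test_boundary_tie_excluded(self):
        pat = _pattern([(0, 0)], [(12, 0)])
        assert mean_count_within(pat, 12.0) == 0.0

    def test_shared_tams_mean(self):
        pat = _pattern([(0, 0), (1, 0)], [(2, 0), (3, 0), (4, 0)])
        assert mean_count_within(pat, 250) == 3.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            mean_count_within(_pattern([(0, 0)], [(1, 1)]), 0)

    def test_brute_force_disc_count_oracle(self):
        rng = np.random.default_rng(5)
        for radius in (12.0, 250.0):
            for _ in range(15):
                cancer = rng.uniform(-280, 280, (rng.integers(1, 80), 2))
                tams = rng.uniform(-280, 280, (rng.integers(1, 80), 2))
                got = mean_count_within(_pattern(cancer, tams), radius)
                expected = (cdist(cancer, tams) < radius).sum(axis=1).mean()
                assert got == pytest.approx(expected, abs=1e-9)


class TestMetricSuite:
    def test_proportion_and_ordering_invariants(self):
        rng = np.random.default_rng(21)
        cancer = rng.uniform(-200, 200, (40, 2))
        tams = rng.uniform(-200, 200, (5, 2))
        neg = rng.uniform(-200, 200, (45, 2))
        ms = compute_metric_suite(_labelled_core(cancer, tams, neg))
        assert ms.tam_count == 5
        assert ms.tam_proportion == pytest.approx(5 / 50)
        assert ms.nnd_p10 <= ms.nnd_p25 <= ms.nnd_p50 <= 600
        assert 0 <= ms.adj_mean <= ms.comm_mean <= ms.tam_count

    def test_zero_tam_conventions(self):
        ms = compute_metric_suite(_labelled_core([(0, 0), (5, 5)], [], [(1, 1)]))
        assert ms.tam_count == 0 and ms.tam_proportion == 0
        assert (ms.nnd_p10, ms.nnd_p25, ms.nnd_p50) == (600.0, 600.0, 600.0)
        assert ms.adj_mean == 0 and ms.comm_mean == 0

    @pytest.mark.parametrize("angle", [0.7, 2.1])
    def test_isometry_invariance(self, angle):
        rng = np.random.default_rng(8)
        cancer = rng.uniform(-150, 150, (30, 2))
        tams = rng.uniform(-150, 150, (6, 2))
        base = metric_suite_from_arrays(cancer, tams, 20)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shifted = metric_suite_from_arrays(cancer @ R.T + 40.0, tams @ R.T + 40.0, 20)
        for k, v in base.as_dict().items():
            assert getattr(shifted, k) == pytest.approx(v, abs=1e-9), k
        reflected = metric_suite_from_arrays(cancer * [-1, 1], tams * [-1, 1], 20)
        for k, v in base.as_dict().items():
            assert getattr(reflected, k) == pytest.approx(v, abs=1e-9), k

    def test_adding_a_tam_never_increases_nnd(self):
        rng = np.random.default_rng(13)
        cancer = rng.uniform(-100, 100, (25, 2))
        tams = rng.uniform(-100, 100, (4, 2))
        d_before = nnd_set(_pattern(cancer, tams))
        d_after = nnd_set(_pattern(cancer, np.vstack([tams, [[0.0, 0.0]]])))
        assert (d_after <= d_before + 1e-12).all()
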