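"""Clustering, genome-weighted smoothing, probe t statistics, and
region calling, each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_probe_set
from meklchip.tdmr_calling import (
    call_regions,
    cluster_probes,
    pooled_ttest,
    probe_ttest,
    rank_regions,
    smooth_m,
)
from meklchip.types import MethylationMatrix, TDMR


def make_matrix(starts, values, tissues=("a", "a", "b", "b"), chrom="chr1"):
    """MethylationMatrix from a positions vector and probes x samples array."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    probes = make_probe_set(starts, chrom=chrom).table
    sample_ids = [f"s{i}" for i in range(k)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": list(tissues)[:k],
            "input_ng": 250,
            "replicate": list(range(1, k + 1)),
        }
    )
    vals = pd.DataFrame(values, index=probes["probe_id"].to_numpy(),
                        columns=sample_ids)
    return MethylationMatrix(values=vals, probes=probes, samples=samples)


class TestClusterProbes:
    def test_gap_rule(self):
        ps = make_probe_set([0, 35, 70, 1000])
        np.testing.assert_array_equal(cluster_probes(ps, 300), [0, 0, 0, 1])

    def test_singleton(self):
        ps = make_probe_set([100])
        np.testing.assert_array_equal(cluster_probes(ps), [0])

    def test_never_spans_chromosomes(self):
        ps = make_probe_set([0, 35, 0, 35], chrom=["c1", "c1", "c2", "c2"])
        np.testing.assert_array_equal(cluster_probes(ps, 300), [0, 0, 1, 1])


class TestSmoothM:
    def test_constant_within_cluster_unchanged(self):
        m = make_matrix([0, 35, 70], np.full((3, 4), 2.5))
        out = smooth_m(m, np.zeros(3, int), 300)
        np.testing.assert_allclose(out.values.to_numpy(), 2.5)

    def test_singleton_cluster_unchanged(self):
        m = make_matrix([0, 1000], [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])
        out = smooth_m(m, np.array([0, 1]), 300)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_kernel_matches_brute_force_oracle(self):
        """5 equally spaced probes, spike at the center: compare to an
        explicit kernel-sum loop."""
        starts = [0, 100, 200, 300, 400]
        values = np.array([[0.0], [0.0], [1.0], [0.0], [0.0]])
        values = np.repeat(values, 2, axis=1)
        m = make_matrix(starts, values, tissues=("a", "b"))
        window = 300
        out = smooth_m(m, np.zeros(5, int), window)

        def oracle(i):
            num = den = 0.0
            for j in range(5):
                d = abs(starts[i] - starts[j])
                if d <= window:
                    w = 1.0 - d / window
                    num += w * values[j, 0]
                    den += w
            return num / den

        for i in range(5):
            assert out.values.iloc[i, 0] == pytest.approx(oracle(i), abs=1e-12)

    def test_does_not_cross_cluster_boundary(self):
        starts = [0, 100, 200]
        values = np.array([[0.0], [0.0], [9.0]]).repeat(2, axis=1)
        m = make_matrix(starts, values, tissues=("a", "b"))
        out = smooth_m(m, np.array([0, 0, 1]), 300)
        # probe 2 is its own cluster: untouched; probes 0/1 unaffected by it
        assert out.values.iloc[2, 0] == 9.0
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[1, 0] == 0.0

    def test_smoothing_reduces_mean_probe_variance(self):
        """Average across probes of the across-sample variance never grows."""
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = rng.integers(5, 40)
            starts = np.sort(rng.choice(20_000, size=n, replace=False))
            x = rng.normal(size=(n, 6))
            m = make_matrix(starts, x, tissues=("a",) * 3 + ("b",) * 3)
            ps = make_probe_set(starts)
            clusters = cluster_probes(ps, 300)
            out = smooth_m(m, clusters, 300)
            v_before = x.var(axis=1, ddof=1).mean()
            v_after = out.values.to_numpy().var(axis=1, ddof=1).mean()
            assert v_after <= v_before + 1e-12


class TestProbeTtest:
    def test_identical_groups_null(self):
        x = np.array([[1.0, 2.0, 1.0, 2.0]])
        m = make_matrix([0], x)
        out = probe_ttest(m, ["s0", "s1"], ["s2", "s3"])
        assert out["t_stat"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0

    def test_matches_textbook_formula(self):
        """Pooled-variance t recomputed from first principles to 1e-10."""
        g1 = np.array([1.0, 1.1, 0.9])
        g2 = np.array([0.0, -0.1, 0.1])
        m = make_matrix([0], np.concatenate([g1, g2])[None, :],
                        tissues=("a", "a", "a", "b", "b", "b"))
        out = probe_ttest(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # independent oracle
        n1 = n2 = 3
        sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (
            n1 + n2 - 2
        )
        t_expect = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        from scipy import stats as sps

        p_expect = 2 * sps.t.sf(abs(t_expect), n1 + n2 - 2)
        assert out["t_stat"].iloc[0] == pytest.approx(t_expect, abs=1e-10)
        assert out["p_value"].iloc[0] == pytest.approx(p_expect, abs=1e-10)

    def test_sign_of_t_equals_sign_of_delta_m(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(50, 6))
        m = make_matrix(np.arange(50) * 35, x, tissues=("a",) * 3 + ("b",) * 3)
        out = probe_ttest(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        nz = out["t_stat"] != 0
        assert (
            np.sign(out.loc[nz, "t_stat"]) == np.sign(out.loc[nz, "delta_m"])
        ).all()

    def test_zero_variance_nonzero_difference_flagged(self):
        x = np.array([[1.0, 1.0, 0.0, 0.0]])
        m = make_matrix([0], x)
        out = probe_ttest(m, ["s0", "s1"], ["s2", "s3"])
        assert out["zero_var_flag"].iloc[0]
        assert 0 < out["p_value"].iloc[0] < 1e-300

    def test_single_sample_group_rejected(self):
        x = np.ones((1, 3))
        m = make_matrix([0], x, tissues=("a", "b", "b"))
        with pytest.raises(ValueError, match="at least 2"):
            pooled_ttest(x[:, :1], x[:, 1:])


def brute_force_regions(p, t, p_cutoff, min_probes):
    """Enumerate every [i, j) window; keep maximal qualifying runs."""
    n = len(p)
    qualifying = []
    for i in range(n):
        for j in range(i + min_probes, n + 1):
            window = range(i, j)
            if all(p[k] < p_cutoff and t[k] != 0 for k in window) and (
                len({np.sign(t[k]) for k in window}) == 1
            ):
                qualifying.append((i, j))
    # maximality: drop windows contained in a larger qualifying window
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if not any(
            (a <= i and j <= b) and (a, b) != (i, j) for (a, b) in qualifying
        )
    ]
    return sorted(maximal)


def stats_frame(p, t, starts=None):
    n = len(p)
    starts = list(range(0, n * 35, 35)) if starts is None else starts
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:04d}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "length": 50,
            "delta_m": np.sign(t) * 1.0,
            "t_stat": t,
            "p_value": p,
        }
    )


class TestCallRegions:
    def test_single_run_of_five(self):
        p = np.full(5, 0.001)
        t = np.full(5, 7.0)
        regions = call_regions(stats_frame(p, t), np.zeros(5, int))
        assert len(regions) == 1
        assert regions[0].n_probes == 5
        assert regions[0].start == 0 and regions[0].end == 4 * 35 + 50

    def test_two_probe_run_excluded(self):
        p = np.array([0.001, 0.001, 0.9])
        t = np.array([7.0, 7.0, 0.1])
        assert call_regions(stats_frame(p, t), np.zeros(3, int)) == []

    def test_sign_change_splits_runs(self):
        p = np.full(6, 0.001)
        t = np.array([7.0, 7.0, 7.0, -7.0, -7.0, -7.0])
        regions = call_regions(stats_frame(p, t), np.zeros(6, int))
        assert len(regions) == 2
        assert sorted(r.direction for r in regions) == [-1, 1]
        assert all(r.n_probes == 3 for r in regions)

    def test_direction_coherence_and_delta_m(self):
        p = np.full(4, 0.001)
        t = np.array([-5.0, -6.0, -7.0, -5.5])
        regions = call_regions(stats_frame(p, t), np.zeros(4, int))
        r = regions[0]
        assert r.direction == -1
        assert np.sign(r.delta_m) == -1
        assert r.area == pytest.approx(23.5)

    def test_matches_exhaustive_enumeration(self):
        """All significance/sign patterns on clusters up to 8 probes equal
        the brute-force maximal-run enumeration."""
        p_cutoff, min_probes = 0.005, 3
        for n in range(1, 9):
            for pattern in itertools.product((0, 1, -1), repeat=n):
                t = np.array([7.0 * s for s in pattern])
                p = np.where(t != 0, 0.001, 0.5)
                regions = call_regions(
                    stats_frame(p, t), np.zeros(n, int), p_cutoff, min_probes
                )
                got = sorted(
                    (
                        int(r.probe_ids[0][1:]),
                        int(r.probe_ids[-1][1:]) + 1,
                    )
                    for r in regions
                )
                assert got == brute_force_regions(p, t, p_cutoff, min_probes), (
                    f"pattern {pattern}"
                )

    def test_runs_never_cross_clusters(self):
        p = np.full(6, 0.001)
        t = np.full(6, 7.0)
        clusters = np.array([0, 0, 0, 1, 1, 1])
        regions = call_regions(stats_frame(p, t), clusters)
        assert len(regions) == 2

    def test_region_p_from_region_means(self):
        """Region p equals a pooled t test on per-sample region means."""
        rng = np.random.default_rng(9)
        x = 0.2 * rng.normal(size=(5, 6)) + np.array([3.0] * 3 + [0.0] * 3)
        m = make_matrix(np.arange(5) * 35, x, tissues=("a",) * 3 + ("b",) * 3)
        stats = probe_ttest(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        regions = call_regions(
            stats, np.zeros(5, int), p_cutoff=0.05, min_probes=3,
            matrix=m, group1=["s0", "s1", "s2"], group2=["s3", "s4", "s5"],
        )
        assert len(regions) == 1
        means = x.mean(axis=0)
        _, p_expect, _ = pooled_ttest(means[None, :3], means[None, 3:])
        assert regions[0].region_p == pytest.approx(float(p_expect[0]), rel=1e-12)


class TestRankRegions:
    def _region(self, p, area, start=0):
        return TDMR(
            chrom="chr1", start=start, end=start + 100,
            probe_ids=("x",), direction=1, delta_m=1.0,
            area=area, region_p=p, cluster_id=0,
        )

    def test_p_value_ordering(self):
        out = rank_regions([self._region(1e-5, 1.0), self._region(1e-20, 1.0, 500)])
        assert out[0].region_p == 1e-20 and out[0].rank == 1
        assert out[1].rank == 2

    def test_area_breaks_ties(self):
        out = rank_regions(
            [self._region(1e-5, 12.0), self._region(1e-5, 40.0, 500)]
        )
        assert out[0].area == 40.0

    def test_empty(self):
        assert rank_regions([]) == []
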