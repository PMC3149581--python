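"""Collection, grouping, representatives, chromatogram extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from amdorap import (
    PointSet,
    collect_data_points,
    extract_chromatogram,
    extract_chromatograms,
    group_by_mz,
    representative_mz,
    sweep_closeness,
    variance_explained,
)
from conftest import make_run


def points_from_mz(mz_values, sample="s") -> PointSet:
    mz = np.asarray(mz_values, dtype=float)
    n = mz.size
    return PointSet(
        np.full(n, sample, dtype=object),
        np.zeros(n, dtype=np.int64),
        np.zeros(n),
        mz,
        np.ones(n),
    )


def brute_force_groups(mz_values, closeness_ppm):
    """Independent oracle: connected components of the pairwise ppm graph.

    An edge joins two m/z values whose relative difference (denominator =
    the lower value) is within tolerance; on sorted data the resulting
    components coincide with single-linkage chaining over adjacent gaps.
    """
    mz = np.sort(np.asarray(mz_values, dtype=float))
    n = mz.size
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (mz[j] - mz[i]) / mz[i] * 1e6 <= closeness_ppm:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return n_comp, labels


# ---------------------------------------------------------------------------
# collection
# ---------------------------------------------------------------------------


class TestCollectDataPoints:
    def test_full_fraction_returns_every_point(self):
        run = make_run("a", [(0.0, [100.0, 200.0], [5.0, 7.0]), (1.0, [150.0], [3.0])])
        pts = collect_data_points([run], top_fraction=1.0)
        assert len(pts) == 3

    def test_top_fraction_matches_full_sort_oracle(self):
        rng = np.random.default_rng(42)
        intensities = rng.permutation(np.arange(1.0, 1001.0))  # 1000 distinct values
        mz = np.sort(rng.uniform(70, 1500, size=1000))
        run = make_run("a", [(0.0, list(mz), list(intensities))])
        pts = collect_data_points([run], top_fraction=0.01)
        expected = set(np.sort(intensities)[-10:])  # brute force: full sort, top 10
        assert len(pts) == 10
        assert set(pts.intensity) == expected

    def test_thresholding_is_per_sample_not_pooled(self):
        rng = np.random.default_rng(0)
        bright = make_run(
            "bright", [(0.0, list(np.sort(rng.uniform(70, 1500, 200))), list(rng.uniform(1e4, 1e5, 200)))]
        )
        dim = make_run(
            "dim", [(0.0, list(np.sort(rng.uniform(70, 1500, 200))), list(rng.uniform(1e2, 1e3, 200)))]
        )
        pts = collect_data_points([bright, dim], top_fraction=0.01)
        assert (pts.sample_id == "bright").sum() == 2
        assert (pts.sample_id == "dim").sum() == 2

    def test_intensity_scaling_of_one_sample_keeps_its_selection(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(70, 1500, 300))
        inten = rng.uniform(1, 1e6, 300)
        base = make_run("s", [(0.0, list(mz), list(inten))])
        scaled = make_run("s", [(0.0, list(mz), list(inten * 37.5))])
        sel_base = collect_data_points([base], 0.05)
        sel_scaled = collect_data_points([scaled], 0.05)
        assert np.array_equal(np.sort(sel_base.mz), np.sort(sel_scaled.mz))

    def test_threshold_ties_are_all_retained(self):
        run = make_run("a", [(0.0, [100.0, 200.0, 300.0, 400.0], [1.0, 9.0, 9.0, 9.0])])
        pts = collect_data_points([run], top_fraction=0.25)  # k = 1, but 3-way tie
        assert len(pts) == 3
        assert set(pts.intensity) == {9.0}

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        run = make_run("a", [(0.0, [100.0], [1.0])])
        with pytest.raises(ValueError):
            collect_data_points([run], top_fraction=bad)

    def test_empty_run_rejected(self):
        run = make_run("a", [])
        with pytest.raises(ValueError):
            collect_data_points([run], top_fraction=0.5)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


class TestGroupByMz:
    @pytest.mark.parametrize(
        "mz, ppm, expected_groups",
        [
            # gaps 4.0 and 11.0 ppm at 5 ppm closeness -> split after 2nd
            ([100.0000, 100.0004, 100.0015], 5.0, [[100.0000, 100.0004], [100.0015]]),
            # chain of 4 ppm gaps, 12 ppm total span: one group, no span limit
            ([100.0000, 100.0004, 100.0008, 100.0012], 5.0, [[100.0000, 100.0004, 100.0008, 100.0012]]),
            ([523.4], 5.0, [[523.4]]),
        ],
    )
    def test_known_groupings(self, mz, ppm, expected_groups):
        groups = group_by_mz(points_from_mz(mz), ppm)
        got = [list(g.members.mz) for g in groups]
        assert got == expected_groups

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        mz = rng.uniform(70, 1500, 500)
        pts = points_from_mz(mz)
        groups = group_by_mz(pts, 5.0)
        assert sum(g.n_points for g in groups) == len(pts)
        pooled = np.sort(np.concatenate([g.members.mz for g in groups]))
        assert np.array_equal(pooled, np.sort(mz))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        mz=st.lists(st.floats(70.0, 1500.0), min_size=1, max_size=200),
        ppm=st.floats(0.5, 50.0),
    )
    def test_matches_bruteforce_connected_components(self, mz, ppm):
        groups = group_by_mz(points_from_mz(mz), ppm)
        n_comp, _ = brute_force_groups(mz, ppm)
        assert len(groups) == n_comp

    def test_result_independent_of_input_order(self):
        rng = np.random.default_rng(9)
        mz = rng.uniform(100, 110, 80)
        a = group_by_mz(points_from_mz(mz), 5.0)
        b = group_by_mz(points_from_mz(rng.permutation(mz)), 5.0)
        assert [list(g.members.mz) for g in a] == [list(g.members.mz) for g in b]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_by_mz(points_from_mz([]), 5.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            group_by_mz(points_from_mz([100.0]), 0.0)


class TestRepresentativeMz:
    def test_odd_count_median(self):
        g = group_by_mz(points_from_mz([106.0495, 106.0496, 106.0497]), 50.0)[0]
        assert representative_mz(g) == pytest.approx(106.0496, abs=1e-10)

    def test_even_count_mean_of_central_pair(self):
        g = group_by_mz(points_from_mz([100.0000, 100.0002]), 50.0)[0]
        assert representative_mz(g) == pytest.approx(100.0001, abs=1e-10)

    def test_invariant_under_sample_relabeling(self):
        mz = [100.0000, 100.0001, 100.0003]
        a = PointSet(
            np.array(["x", "y", "x"], dtype=object),
            np.zeros(3, dtype=np.int64),
            np.zeros(3),
            np.array(mz),
            np.ones(3),
        )
        b = PointSet(
            np.array(["y", "x", "y"], dtype=object),
            np.zeros(3, dtype=np.int64),
            np.zeros(3),
            np.array(mz),
            np.ones(3),
        )
        ga = group_by_mz(a, 50.0)[0]
        gb = group_by_mz(b, 50.0)[0]
        assert representative_mz(ga) == representative_mz(gb)

    def test_representative_lies_within_member_span(self):
        rng = np.random.default_rng(2)
        mz = 300.0 * (1 + rng.normal(0, 1e-6, 41))
        g = group_by_mz(points_from_mz(mz), 1e4)[0]
        lo, hi = g.mz_span
        assert lo <= representative_mz(g) <= hi


# ---------------------------------------------------------------------------
# chromatogram extraction
# ---------------------------------------------------------------------------


class TestExtractChromatogram:
    def test_empty_window_gives_full_length_zero_trace(self):
        run = make_run("a", [(0.0, [100.0], [5.0]), (1.0, [100.0], [5.0]), (2.0, [100.0], [5.0])])
        chrom = extract_chromatogram(run, 500.0, 5.0)
        assert chrom.intensity.shape == (3,)
        assert np.all(chrom.intensity == 0.0)
        assert np.array_equal(chrom.rt, [0.0, 1.0, 2.0])

    def test_multiple_in_window_peaks_are_summed(self):
        center = 200.0
        inside = [center * (1 - 2e-6), center * (1 + 2e-6)]
        run = make_run("a", [(0.0, inside, [3.0, 4.0])])
        chrom = extract_chromatogram(run, center, 5.0)
        assert chrom.intensity[0] == pytest.approx(7.0)

    def test_window_ends_are_inclusive(self):
        center = 400.0
        lo = center * (1 - 5e-6)
        hi = center * (1 + 5e-6)
        run = make_run("a", [(0.0, [lo, hi], [1.0, 2.0])])
        chrom = extract_chromatogram(run, center, 5.0)
        assert chrom.intensity[0] == pytest.approx(3.0)

    def test_conserves_injected_compound_signal(self, noise_free_run):
        run, truth = noise_free_run
        t = truth.iloc[0]
        chrom = extract_chromatogram(run, t.true_mz, 5.0)
        assert chrom.eic_sum == pytest.approx(t.total_ion_count, rel=1e-12)

    def test_disjoint_tiling_conserves_per_scan_totals(self, small_run):
        run, _ = small_run
        # boundaries offset so no centroid sits exactly on an edge
        edges = np.linspace(69.9371, 1500.0137, 24)
        total = np.zeros(run.n_scans)
        for lo, hi in zip(edges[:-1], edges[1:]):
            center = (lo + hi) / 2
            tol_ppm = (hi - center) / center * 1e6
            total += extract_chromatogram(run, center, tol_ppm).intensity
        assert np.allclose(total, run.total_ion_counts(), rtol=1e-12)

    def test_batch_extraction_matches_single(self, small_run):
        run, truth = small_run
        centers = list(truth.true_mz)
        batch = extract_chromatograms(run, centers, 5.0)
        for center, chrom in zip(centers, batch):
            single = extract_chromatogram(run, center, 5.0)
            assert np.array_equal(chrom.intensity, single.intensity)


# ---------------------------------------------------------------------------
# variance explained / closeness sweep
# ---------------------------------------------------------------------------


class TestVarianceExplained:
    def test_whole_data_fraction_is_100(self):
        assert variance_explained(np.array([1.0, 5.0, 9.0]), 1.0) == pytest.approx(100.0)

    def test_hand_computed_example(self):
        # {10,1,1,1,1}, top 20% = {10}: mu=2.8, (10-2.8)^2=51.84 of 64.8 total
        x = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        assert variance_explained(x, 0.2) == pytest.approx(80.0)

    def test_matches_bruteforce_on_random_vector(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(10.0, 500)
        frac = 0.03
        k = math.ceil(frac * x.size)
        mu = x.mean()
        expected = 100 * ((np.sort(x)[::-1][:k] - mu) ** 2).sum() / (((x - mu) ** 2).sum())
        assert variance_explained(x, frac) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_returns_100_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert variance_explained(np.full(10, 3.3), 0.5) == 100.0

    def test_noise_dominated_simulated_run_concentrates_variance(self, small_run):
        run, _ = small_run
        share = variance_explained(run.point_arrays()[1], 0.01)
        assert share > 95.0


class TestSweepCloseness:
    def test_known_counts_across_tolerances(self):
        pts = points_from_mz([100.0000, 100.0004, 100.0015])
        counts = sweep_closeness(pts, [3.0, 5.0, 12.0])
        assert list(counts) == [3, 2, 1]

    def test_counts_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(12)
        pts = points_from_mz(rng.uniform(70, 1500, 400))
        counts = sweep_closeness(pts, list(range(1, 21)))
        assert np.all(np.diff(counts) <= 0)

    def test_single_point_always_one_group(self):
        counts = sweep_closeness(points_from_mz([250.0]), [1.0, 5.0, 20.0])
        assert list(counts) == [1, 1, 1]

    def test_descending_tolerances_rejected(self):
        with pytest.raises(ValueError):
            sweep_closeness(points_from_mz([100.0]), [5.0, 3.0])
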