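"""The profiling algorithm proper: collect, group, represent, extract.

Peak picking and cross-sample alignment happen in a single grouping step:
the highest-intensity data points of every sample are pooled into one
spectrum-like point set, the pooled m/z values are clustered by ppm
closeness (single linkage on adjacent gaps), and each cluster's median m/z
becomes the feature's representative value. Ion chromatograms are then
extracted per sample inside a ±ppm window around each representative. No
retention-time alignment is performed anywhere: with ppm-stable mass
accuracy the m/z values themselves are the cross-sample coordinates.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .model import CentroidRun, Chromatogram, MzGroup, PointSet

__all__ = [
    "collect_data_points",
    "group_by_mz",
    "representative_mz",
    "extract_chromatogram",
    "extract_chromatograms",
    "variance_explained",
    "sweep_closeness",
]


def collect_data_points(
    runs: Sequence[CentroidRun], top_fraction: float = 0.01
) -> PointSet:
    """Pool each sample's top-intensity data points across all runs.

    For each run independently, the ``ceil(top_fraction * N)`` points of
    highest intensity are retained (N = the run's total MS1 point count);
    the per-sample threshold is the intensity of the k-th largest point and
    ties at the threshold are all kept, so the result is deterministic and
    independent of input order. Thresholding per sample (never pooled)
    means a globally dimmer sample still contributes its own top fraction.

    Parameters
    ----------
    runs : sequence of CentroidRun
        One entry per sample; each must contain at least one data point.
    top_fraction : float in (0, 1]
        Fraction of each sample's points to keep. 1.0 keeps everything.

    Returns
    -------
    PointSet
        Concatenation over samples, each point tagged with its sample_id.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if len(runs) == 0:
        raise ValueError("at least one run is required")
    parts: list[PointSet] = []
    for run in runs:
        n = run.n_points
        if n == 0:
            raise ValueError(f"run {run.sample_id!r} contains no data points")
        mz, inten, scan_idx, rt = run.point_arrays()
        k = math.ceil(top_fraction * n)
        # intensity of the k-th largest point; >= keeps ties at the threshold
        threshold = np.partition(inten, n - k)[n - k]
        mask = inten >= threshold
        parts.append(
            PointSet(
                np.full(int(mask.sum()), run.sample_id, dtype=object),
                scan_idx[mask],
                rt[mask],
                mz[mask],
                inten[mask],
            )
        )
    return PointSet.concatenate(parts)


def group_by_mz(points: PointSet, closeness_ppm: float = 5.0) -> list[MzGroup]:
    """Cluster pooled m/z values by single-linkage ppm closeness.

    All pooled m/z values are sorted ascending and a new group starts
    wherever the gap to the previous value, ``(mz[i] - mz[i-1]) / mz[i-1]
    * 1e6``, exceeds ``closeness_ppm``. Chaining is deliberate: a group's
    total span may exceed the tolerance and there is no upper bound on the
    number of points in one group. The groups partition the input.
    """
    if closeness_ppm <= 0:
        raise ValueError(f"closeness_ppm must be positive, got {closeness_ppm}")
    if len(points) == 0:
        raise ValueError("cannot group an empty point set")
    order = np.argsort(points.mz, kind="stable")
    sorted_points = points.take(order)
    mz = sorted_points.mz
    # relative gap to the LOWER of each adjacent pair, in ppm
    gaps_ppm = np.diff(mz) / mz[:-1] * 1e6
    breaks = np.flatnonzero(gaps_ppm > closeness_ppm) + 1
    bounds = np.concatenate(([0], breaks, [len(points)]))
    return [
        MzGroup(sorted_points[int(a) : int(b)]) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def representative_mz(group: MzGroup) -> float:
    """Median m/z of a group's members pooled across all samples.

    For an even member count this is the arithmetic mean of the two central
    values. The statistic ignores sample labels entirely.
    """
    return float(np.median(group.members.mz))


def extract_chromatogram(
    run: CentroidRun, mz_center: float, tol_ppm: float = 5.0
) -> Chromatogram:
    """Extract one ±ppm ion chromatogram from a run.

    For every MS1 scan the trace holds the sum of all centroid peaks whose
    m/z lies inside ``[mz_center*(1 - tol_ppm*1e-6), mz_center*(1 +
    tol_ppm*1e-6)]`` (both ends inclusive); scans with no in-window peak
    contribute zero. The trace is on the sample's own scan grid — no
    retention-time alignment across samples.
    """
    return extract_chromatograms(run, [mz_center], tol_ppm)[0]


def extract_chromatograms(
    run: CentroidRun, mz_centers: Sequence[float], tol_ppm: float = 5.0
) -> list[Chromatogram]:
    """Batch form of :func:`extract_chromatogram` (one m/z-sorted search
    structure shared across all windows)."""
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    mz_sorted, inten_sorted, scan_sorted = run.mz_sorted_arrays()
    rt = run.rt_grid
    n_scans = run.n_scans
    out: list[Chromatogram] = []
    for center in mz_centers:
        half = tol_ppm * 1e-6 * center
        lo, hi = center - half, center + half
        i0 = np.searchsorted(mz_sorted, lo, side="left")
        i1 = np.searchsorted(mz_sorted, hi, side="right")
        if i1 > i0:
            trace = np.bincount(
                scan_sorted[i0:i1], weights=inten_sorted[i0:i1], minlength=n_scans
            ).astype(float)
        else:
            trace = np.zeros(n_scans)
        out.append(
            Chromatogram(
                sample_id=run.sample_id,
                mz_center=float(center),
                tol_ppm=float(tol_ppm),
                rt=rt,
                intensity=trace,
            )
        )
    return out


def variance_explained(intensities: np.ndarray, fraction: float) -> float:
    """Percent of total intensity variance carried by the top fraction.

    With μ the mean of ALL intensities, returns ``100 * Σ_top (x-μ)² /
    Σ_all (x-μ)²`` where the top set is the ``ceil(fraction*N)`` largest
    intensities. A constant vector has zero total variance; by convention
    the whole of nothing is everything, so 100 is returned with a warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("intensity vector is empty")
    mu = x.mean()
    dev2 = (x - mu) ** 2
    total = dev2.sum()
    if total == 0.0:
        warnings.warn(
            "constant intensity vector: zero total variance, returning 100 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 100.0
    k = math.ceil(fraction * x.size)
    top_idx = np.argpartition(x, x.size - k)[x.size - k :]
    return float(100.0 * dev2[top_idx].sum() / total)


def sweep_closeness(points: PointSet, ppm_values: Sequence[float]) -> np.ndarray:
    """Number of m/z groups at each closeness tolerance.

    ``ppm_values`` must be positive and ascending; the returned counts are
    monotonically non-increasing because single-linkage groups can only
    merge as the tolerance grows.
    """
    ppm = np.asarray(ppm_values, dtype=float)
    if ppm.size == 0 or np.any(ppm <= 0):
        raise ValueError("ppm_values must be positive")
    if np.any(np.diff(ppm) < 0):
        raise ValueError("ppm_values must be ascending")
    return np.array([len(group_by_mz(points, p)) for p in ppm], dtype=np.int64)
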