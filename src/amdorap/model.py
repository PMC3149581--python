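"""In-memory containers for centroid LC-MS data and derived objects.

A run is a retention-time-ordered sequence of centroid MS1 scans; every
downstream object (pooled data points, m/z groups, extracted ion
chromatograms) keeps its values in parallel numpy arrays so that the
pipeline stays vectorised even for runs with ~10^6 data points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Scan",
    "CentroidRun",
    "DataPoint",
    "PointSet",
    "MzGroup",
    "Chromatogram",
]


@dataclass(frozen=True)
class Scan:
    """One centroid MS1 scan: (m/z, intensity) points at a retention time.

    Parameters
    ----------
    scan_index : int
        Zero-based position of the scan within its run.
    rt : float
        Retention time in minutes.
    mz : ndarray
        Centroid m/z values (Thomson), sorted ascending.
    intensity : ndarray
        Ion counts, same length as ``mz``, all strictly positive.
    ms_level : int
        MS level; only level-1 scans participate in profiling.
    """

    scan_index: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size:
            if np.any(np.diff(mz) < 0):
                raise ValueError(f"scan {self.scan_index}: m/z not sorted ascending")
            if np.any(mz <= 0):
                raise ValueError(f"scan {self.scan_index}: non-positive m/z")
            if np.any(intensity <= 0):
                raise ValueError(f"scan {self.scan_index}: non-positive intensity")

    @property
    def n_points(self) -> int:
        return int(self.mz.size)

    @property
    def total_ion_count(self) -> float:
        return float(self.intensity.sum())


class CentroidRun:
    """One sample's centroid MS1 data, scans strictly ordered by rt."""

    def __init__(self, sample_id: str, scans: Sequence[Scan]):
        scans = [s for s in scans if s.ms_level == 1]
        rts = np.array([s.rt for s in scans], dtype=float)
        if rts.size > 1 and np.any(np.diff(rts) <= 0):
            raise ValueError(
                f"run {sample_id!r}: retention times must be strictly increasing"
            )
        self.sample_id = str(sample_id)
        self.scans: list[Scan] = list(scans)
        self._flat: tuple[np.ndarray, ...] | None = None
        self._mz_sorted: tuple[np.ndarray, ...] | None = None

    # -- basic geometry ---------------------------------------------------
    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def n_points(self) -> int:
        return sum(s.n_points for s in self.scans)

    @property
    def rt_grid(self) -> np.ndarray:
        """Retention times (minutes) of all MS1 scans."""
        return np.array([s.rt for s in self.scans], dtype=float)

    def total_ion_counts(self) -> np.ndarray:
        """Per-scan summed intensity over the full m/z range."""
        return np.array([s.total_ion_count for s in self.scans], dtype=float)

    # -- flattened views (cached) -----------------------------------------
    def point_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """All points in scan order as (mz, intensity, scan_index, rt)."""
        if self._flat is None:
            if self.n_scans == 0:
                empty = np.empty(0)
                self._flat = (empty, empty.copy(), np.empty(0, dtype=np.int64), empty.copy())
            else:
                mz = np.concatenate([s.mz for s in self.scans])
                inten = np.concatenate([s.intensity for s in self.scans])
                scan_idx = np.concatenate(
                    [np.full(s.n_points, i, dtype=np.int64) for i, s in enumerate(self.scans)]
                )
                rt = np.concatenate(
                    [np.full(s.n_points, s.rt, dtype=float) for s in self.scans]
                )
                self._flat = (mz, inten, scan_idx, rt)
        return self._flat

    def mz_sorted_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All points sorted by m/z, as (mz, intensity, scan_index).

        Cached; this is the search structure behind chromatogram extraction.
        """
        if self._mz_sorted is None:
            mz, inten, scan_idx, _ = self.point_arrays()
            order = np.argsort(mz, kind="stable")
            self._mz_sorted = (mz[order], inten[order], scan_idx[order])
        return self._mz_sorted

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CentroidRun(sample_id={self.sample_id!r}, n_scans={self.n_scans}, "
            f"n_points={self.n_points})"
        )


@dataclass(frozen=True)
class DataPoint:
    """A single ion observation pooled into the cross-sample point set."""

    sample_id: str
    scan_index: int
    rt: float
    mz: float
    intensity: float


class PointSet(Sequence):
    """Column-oriented sequence of :class:`DataPoint`.

    Behaves as a sequence of DataPoint for inspection while keeping the
    underlying values in numpy arrays for vectorised grouping.
    """

    def __init__(
        self,
        sample_id: np.ndarray,
        scan_index: np.ndarray,
        rt: np.ndarray,
        mz: np.ndarray,
        intensity: np.ndarray,
    ):
        self.sample_id = np.asarray(sample_id, dtype=object)
        self.scan_index = np.asarray(scan_index, dtype=np.int64)
        self.rt = np.asarray(rt, dtype=float)
        self.mz = np.asarray(mz, dtype=float)
        self.intensity = np.asarray(intensity, dtype=float)
        n = self.mz.size
        if not all(
            a.size == n for a in (self.sample_id, self.scan_index, self.rt, self.intensity)
        ):
            raise ValueError("PointSet columns must have equal length")

    @classmethod
    def from_points(cls, points: Sequence[DataPoint]) -> "PointSet":
        return cls(
            np.array([p.sample_id for p in points], dtype=object),
            np.array([p.scan_index for p in points], dtype=np.int64),
            np.array([p.rt for p in points], dtype=float),
            np.array([p.mz for p in points], dtype=float),
            np.array([p.intensity for p in points], dtype=float),
        )

    def __len__(self) -> int:
        return int(self.mz.size)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PointSet(
                self.sample_id[i], self.scan_index[i], self.rt[i], self.mz[i], self.intensity[i]
            )
        return DataPoint(
            sample_id=str(self.sample_id[i]),
            scan_index=int(self.scan_index[i]),
            rt=float(self.rt[i]),
            mz=float(self.mz[i]),
            intensity=float(self.intensity[i]),
        )

    def __iter__(self) -> Iterator[DataPoint]:
        for i in range(len(self)):
            yield self[i]

    def take(self, order: np.ndarray) -> "PointSet":
        return PointSet(
            self.sample_id[order],
            self.scan_index[order],
            self.rt[order],
            self.mz[order],
            self.intensity[order],
        )

    @staticmethod
    def concatenate(sets: Sequence["PointSet"]) -> "PointSet":
        return PointSet(
            np.concatenate([s.sample_id for s in sets]),
            np.concatenate([s.scan_index for s in sets]),
            np.concatenate([s.rt for s in sets]),
            np.concatenate([s.mz for s in sets]),
            np.concatenate([s.intensity for s in sets]),
        )


@dataclass
class MzGroup:
    """A ppm-closeness cluster of pooled data points.

    ``members`` are sorted by m/z; the representative m/z is the median of
    the member m/z values pooled across all samples.
    """

    members: PointSet

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("MzGroup requires at least one member")

    @property
    def n_points(self) -> int:
        return len(self.members)

    @property
    def representative_mz(self) -> float:
        return float(np.median(self.members.mz))

    @property
    def mz_span(self) -> tuple[float, float]:
        return float(self.members.mz[0]), float(self.members.mz[-1])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.mz_span
        return (
            f"MzGroup(representative_mz={self.representative_mz:.5f}, "
            f"n_points={self.n_points}, span=[{lo:.5f}, {hi:.5f}])"
        )


@dataclass
class Chromatogram:
    """Per-sample intensity trace for one ±ppm m/z window.

    One intensity per MS1 scan of the sample (zero where no centroid peak
    falls inside the window); the window is inclusive at both ends.
    """

    sample_id: str
    mz_center: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")

    @property
    def window(self) -> tuple[float, float]:
        half = self.tol_ppm * 1e-6 * self.mz_center
        return self.mz_center - half, self.mz_center + half

    @property
    def eic_sum(self) -> float:
        return float(self.intensity.sum())
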