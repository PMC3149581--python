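"""Shared fixtures: tiny synthetic runs and mzML construction helpers."""

from __future__ import annotations

import base64
import zlib
from dataclasses import replace

import numpy as np
import pytest

from amdorap import CentroidRun, Scan, default_scenario, simulate_run


def make_run(sample_id: str, scans: list[tuple[float, list[float], list[float]]]) -> CentroidRun:
    """Build a run from (rt, mz_list, intensity_list) triples."""
    return CentroidRun(
        sample_id,
        [
            Scan(scan_index=i, rt=rt, mz=np.array(mz), intensity=np.array(inten))
            for i, (rt, mz, inten) in enumerate(scans)
        ],
    )


def encode_array(values, compress: bool = True) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


@pytest.fixture
def small_run():
    """A 200-scan run with 5 well-separated compounds over a light noise floor."""
    scenario = replace(
        default_scenario(seed=11, n_compounds=5),
        n_scans=200,
        noise_points_per_scan=100,
    )
    run, truth = simulate_run(scenario, "small")
    return run, truth


@pytest.fixture
def noise_free_run():
    """One compound, no noise floor: every point belongs to the compound."""
    scenario = replace(
        default_scenario(seed=3, n_compounds=1),
        n_scans=300,
        noise_points_per_scan=0,
    )
    run, truth = simulate_run(scenario, "clean")
    return run, truth
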