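"""Reading mzML runs and compound tables; writing feature tables.

The mzML reader is a deliberately small lxml-based parser covering the
subset this pipeline consumes: MS1 centroid spectra with 32/64-bit float
binary arrays, zlib-compressed or raw. Only centroid data is accepted:
the point-pooling model is meaningless on profile data, so spectra
flagged as profile mode are a hard error rather than being silently
centroided. Retention times are normalized to minutes on read regardless
of the file's unit attribute.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

from . import masscalc
from .model import CentroidRun, Scan

__all__ = [
    "FormatError",
    "ProfileModeError",
    "CompoundRecord",
    "read_centroid_run",
    "load_compound_table",
    "write_feature_table",
    "read_feature_table",
    "MZ_DECIMALS",
    "PPM_DECIMALS",
]

# printed precision of m/z values and ppm errors in all text output
MZ_DECIMALS = 5
PPM_DECIMALS = 2


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


class ProfileModeError(FormatError):
    """A spectrum carries profile-mode metadata; centroid data is required."""


@dataclass(frozen=True)
class CompoundRecord:
    """A named compound with a validated molecular formula."""

    name: str
    formula: str

    @property
    def composition(self) -> dict[str, int]:
        return masscalc.parse_formula(self.formula)

    @property
    def neutral_mass(self) -> float:
        return masscalc.monoisotopic_mass(self.composition)

    def theoretical_adduct_mz(self, adduct: str = "[M+H]+") -> float:
        """Theoretical m/z of this compound under the named adduct."""
        return masscalc.adduct_mz(self.neutral_mass, adduct)


# cvParam accessions this reader understands
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, dict]:
    """accession -> {'value': ..., 'unitName': ...} for direct cvParam children."""
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value"),
                "unitName": child.get("unitName"),
            }
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params: dict[str, dict] = {}
    payload = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            params[child.get("accession")] = {"value": child.get("value")}
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = None
    if _ACC_MZ_ARRAY in params:
        kind = "mz"
    elif _ACC_INT_ARRAY in params:
        kind = "intensity"
    return kind, values


def _parse_spectrum(spectrum, path: Path):
    """Return (rt_minutes, mz, intensity) for an MS1 spectrum, or None."""
    sid = spectrum.get("id", "?")
    params = _cv_params(spectrum)
    ms_level = int(params.get(_ACC_MS_LEVEL, {}).get("value") or 1)
    if ms_level != 1:
        return None
    if _ACC_PROFILE in params:
        raise ProfileModeError(
            f"{path}: spectrum {sid!r} is profile mode; centroid data is required"
        )
    rt = None
    mz = np.empty(0)
    inten = np.empty(0)
    for child in spectrum.iter():
        name = _local(child.tag)
        if name == "cvParam" and child.get("accession") == _ACC_SCAN_START:
            rt = float(child.get("value"))
            unit = (child.get("unitName") or "minute").lower()
            if unit in ("second", "seconds", "s"):
                rt /= 60.0
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if rt is None:
        raise FormatError(f"{path}: spectrum {sid!r} has no scan start time")
    if mz.size != inten.size:
        raise FormatError(
            f"{path}: spectrum {sid!r} m/z and intensity arrays differ in length"
        )
    keep = inten > 0
    mz, inten = mz[keep], inten[keep]
    order = np.argsort(mz, kind="stable")
    return rt, mz[order], inten[order]


def read_centroid_run(path: str | Path, sample_id: str | None = None) -> CentroidRun:
    """Read one centroid-mode mzML run, keeping MS1 scans only.

    Scans come back ordered by retention time (minutes) with per-scan m/z
    arrays sorted ascending and zero-intensity centroids dropped. MS2 (and
    higher) spectra are filtered out without reordering the retained MS1
    scans.

    Raises
    ------
    FormatError
        If the file is missing or not well-formed mzML.
    ProfileModeError
        If any spectrum is flagged as profile mode, naming the scan.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file does not exist: {path}")
    scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    saw_mzml_root = False
    try:
        for event, element in etree.iterparse(str(path), events=("end",)):
            name = _local(element.tag)
            if name in ("mzML", "indexedmzML"):
                saw_mzml_root = True
            elif name == "spectrum":
                parsed = _parse_spectrum(element, path)
                if parsed is not None:
                    scans.append(parsed)
                element.clear()
    except ProfileModeError:
        raise
    except FormatError:
        raise
    except Exception as exc:  # XML syntax errors, bad base64, ...
        raise FormatError(f"{path}: not readable as mzML ({exc})") from exc
    if not saw_mzml_root:
        raise FormatError(f"{path}: not an mzML document")
    # stable sort: MS1 scans are already rt-ordered in well-formed files
    scans.sort(key=lambda t: t[0])
    run_scans = [
        Scan(scan_index=i, rt=rt, mz=mz, intensity=inten)
        for i, (rt, mz, inten) in enumerate(scans)
    ]
    return CentroidRun(sample_id or path.stem, run_scans)


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Load a delimited compound table with name and ``formula`` columns.

    The name column may be called ``name``, ``metabolite`` or ``compound``.

    The delimiter (tab or comma) is sniffed from the header line. Every
    formula is validated on load; an unparseable formula raises a
    :class:`FormatError` naming the offending row. An empty table yields
    an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"compound table does not exist: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    name_col = cols.get("name") or cols.get("metabolite") or cols.get("compound")
    if name_col is None or "formula" not in cols:
        raise FormatError(
            f"{path}: compound table needs a name (or metabolite) and a "
            f"formula column, found {list(df.columns)}"
        )
    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        name = str(row[name_col])
        formula = str(row[cols["formula"]])
        try:
            masscalc.parse_formula(formula)
        except masscalc.FormulaError as exc:
            raise FormatError(f"{path}: row {i + 1} ({name}): {exc}") from exc
        records.append(CompoundRecord(name=name, formula=formula))
    return records


def write_feature_table(features: Sequence, path: str | Path) -> None:
    """Write the feature table as UTF-8 TSV, one row per m/z group.

    Columns: representative m/z (printed to 5 decimals), member point
    count, then per sample (in sorted sample order) the EIC sum, the
    S/N-gated area, the peak-region count and the reliability flag, and
    finally the annotation string. Column order is deterministic so the
    same features always serialize byte-identically.

    ``features`` are objects with ``representative_mz``, ``n_points``,
    ``quant`` (mapping sample_id -> QuantResult) and ``annotation``
    attributes (see :class:`amdorap.pipeline.FeatureRecord`).
    """
    sample_ids = sorted({sid for f in features for sid in f.quant})
    columns = ["mz", "n_points"]
    for sid in sample_ids:
        columns += [
            f"eic_sum_{sid}",
            f"sn_area_{sid}",
            f"n_peaks_{sid}",
            f"reliable_{sid}",
        ]
    columns.append("annotation")
    rows = []
    for f in features:
        row: dict[str, object] = {
            "mz": f"{f.representative_mz:.{MZ_DECIMALS}f}",
            "n_points": f.n_points,
        }
        for sid in sample_ids:
            q = f.quant.get(sid)
            if q is None:
                row[f"eic_sum_{sid}"] = ""
                row[f"sn_area_{sid}"] = ""
                row[f"n_peaks_{sid}"] = ""
                row[f"reliable_{sid}"] = ""
            else:
                row[f"eic_sum_{sid}"] = repr(q.eic_sum)
                row[f"sn_area_{sid}"] = repr(q.sn_area)
                row[f"n_peaks_{sid}"] = q.n_peak_regions
                row[f"reliable_{sid}"] = str(bool(q.reliable))
        row["annotation"] = f.annotation or ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, sep="\t")
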