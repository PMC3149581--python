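"""Molecular formulas, monoisotopic masses, adduct m/z and ppm errors.

Atomic monoisotopic masses and adduct deltas ship as versioned TSV data
files inside the package so that every derived number is reproducible
independently of any library's internal tables. Adduct deltas are
charge-aware: [M+H]+ adds the proton mass 1.00727646 Da (hydrogen atom
minus one electron), so an observed ion m/z compares directly against
``neutral_mass + delta``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "Annotation",
    "annotate",
    "compare_tools",
    "atomic_masses",
    "adduct_table",
    "load_table1",
    "PROTON_MASS",
]

PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Raised for malformed molecular formulas or unknown element symbols."""


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("amdorap.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


_ATOMIC_MASSES: dict[str, float] | None = None
_ADDUCTS: dict[str, tuple[float, int]] | None = None


def atomic_masses() -> dict[str, float]:
    """Element symbol -> monoisotopic mass (Da), from the packaged table."""
    global _ATOMIC_MASSES
    if _ATOMIC_MASSES is None:
        df = _read_packaged_tsv("atomic_masses.tsv")
        _ATOMIC_MASSES = dict(zip(df["element"], df["monoisotopic_mass"].astype(float)))
    return _ATOMIC_MASSES


def adduct_table() -> dict[str, tuple[float, int]]:
    """Adduct name -> (mass delta in Da, charge), from the packaged table."""
    global _ADDUCTS
    if _ADDUCTS is None:
        df = _read_packaged_tsv("adducts.tsv")
        _ADDUCTS = {
            str(r.adduct): (float(r.mass_delta), int(r.charge))
            for r in df.itertuples(index=False)
        }
    return _ADDUCTS


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    A count of 1 is implicit ("C3H7NO3" -> {C: 3, H: 7, N: 1, O: 3});
    multi-digit counts are supported. Unknown element symbols and any
    leftover characters raise :class:`FormulaError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    masses = atomic_masses()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        element = m.group(1)
        if element not in masses:
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    if not counts:
        raise FormulaError(f"no elements found in formula {text!r}")
    return counts


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an element-count composition.

    The empty composition has mass 0. Additive: disjoint compositions sum.
    """
    masses = atomic_masses()
    total = 0.0
    for element, n in composition.items():
        if element not in masses:
            raise FormulaError(f"unknown element {element!r}")
        total += n * masses[element]
    return total


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of an ionised molecule for a named adduct.

    For the singly charged adducts packaged here this is ``neutral_mass +
    mass_delta``; in general ``(neutral_mass + delta * |z|) / |z|`` with the
    delta stored per charge.
    """
    table = adduct_table()
    if adduct not in table:
        raise KeyError(
            f"unknown adduct {adduct!r}; known: {', '.join(sorted(table))}"
        )
    delta, charge = table[adduct]
    z = abs(charge)
    return (neutral_mass + delta * z) / z


def formula_mz(formula: str, adduct: str = "[M+H]+") -> float:
    """Convenience: theoretical adduct m/z straight from a formula string."""
    return adduct_mz(monoisotopic_mass(parse_formula(formula)), adduct)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    ``(observed - theoretical) / theoretical * 1e6``; reported to two
    decimals in user-facing output.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Annotation:
    """A database hit for one query m/z: compound, adduct, signed ppm error."""

    query_mz: float
    name: str
    formula: str
    adduct: str
    theoretical_mz: float
    error_ppm: float


def annotate(
    mz_values: Sequence[float],
    compounds: Sequence,
    adducts: Sequence[str] = ("[M+H]+",),
    tol_ppm: float = 5.0,
) -> list[Annotation]:
    """Match query m/z values against a compound table within ±tol ppm.

    Every (query, compound, adduct) triple with ``|error_ppm| <= tol_ppm``
    is returned, sorted per query by absolute error: isobars (identical
    formulas, structural isomers, stereoisomers) all match and it is the
    caller's job not to over-interpret. An empty database yields an empty
    result.

    ``compounds`` may contain :class:`~amdorap.formats_io.CompoundRecord`
    objects or any object with ``name`` and ``formula`` attributes.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    theoretical = [
        (c, a, formula_mz(c.formula, a)) for c in compounds for a in adducts
    ]
    hits: list[Annotation] = []
    for q in mz_values:
        per_query = []
        for compound, adduct, theo in theoretical:
            err = ppm_error(q, theo)
            if abs(err) <= tol_ppm:
                per_query.append(
                    Annotation(
                        query_mz=float(q),
                        name=compound.name,
                        formula=compound.formula,
                        adduct=adduct,
                        theoretical_mz=theo,
                        error_ppm=err,
                    )
                )
        per_query.sort(key=lambda a: abs(a.error_ppm))
        hits.extend(per_query)
    return hits


def load_table1() -> pd.DataFrame:
    """The packaged 14-compound mass-accuracy reference table.

    Columns: metabolite, formula, theoretical_mz, then observed m/z and
    printed ppm error for each of the three tools (amdorap, mzmine2, xcms).
    """
    return _read_packaged_tsv("table1.tsv")


def compare_tools(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute per-tool ppm errors for the reference compounds.

    For every row the theoretical [M+H]+ m/z is rebuilt from the formula
    (full precision, not the printed 5-decimal value) and each tool's
    observed m/z is scored as a signed ppm error. A ``closest`` column
    names the tool with the strictly smallest absolute error; ties name no
    winner (empty string).

    Returns the augmented DataFrame; summary statistics (max absolute
    error and strict-win count per tool) are in ``df.attrs["max_abs_ppm"]``
    and ``df.attrs["wins"]``.
    """
    if table is None:
        table = load_table1()
    tools = ["amdorap", "mzmine2", "xcms"]
    df = table.copy()
    df["theoretical_exact"] = [formula_mz(f, "[M+H]+") for f in df["formula"]]
    for t in tools:
        df[f"{t}_ppm_calc"] = [
            ppm_error(obs, theo)
            for obs, theo in zip(df[f"{t}_mz"], df["theoretical_exact"])
        ]
    closest = []
    for _, row in df.iterrows():
        errs = {t: abs(row[f"{t}_ppm_calc"]) for t in tools}
        best = min(errs, key=errs.get)
        # strict win only: any tie for the minimum leaves the row unawarded
        if sum(1 for v in errs.values() if v == errs[best]) > 1:
            closest.append("")
        else:
            closest.append(best)
    df["closest"] = closest
    df.attrs["max_abs_ppm"] = {t: float(df[f"{t}_ppm_calc"].abs().max()) for t in tools}
    df.attrs["wins"] = {t: int((df["closest"] == t).sum()) for t in tools}
    return df
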