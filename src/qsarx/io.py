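"""CSV input/output and bundled reference tables.

Three plain-text reference tables ship with the package:

* ``high_efficiency_drugs.csv`` — descriptor values (pKa, frontier-orbital
  energies, tabulated omega and delta_n) and predicted IE% for the ten
  drugs in the published high-efficiency cohort.
* ``lidocaine_eis.csv`` — fitted equivalent-circuit parameters for
  lidocaine on API 5L steel in 3% NaCl at 0/10/20/50/100 ppm, with the
  published IE% column for comparison.
* ``lidocaine_polarization.csv`` — Tafel-analysis parameters for the same
  system (``bc`` stores the cathodic slope magnitude).

All CSV is UTF-8 with '.' decimal separators; ``#`` starts a comment line.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .descriptors import CompoundRecord
from .electrochem import EISRecord, PolarizationRecord

__all__ = [
    "COMPOUND_COLUMNS",
    "read_compound_table",
    "write_compound_table",
    "compound_records",
    "read_eis_table",
    "read_polarization_table",
    "eis_records",
    "polarization_records",
    "load_high_efficiency_table",
    "load_eis_table",
    "load_polarization_table",
]

#: Header of a full compound descriptor CSV; ``ie_obs`` may be empty and
#: ``omega``/``delta_n`` are optional extra columns.
COMPOUND_COLUMNS = [
    "name", "mw", "pka", "logp", "logs", "psa", "alpha", "e_homo", "e_lumo", "ie_obs",
]

EIS_COLUMNS = ["conc_ppm", "rs", "n_cpe", "cdl", "rct", "cf", "n2", "rmol", "rtotal"]
POLARIZATION_COLUMNS = ["conc_ppm", "ecorr", "icorr", "ba", "bc"]


class CSVFormatError(ValueError):
    """Malformed input CSV, with the offending file and detail."""


def _read_csv(path: Union[str, Path], required: List[str], optional: List[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise CSVFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing required column(s) {missing}; header was {list(frame.columns)}")
    for col in frame.columns:
        if col in ("name", *required, *optional) and col != "name":
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
            if bad.any():
                line = int(frame.index[bad][0]) + 2  # 1-based + header
                raise CSVFormatError(
                    f"{path}: non-numeric value {frame[col][bad].iloc[0]!r} in column {col!r} near line {line}"
                )
            frame[col] = coerced
    return frame


def read_compound_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a compound descriptor CSV (see :data:`COMPOUND_COLUMNS`)."""
    numeric = [c for c in COMPOUND_COLUMNS if c != "name"]
    frame = _read_csv(path, required=["name", *numeric[:-1]], optional=["ie_obs", "omega", "delta_n"])
    return frame


def write_compound_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a compound descriptor CSV with full float precision."""
    frame.to_csv(path, index=False)


def compound_records(frame: pd.DataFrame) -> List[CompoundRecord]:
    """Materialize a descriptor frame as validated CompoundRecord objects."""

    def opt(row, col):
        if col not in frame.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    return [
        CompoundRecord(
            name=str(row["name"]),
            mw=float(row["mw"]), pka=float(row["pka"]), logp=float(row["logp"]),
            logs=float(row["logs"]), psa=float(row["psa"]), alpha=float(row["alpha"]),
            e_homo=float(row["e_homo"]), e_lumo=float(row["e_lumo"]),
            ie_obs=opt(row, "ie_obs"), omega=opt(row, "omega"), delta_n=opt(row, "delta_n"),
        )
        for _, row in frame.iterrows()
    ]


def read_eis_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read an EIS circuit-parameter CSV (columns mirror the bundled table)."""
    return _read_csv(path, required=["conc_ppm", "rs", "n_cpe", "cdl", "rct"],
                     optional=["cf", "n2", "rmol", "rtotal", "ie_printed"])


def read_polarization_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a polarization-parameter CSV."""
    return _read_csv(path, required=POLARIZATION_COLUMNS, optional=["ie_printed"])


def eis_records(frame: pd.DataFrame) -> List[EISRecord]:
    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        EISRecord(
            conc=float(r["conc_ppm"]), rs=float(r["rs"]), n_cpe=float(r["n_cpe"]),
            cdl=float(r["cdl"]), rct=float(r["rct"]),
            cf=opt(r.get("cf", np.nan)), n2=opt(r.get("n2", np.nan)),
            rmol=opt(r.get("rmol", np.nan)), rtotal=opt(r.get("rtotal", np.nan)),
        )
        for _, r in frame.iterrows()
    ]


def polarization_records(frame: pd.DataFrame) -> List[PolarizationRecord]:
    return [
        PolarizationRecord(
            conc=float(r["conc_ppm"]), ecorr=float(r["ecorr"]), icorr=float(r["icorr"]),
            ba=float(r["ba"]), bc=float(r["bc"]),
        )
        for _, r in frame.iterrows()
    ]


def _data_path(filename: str) -> Path:
    return Path(str(importlib.resources.files("qsarx").joinpath("data", filename)))


def load_high_efficiency_table() -> pd.DataFrame:
    """The ten-drug high-efficiency reference table.

    Columns: name, pka, e_homo, e_lumo, omega (table-compatible scale),
    delta_n, ie_obs (the published predicted IE%).
    """
    return _read_csv(_data_path("high_efficiency_drugs.csv"),
                     required=["name", "pka", "e_homo", "e_lumo", "omega", "delta_n", "ie_obs"],
                     optional=[])


def load_eis_table() -> pd.DataFrame:
    """Lidocaine EIS circuit parameters (0 ppm row is the blank)."""
    return read_eis_table(_data_path("lidocaine_eis.csv"))


def load_polarization_table() -> pd.DataFrame:
    """Lidocaine polarization parameters (0 ppm row is the blank)."""
    return read_polarization_table(_data_path("lidocaine_polarization.csv"))
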