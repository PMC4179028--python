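"""Delimited-text readers and writers for spectra, chemistry and band tables.

Spectra files are CSV with a ``sample_id`` first column and one column per
wavenumber (header in cm⁻¹). Instruments commonly export the axis in
descending wavenumber order; files are normalized to the package's internal
ascending convention on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import ResidualRecord
from .synth import BandTable, ChemistryReference, SpectraSet, WavenumberGrid

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_chemistry",
    "write_chemistry",
    "read_bands",
    "write_bands",
    "residuals_to_frame",
    "write_residuals",
    "read_residuals",
]


def _check_unique_ids(ids: pd.Index, path: Path) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")


def read_spectra(path: "str | Path") -> SpectraSet:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    _check_unique_ids(df.index, path)
    try:
        wn = df.columns.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header ({exc})") from exc
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = [
            (str(df.index[i]), df.columns[j])
            for i, j in zip(*np.where(df.map(lambda x: not _is_number(x))))
        ][:5]
        raise ValueError(f"{path}: non-numeric absorbance cells at {bad}")
    if wn.size >= 2 and wn[0] > wn[-1]:  # instrument (descending) order
        wn = wn[::-1]
        vals = vals[:, ::-1]
    return SpectraSet(
        grid=WavenumberGrid(wn),
        absorbance=vals.astype(float),
        sample_ids=[str(i) for i in df.index],
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_spectra(spectra: SpectraSet, path: "str | Path") -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{w:.10g}" for w in spectra.grid.values],
    )
    df.to_csv(path, float_format="%.12g")


def read_chemistry(path: "str | Path") -> ChemistryReference:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    _check_unique_ids(df.index, path)
    for col in df.columns:
        bad = df[~df[col].map(_is_number)]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, "
                f"sample {bad.index[0]!r}"
            )
    df.index = df.index.map(str)
    # files hold measured values; assay error may nudge totals past 100
    return ChemistryReference(df.astype(float), measured=True)


def write_chemistry(chem: ChemistryReference, path: "str | Path") -> None:
    out = chem.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")


def read_bands(path: "str | Path") -> BandTable:
    return BandTable(pd.read_csv(path))


def write_bands(bands: BandTable, path: "str | Path") -> None:
    bands.entries.to_csv(path, index=False)


def residuals_to_frame(records: list[ResidualRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "constituent": [r.constituent for r in records],
            "method": [r.method for r in records],
            "pretreatment": [r.pretreatment for r in records],
            "ba_l_cm1": [r.ba_l_cm1 for r in records],
            "c_cm1": [r.c_cm1 for r in records],
            "r_cm1": [r.r_cm1 for r in records],
            "matched": [r.matched for r in records],
        }
    )


def write_residuals(records: "list[ResidualRecord] | pd.DataFrame", path: "str | Path") -> None:
    df = records if isinstance(records, pd.DataFrame) else residuals_to_frame(records)
    df.to_csv(path, index=False, float_format="%.12g")


def read_residuals(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)
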