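"""CSV reading and writing for spectra and reference tables.

Spectra files are wide-format CSV: first column is the sample ID, the
header row carries wavenumbers in cm^-1, cells are log(1/R) absorbance.
Instrument exports often list wavenumbers descending; files are re-sorted
to the package's ascending convention on read (with a log note).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import ParseError, ReferenceTable, SpectralDataset

logger = logging.getLogger(__name__)

_ID_COLUMN = "sample_id"
_REGION_COLUMN = "region"


def read_spectra_csv(path) -> SpectralDataset:
    """Load a wide-format spectra CSV, re-sorting descending grids ascending."""
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    regions = None
    if _REGION_COLUMN in df.columns:
        regions = df.pop(_REGION_COLUMN).astype(str).tolist()
    try:
        wavenumbers = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavenumber header: {exc}") from None
    matrix = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            matrix[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ParseError(
                f"{path}: non-numeric absorbance in column {col!r}, rows {bad}"
            ) from None
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample IDs: {dupes}")
    order = np.argsort(wavenumbers)
    if not np.array_equal(order, np.arange(wavenumbers.size)):
        logger.info("%s: wavenumber grid not ascending; re-sorting columns", path)
        wavenumbers = wavenumbers[order]
        matrix = matrix[:, order]
    return SpectralDataset(ids=ids, wavenumbers=wavenumbers, absorbance=matrix, regions=regions)


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    df = pd.DataFrame(
        dataset.absorbance,
        index=pd.Index(dataset.ids, name=_ID_COLUMN),
        columns=[repr(float(w)) for w in dataset.wavenumbers],
    )
    if dataset.regions is not None:
        df.insert(0, _REGION_COLUMN, dataset.regions)
    # default float repr is the shortest exact round-trip form
    df.to_csv(path)


def read_reference_csv(path) -> ReferenceTable:
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()].tolist()
            raise ParseError(f"{path}: non-numeric value in column {col!r}, rows {bad}")
    return ReferenceTable(df)


def write_reference_csv(table: ReferenceTable, path) -> None:
    df = table.values.copy()
    df.index.name = _ID_COLUMN
    df.to_csv(path)
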