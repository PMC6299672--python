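"""Core data containers shared by every pipeline stage.

Two objects travel through the whole assay: a :class:`SpectralDataset`
holding log(1/R) absorbance spectra on a common ascending wavenumber grid,
and a :class:`ReferenceTable` holding the per-sample wet-chemistry reference
values (five composition indicators in % dry matter, three digestibility
yields in % of theoretical) that serve as regression and scoring targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Chemical composition indicators, % dry matter.
COMPOSITION_INDICATORS: tuple[str, ...] = (
    "soluble_sugars",
    "cellulose",
    "hemicellulose",
    "lignin",
    "ash",
)

#: Sugar yields after alkali pretreatment + enzymatic hydrolysis, % of theoretical.
DIGESTIBILITY_YIELDS: tuple[str, ...] = (
    "hexoses",
    "pentoses",
    "total_carbohydrates",
)

REFERENCE_COLUMNS: tuple[str, ...] = COMPOSITION_INDICATORS + DIGESTIBILITY_YIELDS


class ConfigurationError(ValueError):
    """An invalid parameter value or combination of parameters."""


class ParseError(ValueError):
    """A malformed input file (ragged rows, duplicate IDs, bad cells)."""


@dataclass
class SpectralDataset:
    """Near-infrared spectra for a set of samples.

    Parameters
    ----------
    ids
        Unique sample identifiers, one per spectrum.
    wavenumbers
        Strictly ascending grid in cm^-1.
    absorbance
        log(1/R) matrix, shape ``(n_samples, n_wavenumbers)``.
    regions
        Optional per-sample provenance labels (e.g. growth region codes).
    """

    ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    regions: list[str] | None = None

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({s for s in self.ids if self.ids.count(s) > 1})
            raise ParseError(f"duplicate sample IDs: {dupes}")
        if self.absorbance.shape != (len(self.ids), self.wavenumbers.size):
            raise ConfigurationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.ids)} samples x {self.wavenumbers.size} wavenumbers"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ConfigurationError("wavenumber grid must be strictly ascending")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ConfigurationError("wavenumbers must be finite")
        if not np.all(np.isfinite(self.absorbance)):
            raise ConfigurationError("absorbance values must be finite")
        if self.regions is not None:
            self.regions = [str(r) for r in self.regions]
            if len(self.regions) != len(self.ids):
                raise ConfigurationError("regions length must match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_variables(self) -> int:
        return int(self.wavenumbers.size)

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectralDataset":
        """Copy of this dataset with a replaced absorbance matrix."""
        return SpectralDataset(
            ids=list(self.ids),
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            regions=list(self.regions) if self.regions is not None else None,
        )

    def take(self, sample_indices: np.ndarray | list[int]) -> "SpectralDataset":
        """Row subset by positional indices, preserving the given order."""
        idx = np.asarray(sample_indices, dtype=int)
        return SpectralDataset(
            ids=[self.ids[i] for i in idx],
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx],
            regions=[self.regions[i] for i in idx] if self.regions is not None else None,
        )

    def select_ids(self, ids: list[str]) -> "SpectralDataset":
        """Row subset by sample ID, in the order the IDs are given."""
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        return self.take([pos[s] for s in ids])

    def restrict(self, variable_indices: np.ndarray | list[int]) -> "SpectralDataset":
        """Column subset (wavenumber selection); indices re-sorted ascending."""
        idx = np.unique(np.asarray(variable_indices, dtype=int))
        if idx.size == 0:
            raise ConfigurationError("variable subset is empty")
        if idx[0] < 0 or idx[-1] >= self.n_variables:
            raise ConfigurationError("variable index out of range")
        return SpectralDataset(
            ids=list(self.ids),
            wavenumbers=self.wavenumbers[idx],
            absorbance=self.absorbance[:, idx],
            regions=list(self.regions) if self.regions is not None else None,
        )


@dataclass
class ReferenceTable:
    """Per-sample composition and digestibility reference values.

    Wraps a :class:`pandas.DataFrame` indexed by sample ID with the eight
    canonical columns of :data:`REFERENCE_COLUMNS`. Composition indicators
    are % dry matter in [0, 100); digestibility yields are % of theoretical
    in (0, 100].
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.index = df.index.map(str)
        missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"reference table missing columns: {missing}")
        df = df.loc[:, list(REFERENCE_COLUMNS)].astype(float)
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ParseError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(df.to_numpy())):
            raise ConfigurationError("reference values must be finite")
        comp = df.loc[:, list(COMPOSITION_INDICATORS)].to_numpy()
        if np.any(comp < 0) or np.any(comp >= 100):
            raise ConfigurationError("composition indicators must lie in [0, 100)")
        dig = df.loc[:, list(DIGESTIBILITY_YIELDS)].to_numpy()
        if np.any(dig <= 0) or np.any(dig > 100):
            raise ConfigurationError("digestibility yields must lie in (0, 100]")
        self.values = df

    @property
    def ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def response(self, name: str) -> np.ndarray:
        """One response column as a float vector, in table row order."""
        if name not in REFERENCE_COLUMNS:
            raise KeyError(f"unknown response {name!r}; choose from {REFERENCE_COLUMNS}")
        return self.values[name].to_numpy(dtype=float)

    def select_ids(self, ids: list[str]) -> "ReferenceTable":
        missing = [s for s in ids if s not in self.values.index]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        return ReferenceTable(self.values.loc[ids])
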