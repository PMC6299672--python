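"""Synthetic NIRS generator with known ground truth.

Emulates a population of lignocellulosic stem samples scanned by diffuse
reflectance over 4000-10,000 cm^-1: each chemical component contributes a
pure absorptivity spectrum (a sum of Gaussian bands concentrated in the
information-rich 4000-7500 cm^-1 window), spectra mix linearly in the
component concentrations (Beer-Lambert), a water component absorbs only
inside the 5150-5195 cm^-1 interference window with a per-sample amplitude
independent of every modeling target, and the instrument adds multiplicative
scatter, a linear additive baseline, and white noise. Digestibility yields
are coupled negatively to lignin and ash so the population has a recoverable
structure-quality relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datasets import (
    COMPOSITION_INDICATORS,
    ConfigurationError,
    ReferenceTable,
    SpectralDataset,
)
from .io import write_reference_csv, write_spectra_csv

import pandas as pd

WATER = "water"
#: Residual dry-matter component (extractives, protein, pectin, ...) closing
#: the composition to 100 % dry matter; absorbs like the others but is not a
#: modeling target.
MATRIX = "matrix"
#: Window (cm^-1) of the O-H water interference band.
WATER_BAND = (5150.0, 5195.0)
#: Window (cm^-1) holding the main absorption bands of the cell-wall components.
INFORMATIVE_WINDOW = (4000.0, 7500.0)

_REGIONS = ("NEC", "NC", "EC", "CSC", "NWC", "SWC")


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: amplitude * exp(-(v-center)^2 / (2 width^2))."""

    center: float
    width: float
    amplitude: float


@dataclass
class ComponentLibrary:
    """Pure-component absorptivity spectra on a fixed wavenumber grid."""

    wavenumbers: np.ndarray
    bands: dict[str, tuple[Band, ...]]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        for name, bands in self.bands.items():
            for b in bands:
                if not lo <= b.center <= hi:
                    raise ConfigurationError(
                        f"{name}: band center {b.center} outside grid [{lo}, {hi}]"
                    )
                if b.amplitude < 0:
                    raise ConfigurationError(f"{name}: negative band amplitude")
        for b in self.bands.get(WATER, ()):
            if not WATER_BAND[0] <= b.center <= WATER_BAND[1]:
                raise ConfigurationError("water band center outside the water window")

    @property
    def components(self) -> list[str]:
        return list(self.bands)

    def absorptivity(self, name: str) -> np.ndarray:
        """Closed-form Gaussian-sum absorptivity of one component on the grid."""
        v = self.wavenumbers
        out = np.zeros_like(v)
        for b in self.bands[name]:
            out += b.amplitude * np.exp(-((v - b.center) ** 2) / (2.0 * b.width**2))
        return out

    def support_indices(self, name: str, threshold: float = 0.1) -> np.ndarray:
        """Grid indices where the component absorbs above ``threshold`` x its peak.

        This is the ground-truth bookkeeping that lets tests check whether a
        variable selector recovered a component's informative region.
        """
        s = self.absorptivity(name)
        return np.flatnonzero(s > threshold * s.max())


def make_component_library(
    seed: int,
    n_bands: tuple[int, int] = (3, 6),
    grid_points: int = 1557,
    grid_range: tuple[float, float] = (4000.0, 10000.0),
) -> ComponentLibrary:
    """Draw a random but reproducible library of pure-component spectra.

    Composition components receive all their Gaussian bands inside the
    4000-7500 cm^-1 window (where real cell-wall overtone/combination bands
    live); the water component absorbs only inside 5150-5195 cm^-1.
    """
    if grid_points < 10:
        raise ConfigurationError("grid_points must be >= 10")
    lo_bands, hi_bands = int(n_bands[0]), int(n_bands[1])
    if lo_bands < 1 or hi_bands < lo_bands:
        raise ConfigurationError("n_bands range must be >= 1 and ordered")
    rng = np.random.default_rng(seed)
    grid = np.linspace(grid_range[0], grid_range[1], int(grid_points))
    bands: dict[str, tuple[Band, ...]] = {}
    win_lo = max(INFORMATIVE_WINDOW[0] + 100.0, grid[0])
    win_hi = min(INFORMATIVE_WINDOW[1] - 100.0, grid[-1])
    for name in COMPOSITION_INDICATORS + (MATRIX,):
        k = int(rng.integers(lo_bands, hi_bands + 1))
        centers = rng.uniform(win_lo, win_hi, size=k)
        widths = rng.uniform(10.0, 60.0, size=k)
        amps = rng.uniform(0.004, 0.02, size=k)
        bands[name] = tuple(Band(c, w, a) for c, w, a in zip(centers, widths, amps))
    k = 2
    centers = rng.uniform(WATER_BAND[0], WATER_BAND[1], size=k)
    widths = rng.uniform(8.0, 20.0, size=k)
    amps = rng.uniform(0.01, 0.03, size=k)
    bands[WATER] = tuple(Band(c, w, a) for c, w, a in zip(centers, widths, amps))
    return ComponentLibrary(wavenumbers=grid, bands=bands)


@dataclass(frozen=True)
class IndicatorDistribution:
    """Truncated-normal concentration distribution, % dry matter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: negative SD")
        if self.lower >= self.upper:
            raise ConfigurationError(f"{name}: bounds inverted ({self.lower} >= {self.upper})")


def _default_composition() -> dict[str, IndicatorDistribution]:
    # Means match the printed population statistics for soluble sugars,
    # cellulose and hemicellulose; SDs/bounds bracket the ranges seen in the
    # top-graded accessions.
    return {
        "soluble_sugars": IndicatorDistribution(18.2, 5.0, 5.0, 40.0),
        "cellulose": IndicatorDistribution(28.3, 3.0, 18.0, 40.0),
        "hemicellulose": IndicatorDistribution(14.0, 2.5, 8.0, 22.0),
        "lignin": IndicatorDistribution(16.0, 2.5, 8.0, 25.0),
        "ash": IndicatorDistribution(4.2, 1.0, 1.5, 8.0),
    }


@dataclass
class SimulationConfig:
    """Study-scale defaults for one synthetic scanning campaign.

    Digestibility is linear-Gaussian in lignin and ash
    (yield = b0 + b1*lignin + b2*ash + eps, b1, b2 <= 0), which with the
    defaults lands total-carbohydrate yields in roughly the 63-83 % window.
    """

    n: int = 60
    composition: dict[str, IndicatorDistribution] = field(default_factory=_default_composition)
    water: IndicatorDistribution = field(
        default_factory=lambda: IndicatorDistribution(10.0, 3.0, 2.0, 20.0)
    )
    digest_intercept: float = 95.0
    lignin_slope: float = -1.2
    ash_slope: float = -0.8
    digest_noise_sd: float = 2.0
    yield_offset_sd: float = 2.0
    scatter_slope_sd: float = 0.02
    scatter_offset_sd: float = 0.01
    baseline_amplitude: float = 0.005
    noise_sd: float = 2e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.lignin_slope > 0 or self.ash_slope > 0:
            raise ConfigurationError("digestibility slopes must be <= 0")
        for sd_name in ("digest_noise_sd", "yield_offset_sd", "scatter_slope_sd",
                        "scatter_offset_sd", "noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        missing = [c for c in COMPOSITION_INDICATORS if c not in self.composition]
        if missing:
            raise ConfigurationError(f"composition distributions missing: {missing}")
        for name, dist in self.composition.items():
            dist.validate(name)
        self.water.validate("water")


def _truncated_normal(
    rng: np.random.Generator, dist: IndicatorDistribution, n: int, max_tries: int = 1000
) -> np.ndarray:
    """Rejection-sampled truncated normal; errors out after ``max_tries`` per draw."""
    out = np.empty(n)
    for i in range(n):
        for _ in range(max_tries):
            x = rng.normal(dist.mean, dist.sd)
            if dist.lower <= x <= dist.upper:
                out[i] = x
                break
        else:
            raise ConfigurationError(
                f"truncated-normal rejection failed after {max_tries} tries "
                f"(mean={dist.mean}, sd={dist.sd}, bounds=({dist.lower}, {dist.upper}))"
            )
    return out


def simulate_dataset(
    library: ComponentLibrary, config: SimulationConfig
) -> tuple[SpectralDataset, ReferenceTable]:
    """Simulate one campaign: spectra plus linked reference chemistry.

    Per sample: absorbance = slope * (sum_k c_k s_k(v) + c_w s_w(v) +
    baseline ramp) + offset + noise. All randomness comes from
    ``config.seed``; identical inputs give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    grid = library.wavenumbers
    p = grid.size

    conc = {name: _truncated_normal(rng, config.composition[name], n)
            for name in COMPOSITION_INDICATORS}
    water_conc = _truncated_normal(rng, config.water, n)

    lignin, ash = conc["lignin"], conc["ash"]
    total = (config.digest_intercept + config.lignin_slope * lignin
             + config.ash_slope * ash + rng.normal(0.0, config.digest_noise_sd, n))
    hexoses = total + rng.normal(0.0, config.yield_offset_sd, n)
    pentoses = total + rng.normal(0.0, config.yield_offset_sd, n)
    eps = 1e-6
    total, hexoses, pentoses = (np.clip(v, eps, 100.0) for v in (total, hexoses, pentoses))

    S = np.vstack([library.absorptivity(name) for name in COMPOSITION_INDICATORS])
    C = np.vstack([conc[name] for name in COMPOSITION_INDICATORS]).T  # (n, 5)
    pure = C @ S + np.outer(water_conc, library.absorptivity(WATER))
    # compositional closure: the residual dry matter absorbs too, so the
    # total absorbing mass stays near 100 % and MSC sees scatter, not
    # chemistry, in its slope estimate
    if MATRIX in library.bands:
        rest = np.clip(100.0 - C.sum(axis=1), 0.0, None)
        pure = pure + np.outer(rest, library.absorptivity(MATRIX))

    ramp = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = np.outer(rng.normal(0.0, config.baseline_amplitude, n), ramp)
    slope = np.clip(1.0 + rng.normal(0.0, config.scatter_slope_sd, n), 0.05, None)
    offset = rng.normal(0.0, config.scatter_offset_sd, n)
    noise = (rng.normal(0.0, config.noise_sd, (n, p)) if config.noise_sd > 0
             else np.zeros((n, p)))

    absorbance = slope[:, None] * (pure + baseline) + offset[:, None] + noise

    ids = [f"S{i + 1:03d}" for i in range(n)]
    regions = [str(r) for r in rng.choice(_REGIONS, size=n)]
    spectra = SpectralDataset(ids=ids, wavenumbers=grid.copy(),
                              absorbance=absorbance, regions=regions)
    ref = ReferenceTable(pd.DataFrame(
        {**{name: conc[name] for name in COMPOSITION_INDICATORS},
         "hexoses": hexoses, "pentoses": pentoses, "total_carbohydrates": total},
        index=pd.Index(ids, name="sample_id"),
    ))
    return spectra, ref


def write_fixture(
    outdir,
    library: ComponentLibrary,
    config: SimulationConfig,
    spectra: SpectralDataset,
    reference: ReferenceTable,
) -> None:
    """Bundle a simulated campaign into a directory with a YAML manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(spectra, out / "spectra.csv")
    write_reference_csv(reference, out / "reference.csv")
    manifest = {
        "seed": int(config.seed),
        "n_samples": int(config.n),
        "grid_points": int(library.wavenumbers.size),
        "grid_range": [float(library.wavenumbers[0]), float(library.wavenumbers[-1])],
        "config": _config_to_dict(config),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["composition"] = {k: asdict(v) for k, v in config.composition.items()}
    d["water"] = asdict(config.water)
    return d
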