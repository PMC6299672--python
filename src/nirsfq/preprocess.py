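"""Spectral pretreatments: MSC, Savitzky-Golay derivative, PCA inspection.

The modeling order is multiplicative scatter correction first (removes
per-sample multiplicative/additive scatter against a reference spectrum),
then a Savitzky-Golay smoothed first derivative (removes residual linear
baseline drift and sharpens overlapped bands). PCA score projection is
provided for population inspection and outlier visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datasets import ConfigurationError, SpectralDataset


@dataclass
class PreprocessConfig:
    """Pretreatment settings.

    ``window`` (odd, points) / ``polyorder`` / ``deriv`` parameterize the
    Savitzky-Golay filter; the derivative is expressed per cm^-1. The MSC
    reference is the calibration-subset mean unless a vector is supplied.
    """

    msc_reference: str = "mean"
    window: int = 11
    polyorder: int = 2
    deriv: int = 1
    msc_first: bool = True

    def validate(self) -> None:
        if self.window % 2 == 0:
            raise ConfigurationError("SG window must be odd")
        if self.window <= self.polyorder:
            raise ConfigurationError("SG window must exceed the polynomial order")
        if self.deriv not in (0, 1):
            raise ConfigurationError("derivative order must be 0 or 1")
        if self.deriv > self.polyorder:
            raise ConfigurationError("derivative order must not exceed polynomial order")


@dataclass
class MSCResult:
    """MSC output: corrected spectra, the reference used, per-sample flags."""

    dataset: SpectralDataset
    reference: np.ndarray
    passthrough_ids: list[str] = field(default_factory=list)


def msc(spectra: SpectralDataset, reference="mean") -> MSCResult:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r by ordinary least
    squares, x ~ a*r + b, and returned as (x - b) / a. Pass
    ``reference="mean"`` to use the mean spectrum of ``spectra`` itself
    (do this on the calibration subset, then reuse the returned reference
    for validation spectra to avoid leakage).
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ConfigurationError(f"unknown MSC reference {reference!r}")
        ref = spectra.absorbance.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != spectra.n_variables:
        raise ConfigurationError("MSC reference length must match the grid")
    ref_centered = ref - ref.mean()
    sxx = float(ref_centered @ ref_centered)
    if sxx <= 0:
        raise ConfigurationError("MSC reference is constant")

    X = spectra.absorbance
    Xc = X - X.mean(axis=1, keepdims=True)
    a = (Xc @ ref_centered) / sxx
    b = X.mean(axis=1) - a * ref.mean()
    corrected = X.copy()
    passthrough: list[str] = []
    ok = np.abs(a) > 1e-12
    corrected[ok] = (X[ok] - b[ok, None]) / a[ok, None]
    for i in np.flatnonzero(~ok):
        passthrough.append(spectra.ids[i])
    if passthrough:
        warnings.warn(
            f"MSC: degenerate slope for samples {passthrough}; passed through unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
    return MSCResult(dataset=spectra.with_absorbance(corrected), reference=ref,
                     passthrough_ids=passthrough)


def savgol_derivative(spectra: SpectralDataset, config: PreprocessConfig) -> SpectralDataset:
    """Savitzky-Golay smoothing / derivative, expressed per cm^-1.

    Requires a uniform grid; edges are handled by refitting the polynomial
    on the truncated window.
    """
    config.validate()
    grid = spectra.wavenumbers
    if grid.size < config.window:
        raise ConfigurationError("SG window larger than the grid")
    spacing = np.diff(grid)
    if spacing.size and not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
        raise ConfigurationError("SG filtering requires a uniform wavenumber grid")
    delta = float(spacing[0]) if spacing.size else 1.0
    out = savgol_filter(
        spectra.absorbance,
        window_length=config.window,
        polyorder=config.polyorder,
        deriv=config.deriv,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return spectra.with_absorbance(out)


@dataclass
class PCAProjection:
    """Mean-centered SVD projection of a spectra matrix."""

    loadings: np.ndarray  # (k, p)
    scores: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray  # (k,)
    mean: np.ndarray  # (p,)


def pca_scores(spectra: SpectralDataset, n_components: int = 3) -> PCAProjection:
    """PCA scores of the spectra for inspection plots.

    Sign convention: within each loading vector the largest-magnitude
    element is made positive, so score plots are reproducible.
    """
    X = spectra.absorbance
    n, p = X.shape
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise ConfigurationError(
            f"n_components must lie in [1, {max_k}] for {n} samples x {p} variables"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    k = n_components
    loadings = Vt[:k]
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAProjection(loadings=loadings, scores=scores,
                         explained_variance_ratio=evr, mean=mean)


def preprocess_pipeline(
    spectra: SpectralDataset,
    config: PreprocessConfig | None = None,
    msc_reference="mean",
) -> tuple[SpectralDataset, np.ndarray]:
    """MSC followed by the SG derivative; returns (dataset, MSC reference).

    The returned reference should be passed back in when transforming a
    validation subset so both subsets share the calibration reference.
    """
    config = config or PreprocessConfig()
    config.validate()
    if config.msc_first:
        res = msc(spectra, msc_reference)
        out = savgol_derivative(res.dataset, config)
        return out, res.reference
    out = savgol_derivative(spectra, config)
    res = msc(out, msc_reference)
    return res.dataset, res.reference
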