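"""Sample set partitioning (Kennard-Stone) and Chauvenet outlier rejection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.special import erfc

from .datasets import ConfigurationError, SpectralDataset


@dataclass
class SplitResult:
    """Calibration/validation membership plus the KS selection order."""

    calibration_ids: list[str]
    validation_ids: list[str]
    selection_order: list[str]


@dataclass
class OutlierReport:
    """Chauvenet screen: flagged IDs and the criterion value per sample."""

    flagged_ids: list[str]
    criterion: dict[str, float]
    statistic: str


def _as_matrix(spectra) -> tuple[np.ndarray, list[str]]:
    if isinstance(spectra, SpectralDataset):
        return spectra.absorbance, list(spectra.ids)
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    return X, [str(i) for i in range(X.shape[0])]


def kennard_stone_order(X: np.ndarray) -> list[int]:
    """Full Kennard-Stone ranking of row indices by max-min Euclidean distance.

    The first two picks are the most distant pair; every later pick maximizes
    its minimal distance to the already-picked set. Ties break toward the
    lowest row index.
    """
    n = X.shape[0]
    if n < 2:
        raise ConfigurationError("Kennard-Stone needs at least 2 samples")
    D = squareform(pdist(X, metric="euclidean"))
    if D.max() <= 0:
        raise ConfigurationError("degenerate geometry: all pairwise distances are zero")
    # first pair: argmax over i<j, ties to the lexicographically smallest pair
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest-index) maximum
    order = [int(iu[0][best]), int(iu[1][best])]
    remaining = [i for i in range(n) if i not in order]
    min_dist = np.minimum(D[order[0]], D[order[1]])
    while remaining:
        cand = remaining[int(np.argmax([min_dist[i] for i in remaining]))]
        order.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, D[cand])
    return order


def kennard_stone_split(spectra, validation_fraction: float) -> SplitResult:
    """Partition samples into calibration and validation subsets.

    The first ``ceil((1 - fraction) * n)`` KS-ranked samples form the
    calibration subset; the remainder (the least-representative tail) forms
    the validation subset. ``validation_fraction=0`` puts everything in
    calibration.
    """
    X, ids = _as_matrix(spectra)
    n = X.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 samples to split")
    if not 0 <= validation_fraction < 1:
        raise ConfigurationError("validation_fraction must lie in [0, 1)")
    order = kennard_stone_order(X)
    n_cal = int(np.ceil((1.0 - validation_fraction) * n))
    cal_idx = sorted(order[:n_cal])
    val_idx = sorted(order[n_cal:])
    return SplitResult(
        calibration_ids=[ids[i] for i in cal_idx],
        validation_ids=[ids[i] for i in val_idx],
        selection_order=[ids[i] for i in order],
    )


def chauvenet_criterion(z: np.ndarray, n: int) -> np.ndarray:
    """Chauvenet statistic n * erfc(|z| / sqrt(2)); values < 0.5 are rejected."""
    return n * erfc(np.abs(z) / np.sqrt(2.0))


def chauvenet_outliers(values, ids: list[str] | None = None) -> OutlierReport:
    """Single-pass Chauvenet screen of a numeric vector.

    Uses the sample SD (n-1 denominator); a zero-SD vector flags nothing.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ConfigurationError("Chauvenet's criterion needs at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("values must be finite")
    if ids is None:
        ids = [str(i) for i in range(n)]
    elif len(ids) != n:
        raise ConfigurationError("ids length must match values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        crit = np.full(n, float(n))
    else:
        z = (x - x.mean()) / sd
        crit = chauvenet_criterion(z, n)
    flagged = [ids[i] for i in np.flatnonzero(crit < 0.5)]
    return OutlierReport(
        flagged_ids=flagged,
        criterion={ids[i]: float(crit[i]) for i in range(n)},
        statistic="n*erfc(|z|/sqrt(2)) with sample SD",
    )
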