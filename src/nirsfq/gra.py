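"""Grey relational grade scoring of feedstock quality (FQS and FQG).

Deng's grey relational analysis turns the multi-indicator quality profile
of each sample into a single grade: indicators are min-max normalized with
benefit/cost orientation, compared against the all-ones ideal series via
the grey relational coefficient, and averaged with block weights (0.5 on
the five chemical indicators, 0.5 on total-carbohydrate digestibility).
The weighted grade gamma is rescaled to a 0-100 feedstock quality score
(best sample = 100) and banded into five grades A-E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, ReferenceTable

#: FQG bands: A = [80, 100], B = [60, 80), C = [40, 60), D = [20, 40), E = [0, 20).
GRADE_BANDS: tuple[tuple[str, float], ...] = (
    ("A", 80.0),
    ("B", 60.0),
    ("C", 40.0),
    ("D", 20.0),
    ("E", 0.0),
)


def _default_weights() -> dict[str, float]:
    # chemical block 0.5 split equally over five indicators; digestibility
    # block 0.5 carried by total carbohydrates alone
    return {
        "soluble_sugars": 0.1,
        "cellulose": 0.1,
        "hemicellulose": 0.1,
        "lignin": 0.1,
        "ash": 0.1,
        "total_carbohydrates": 0.5,
    }


@dataclass
class GRAConfig:
    """Indicator orientations, distinguishing coefficient and weights.

    Benefit indicators (more is better): soluble sugars, cellulose,
    hemicellulose, total-carbohydrate yield. Cost indicators (less is
    better): lignin, ash. ``rho`` is Deng's distinguishing coefficient.
    """

    benefit: tuple[str, ...] = (
        "soluble_sugars",
        "cellulose",
        "hemicellulose",
        "total_carbohydrates",
    )
    cost: tuple[str, ...] = ("lignin", "ash")
    rho: float = 0.5
    weights: dict[str, float] = field(default_factory=_default_weights)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.benefit) + tuple(self.cost)

    def validate(self) -> None:
        if not 0 < self.rho <= 1:
            raise ConfigurationError("rho must lie in (0, 1]")
        if set(self.benefit) & set(self.cost):
            raise ConfigurationError("an indicator cannot be both benefit and cost")
        if set(self.weights) != set(self.indicators):
            raise ConfigurationError(
                "weights must cover exactly the benefit + cost indicators"
            )
        w = np.array([self.weights[k] for k in self.indicators])
        if np.any(w < 0):
            raise ConfigurationError("weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1 (got {w.sum()})")


@dataclass
class GRAResult:
    """Full GRA output for one population."""

    normalized: pd.DataFrame
    xi: pd.DataFrame  # grey relational coefficients
    gamma: pd.Series  # weighted grades
    fqs: pd.Series  # 0-100 scores
    fqg: pd.Series  # A-E letters
    delta_min: float
    delta_max: float


def normalize_indicators(reference: ReferenceTable, config: GRAConfig) -> pd.DataFrame:
    """Min-max normalize the decision matrix with benefit/cost orientation.

    Benefit columns map (x - min)/(max - min); cost columns map
    (max - x)/(max - min), so 1 is always ideal. A zero-range column is set
    to all ones (it cannot discriminate) with a warning.
    """
    config.validate()
    if reference.n_samples < 2:
        raise ConfigurationError("GRA needs at least 2 samples")
    out = {}
    for name in config.indicators:
        x = reference.response(name)
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(f"indicator {name!r} has zero range; set to all-ones",
                          RuntimeWarning, stacklevel=2)
            out[name] = np.ones_like(x)
        elif name in config.benefit:
            out[name] = (x - x.min()) / rng
        else:
            out[name] = (x.max() - x) / rng
    return pd.DataFrame(out, index=pd.Index(reference.ids, name="sample_id"))


def grey_relational_coefficients(normalized: pd.DataFrame, rho: float) -> pd.DataFrame:
    """Deng's grey relational coefficient against the all-ones ideal series.

    xi_i(k) = (d_min + rho*d_max) / (d_i(k) + rho*d_max) where
    d_i(k) = |1 - x_i(k)| and d_min/d_max are global over the matrix.
    """
    if not 0 < rho <= 1:
        raise ConfigurationError("rho must lie in (0, 1]")
    M = normalized.to_numpy(dtype=float)
    if M.min() < -1e-12 or M.max() > 1 + 1e-12:
        raise ConfigurationError("normalized matrix must lie in [0, 1]")
    delta = np.abs(1.0 - M)
    d_min, d_max = float(delta.min()), float(delta.max())
    if d_max == 0.0:
        xi = np.ones_like(delta)
    else:
        xi = (d_min + rho * d_max) / (delta + rho * d_max)
    return pd.DataFrame(xi, index=normalized.index, columns=normalized.columns)


def fqs_scores(xi: pd.DataFrame, config: GRAConfig) -> tuple[pd.Series, pd.Series]:
    """Weighted grades gamma and their 0-100 min-max rescale (FQS).

    The best sample scores exactly 100 and the worst exactly 0; an
    all-equal gamma vector maps every sample to 100 with a warning.
    """
    config.validate()
    w = pd.Series(config.weights)
    gamma = (xi.loc[:, w.index] * w).sum(axis=1)
    g_min, g_max = float(gamma.min()), float(gamma.max())
    if g_max == g_min:
        warnings.warn("all grades equal; every FQS set to 100", RuntimeWarning,
                      stacklevel=2)
        fqs = pd.Series(100.0, index=gamma.index)
    else:
        # clip guards the band assignment against float overshoot at the ends
        fqs = (100.0 * (gamma - g_min) / (g_max - g_min)).clip(0.0, 100.0)
    return gamma.rename("gamma"), fqs.rename("fqs")


def assign_fqg(fqs) -> pd.Series:
    """Band FQS values into grades A-E.

    Bands are closed below and open above except A, which includes 100:
    A = [80, 100], B = [60, 80), C = [40, 60), D = [20, 40), E = [0, 20).
    """
    s = pd.Series(fqs, dtype=float)
    v = s.to_numpy()
    if np.any(v < 0) or np.any(v > 100) or not np.all(np.isfinite(v)):
        raise ConfigurationError("FQS values must lie in [0, 100]")
    grades = np.empty(v.size, dtype=object)
    for letter, lower in GRADE_BANDS:
        grades[(v >= lower) & (grades == None)] = letter  # noqa: E711
    return pd.Series(grades, index=s.index, name="fqg")


def grade_analysis(reference: ReferenceTable, config: GRAConfig | None = None) -> GRAResult:
    """Full GRA pipeline: normalize, coefficients, grades, scores, bands."""
    config = config or GRAConfig()
    normalized = normalize_indicators(reference, config)
    delta = np.abs(1.0 - normalized.to_numpy(dtype=float))
    xi = grey_relational_coefficients(normalized, config.rho)
    gamma, fqs = fqs_scores(xi, config)
    fqg = assign_fqg(fqs)
    return GRAResult(
        normalized=normalized,
        xi=xi,
        gamma=gamma,
        fqs=fqs,
        fqg=fqg,
        delta_min=float(delta.min()),
        delta_max=float(delta.max()),
    )
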