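"""Model-population-analysis variable selection: CARS and random frog.

Both selectors grow a population of Monte-Carlo PLS sub-models and keep the
wavenumbers that survive competition. CARS (competitive adaptive reweighted
sampling) combines an exponentially decreasing retained-variable schedule
with coefficient-magnitude-weighted resampling; random frog runs a
reversible-jump-like chain over variable subsets and reports per-variable
selection probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import ConfigurationError
from .pls import _feasible_components, fit_plsr, loo_press_curve


@dataclass
class CARSConfig:
    """CARS settings.

    ``n_runs`` Monte-Carlo runs each fit a PLS sub-model on ``sample_ratio``
    of the calibration samples; the exponentially decreasing function (EDF)
    forces the retained-variable count from p down to 2 across the runs.
    """

    n_runs: int = 50
    sample_ratio: float = 0.8
    max_components: int = 10
    cv_folds: int | None = None  # None -> leave-one-out scoring
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        if not 0 < self.sample_ratio < 1:
            raise ConfigurationError("sample_ratio must lie in (0, 1)")
        if self.max_components < 1:
            raise ConfigurationError("max_components must be >= 1")


@dataclass
class RandomFrogConfig:
    """Random frog settings.

    The chain starts from ``q_init`` random variables; candidate dimensions
    are drawn from Normal(|V|, theta*|V|); worse candidates are accepted
    with probability eta * (RMSECV_current / RMSECV_candidate). The final
    subset is the ``top_n`` most frequently visited variables (or everything
    above ``probability_cutoff`` when that is set instead).
    """

    n_iterations: int = 10000
    q_init: int = 2
    theta: float = 0.3
    omega: float = 3.0
    eta: float = 0.1
    max_components: int = 10
    cv_folds: int | None = 5
    top_n: int | None = 25
    probability_cutoff: float | None = None
    seed: int = 0

    def validate(self, p: int) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 1 <= self.q_init <= p:
            raise ConfigurationError("q_init must lie in [1, p]")
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigurationError("eta must lie in [0, 1]")
        if self.theta <= 0 or self.omega <= 0:
            raise ConfigurationError("theta and omega must be positive")
        if self.top_n is None and self.probability_cutoff is None:
            raise ConfigurationError("set top_n or probability_cutoff")


@dataclass
class VariableSubset:
    """A selected wavenumber subset plus its selection diagnostics."""

    method: str
    indices: np.ndarray  # sorted, unique grid indices
    rmsecv: float
    rmsecv_trace: np.ndarray | None = None  # CARS: per-run winning RMSECV
    n_retained_trace: np.ndarray | None = None  # CARS: per-run subset size
    probabilities: np.ndarray | None = field(default=None, repr=False)  # RF

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ConfigurationError("variable subset is empty")


def edf_ratios(p: int, n_runs: int) -> np.ndarray:
    """Retained-variable ratios r_i = a*exp(-k*i), i = 1..N.

    With a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1) this satisfies r_1 = 1
    (all p variables) and r_N = 2/p (two variables) exactly.
    """
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cv_rmsecv_curve(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    folds: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated RMSE per component count 1..cap on a variable subset.

    ``folds=None`` (or >= n) gives leave-one-out. K-fold assignment uses
    contiguous blocks after a shuffle seeded by ``seed``, so the curve is
    deterministic for fixed arguments. The cap is clipped to what the fold
    sizes admit (with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p == 0:
        raise ConfigurationError("subset is empty")
    k = _feasible_components(n - max(2, int(np.ceil(n / (folds or n)))), p, max_components)
    if k < max_components:
        warnings.warn("PLS components clipped to the feasible maximum for this subset",
                      RuntimeWarning, stacklevel=2)
    if folds is None or folds >= n:
        return np.sqrt(loo_press_curve(X, y, k) / n)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    press = np.zeros(k)
    for fold in np.array_split(perm, folds):
        train = np.setdiff1d(perm, fold)
        kf = _feasible_components(train.size, p, k)
        model = fit_plsr(X[train], y[train], kf)
        path = model.predict_path(X[fold])  # (n_fold, k_avail)
        sq = ((path - y[fold][:, None]) ** 2).sum(axis=0)
        if model.n_components < k:
            sq = np.concatenate([sq, np.full(k - model.n_components, sq[-1])])
        press += sq
    return np.sqrt(press / n)


def subset_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    components: int,
    folds: int | None = None,
    seed: int = 0,
) -> float:
    """Cross-validated RMSE of a PLS model with ``components`` latent
    variables on the given variable subset (clipped to feasibility)."""
    curve = cv_rmsecv_curve(X, y, components, folds=folds, seed=seed)
    return float(curve[-1])


def _best_rmsecv(X, y, max_components, folds, seed) -> float:
    """Subset score: RMSECV at the best component count up to the cap.

    This mirrors how the final calibration chooses its latent dimension, so
    competing subsets of very different sizes are compared fairly.
    """
    curve = cv_rmsecv_curve(X, y, max_components, folds=folds, seed=seed)
    return float(curve.min())


def _fit_weights(X, y, components, rng, sample_ratio, var_idx):
    """|coefficient| weights from one Monte-Carlo PLS sub-model."""
    n = X.shape[0]
    n_mc = max(3, int(round(sample_ratio * n)))
    rows = rng.choice(n, size=min(n_mc, n), replace=False)
    k = _feasible_components(rows.size, var_idx.size, components)
    model = fit_plsr(X[np.ix_(rows, var_idx)], y[rows], k)
    return np.abs(np.atleast_1d(model.coef_))


def cars_select(X: np.ndarray, y: np.ndarray, config: CARSConfig) -> VariableSubset:
    """Competitive adaptive reweighted sampling.

    Each run: Monte-Carlo sample the calibration rows, fit PLS on the
    currently retained variables, rank variables by |coefficient|, enforce
    the EDF schedule, then resample p times with coefficient-proportional
    weights and keep the distinct draws. The subset with minimal
    cross-validated RMSE across runs wins (ties: smaller subset, then
    earlier run).
    """
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ConfigurationError("CARS needs p >= 3")
    rng = np.random.default_rng(config.seed)
    ratios = edf_ratios(p, config.n_runs)
    # latent dimension for the weight fits, chosen once on the full spectrum
    # by the same CV rule as the final calibration; refitting at a noisy
    # over-large dimension would randomize the coefficient ranking
    curve0 = cv_rmsecv_curve(X, y, config.max_components,
                             folds=config.cv_folds, seed=config.seed)
    k_weights = int(np.argmin(curve0)) + 1

    retained = np.arange(p)
    candidates: list[np.ndarray] = []
    scores = np.empty(config.n_runs)
    sizes = np.empty(config.n_runs, dtype=int)
    for run in range(config.n_runs):
        w = _fit_weights(X, y, k_weights, rng, config.sample_ratio, retained)
        # EDF: keep the top ceil(r_i * p) variables by weight
        keep = min(retained.size, max(2, int(np.ceil(ratios[run] * p))))
        order = np.argsort(-w, kind="stable")[:keep]
        kept_vars = retained[order]  # rank order; stays aligned with kept weights
        w_kept = w[order]
        # adaptive reweighted sampling: p weighted draws with replacement
        if w_kept.sum() <= 0:
            probs = np.full(w_kept.size, 1.0 / w_kept.size)
        else:
            probs = w_kept / w_kept.sum()
        drawn = np.unique(rng.choice(kept_vars, size=p, replace=True, p=probs))
        if drawn.size < 2:
            drawn = kept_vars[:2]
        retained = np.sort(drawn)
        scores[run] = _best_rmsecv(X[:, retained], y, config.max_components,
                                   config.cv_folds, config.seed)
        sizes[run] = retained.size
        candidates.append(retained.copy())

    # minimal RMSECV; ties -> smaller subset, then earlier run
    best = min(range(config.n_runs), key=lambda i: (scores[i], sizes[i], i))
    return VariableSubset(
        method="CARS",
        indices=candidates[best],
        rmsecv=float(scores[best]),
        rmsecv_trace=scores,
        n_retained_trace=sizes,
    )


def random_frog_select(
    X: np.ndarray, y: np.ndarray, config: RandomFrogConfig
) -> VariableSubset:
    """Random frog chain over variable subsets.

    Counts every variable's membership in the accepted chain; the selection
    probability is count / n_iterations and the final subset is taken from
    the top of that ranking.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ConfigurationError("random frog needs p >= 3")
    config.validate(p)
    rng = np.random.default_rng(config.seed)

    def score(idx: np.ndarray) -> float:
        return _best_rmsecv(X[:, idx], y, config.max_components,
                            config.cv_folds, config.seed)

    def coef_rank(idx: np.ndarray) -> np.ndarray:
        """idx sorted by decreasing |coefficient| of a PLS fit on idx."""
        k = _feasible_components(n, idx.size, config.max_components)
        model = fit_plsr(X[:, idx], y, k)
        w = np.abs(np.atleast_1d(model.coef_))
        return idx[np.argsort(-w, kind="stable")]

    V = np.sort(rng.choice(p, size=config.q_init, replace=False))
    r_cur = score(V)
    counts = np.zeros(p)
    chain_rmsecv = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        q_star = int(np.clip(round(rng.normal(V.size, config.theta * V.size)), 1, p))
        if q_star < V.size:
            V_cand = np.sort(coef_rank(V)[:q_star])
        elif q_star > V.size:
            outside = np.setdiff1d(np.arange(p), V)
            n_extra = min(outside.size, int(np.ceil(config.omega * (q_star - V.size))))
            pool = np.concatenate([V, rng.choice(outside, size=n_extra, replace=False)])
            V_cand = np.sort(coef_rank(np.sort(pool))[:q_star])
        else:
            V_cand = V
        r_cand = score(V_cand) if V_cand is not V else r_cur
        if r_cand <= r_cur or rng.random() < config.eta * (r_cur / r_cand):
            V, r_cur = V_cand, r_cand
        counts[V] += 1.0
        chain_rmsecv[it] = r_cur

    probabilities = counts / config.n_iterations
    if config.probability_cutoff is not None:
        selected = np.flatnonzero(probabilities >= config.probability_cutoff)
        if selected.size == 0:
            warnings.warn("probability cutoff selected nothing; falling back to top-5",
                          RuntimeWarning, stacklevel=2)
            selected = _top_by_probability(probabilities, 5)
    else:
        selected = _top_by_probability(probabilities, config.top_n)
    return VariableSubset(
        method="RF",
        indices=np.sort(selected),
        rmsecv=float(score(np.sort(selected))),
        rmsecv_trace=chain_rmsecv,
        probabilities=probabilities,
    )


def _top_by_probability(probabilities: np.ndarray, top_n: int) -> np.ndarray:
    top_n = min(top_n, probabilities.size)
    order = np.argsort(-probabilities, kind="stable")  # ties -> lower index first
    return order[:top_n]


def water_band_fraction(
    indices: np.ndarray, wavenumbers: np.ndarray, band: tuple[float, float] = (5150.0, 5195.0)
) -> float:
    """Fraction of selected variables that fall inside the water band."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        return 0.0
    w = np.asarray(wavenumbers, dtype=float)[idx]
    return float(np.mean((w >= band[0]) & (w <= band[1])))
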