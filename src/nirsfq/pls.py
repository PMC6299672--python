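"""NIPALS partial least squares: regression, discriminant analysis, metrics.

Implements PLS1/PLS2 by the classical NIPALS iteration with mean centering
only (no unit-variance scaling of X or y), leave-one-out component
selection, and the calibration/validation metric suite used throughout NIR
calibration work: RMSEC, RMSECV, RMSEP, R2c, R2cv, R2v, RPD and RER.

Two R^2 conventions coexist deliberately. Calibration and cross-validation
R^2 are 1 - SS_res/SS_tot against the calibration mean; external-validation
R2v is the squared Pearson correlation between predicted and reference
values. The two differ whenever predictions are biased, so reports label
them separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ConfigurationError


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model (univariate or multi-response).

    ``coefficients(k)`` gives the regression coefficient matrix on the
    original (centered) variables using the first ``k`` latent components,
    so predictions are ``y_mean + (X - x_mean) @ B_k``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # W, (p, k)
    x_loadings: np.ndarray  # P, (p, k)
    y_loadings: np.ndarray  # Q, (m, k)
    x_scores: np.ndarray  # T, (n, k)
    explained_x_variance: np.ndarray = field(repr=False)  # per-component fractions
    _univariate: bool = True

    @property
    def cumulative_x_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_x_variance)

    def coefficients(self, k: int | None = None) -> np.ndarray:
        k = self.n_components if k is None else int(k)
        if not 1 <= k <= self.n_components:
            raise ConfigurationError(f"k must lie in [1, {self.n_components}]")
        W, P, Q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        R = W @ np.linalg.inv(P.T @ W)
        return R @ Q.T  # (p, m)

    @property
    def coef_(self) -> np.ndarray:
        b = self.coefficients()
        return b[:, 0] if self._univariate else b

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = self.y_mean + (X - self.x_mean) @ self.coefficients(k)
        return Y[:, 0] if self._univariate else Y

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every truncation 1..n_components.

        Returns shape ``(n, k)`` for univariate models, ``(n, m, k)``
        otherwise. Used to make LOO component selection a single fit per
        left-out sample.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean
        ks = self.n_components
        m = self.y_mean.size
        out = np.empty((X.shape[0], m, ks))
        for k in range(1, ks + 1):
            out[:, :, k - 1] = self.y_mean + Xc @ self.coefficients(k)
        return out[:, 0, :] if self._univariate else out


def _nipals(Xc: np.ndarray, Yc: np.ndarray, k: int,
            tol: float = 1e-12, max_iter: int = 500):
    """Classical NIPALS on centered matrices; returns W, P, Q, T, explained."""
    n, p = Xc.shape
    m = Yc.shape[1]
    X = Xc.copy()
    Y = Yc.copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((m, k))
    T = np.zeros((n, k))
    ss_x = float(np.sum(Xc**2))
    explained = np.zeros(k)
    a = 0
    for a in range(k):
        if m == 1:
            w = X.T @ Y[:, 0]
            nw = np.linalg.norm(w)
            if nw < 1e-13:
                break
            w = w / nw
            t = X @ w
            tt = float(t @ t)
            if tt < 1e-13:
                break
            q = (Y.T @ t) / tt
        else:
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t = np.zeros(n)
            degenerate = False
            for _ in range(max_iter):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-13:
                    degenerate = True
                    break
                w = w / nw
                t_new = X @ w
                tt = float(t_new @ t_new)
                if tt < 1e-13:
                    degenerate = True
                    break
                q = (Y.T @ t_new) / tt
                qq = float(q @ q)
                if qq < 1e-13:
                    degenerate = True
                    break
                u = (Y @ q) / qq
                if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    break
                t = t_new
            if degenerate:
                break
            tt = float(t @ t)
            q = (Y.T @ t) / tt
        pa = (X.T @ t) / tt
        X = X - np.outer(t, pa)
        Y = Y - np.outer(t, q)
        W[:, a] = w
        P[:, a] = pa
        Q[:, a] = q
        T[:, a] = t
        explained[a] = tt * float(pa @ pa) / ss_x if ss_x > 0 else 0.0
        a += 1
    return W[:, :a], P[:, :a], Q[:, :a], T[:, :a], explained[:a]


def fit_plsr(X: np.ndarray, y: np.ndarray, components: int) -> PLSModel:
    """Fit a PLS regression with ``components`` latent variables.

    ``y`` may be a vector (PLS1) or a matrix (PLS2, one column per
    response). Only mean centering is applied.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    univariate = y.ndim == 1
    Y = y[:, None] if univariate else y
    n, p = X.shape
    if Y.shape[0] != n:
        raise ConfigurationError("X and y sample counts differ")
    if np.allclose(Y.std(axis=0), 0):
        raise ConfigurationError("constant response")
    max_k = min(n - 1, p)
    if not 1 <= components <= max_k:
        raise ConfigurationError(
            f"components must lie in [1, {max_k}] for n={n}, p={p}"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, P, Q, T, explained = _nipals(X - x_mean, Y - y_mean, components)
    if W.shape[1] < components:
        warnings.warn(
            f"NIPALS stopped after {W.shape[1]} of {components} components "
            "(X residual exhausted)",
            RuntimeWarning,
            stacklevel=2,
        )
        if W.shape[1] == 0:
            raise ConfigurationError("no extractable latent component")
    return PLSModel(
        n_components=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        explained_x_variance=explained,
        _univariate=univariate,
    )


@dataclass
class NullModel:
    """Mean-only predictor, the 0-component baseline."""

    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.y_mean)


def null_model(y: np.ndarray) -> NullModel:
    return NullModel(y_mean=float(np.mean(y)))


# ---------------------------------------------------------------------------
# component selection


def _feasible_components(n_train: int, p: int, requested: int) -> int:
    return max(1, min(requested, n_train - 1, p))


def loo_press_curve(X: np.ndarray, Y: np.ndarray, max_components: int) -> np.ndarray:
    """Leave-one-out squared prediction error summed per component count.

    Returns ``press`` of shape ``(max_components,)`` where entry k-1 sums the
    squared LOO residuals (over all responses) using k components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n = X.shape[0]
    kmax = _feasible_components(n - 1, X.shape[1], max_components)
    press = np.zeros(kmax)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_plsr(X[keep], Y2[keep] if Y2.shape[1] > 1 else Y2[keep, 0], kmax)
        path = model.predict_path(X[i: i + 1])
        k_avail = model.n_components
        if Y2.shape[1] == 1:
            resid = path[0, :] - Y2[i, 0]  # (k_avail,)
            sq = resid**2
        else:
            resid = path[0] - Y2[i][:, None]  # (m, k_avail)
            sq = (resid**2).sum(axis=0)
        if k_avail < kmax:  # pad with the last available truncation
            sq = np.concatenate([sq, np.full(kmax - k_avail, sq[-1])])
        press += sq
    return press


def select_components(
    X: np.ndarray, y: np.ndarray, max_components: int = 10
) -> tuple[int, np.ndarray]:
    """Choose the latent dimension by leave-one-out RMSECV.

    Returns the global minimizer of the LOO RMSECV curve over 1..cap
    (ties go to the fewest components) together with the curve itself.
    """
    if max_components < 1:
        raise ConfigurationError("max_components must be >= 1")
    Y = np.asarray(y, dtype=float)
    n = np.atleast_2d(np.asarray(X)).shape[0]
    m = 1 if Y.ndim == 1 else Y.shape[1]
    press = loo_press_curve(X, y, max_components)
    rmsecv = np.sqrt(press / (n * m))
    best = int(np.argmin(rmsecv)) + 1  # argmin takes the first minimum -> fewest PCs
    return best, rmsecv


# ---------------------------------------------------------------------------
# regression metrics


@dataclass
class CalibrationReport:
    """Calibration-subset summary: RMSEC/R2c and LOO RMSECV/R2cv."""

    n: int
    n_components: int
    rmsec: float
    r2c: float
    rmsecv: float
    r2cv: float


@dataclass
class ValidationReport:
    """External-validation summary: RMSEP, R2v, RPD, RER.

    R2v is the squared Pearson correlation between predicted and reference
    values. RPD = sample SD(reference)/RMSEP; RER = range(reference)/RMSEP.
    ``excellent`` applies the conventional screening rule RPD > 3 and
    RER > 15. A zero RMSEP yields infinite RPD/RER with ``perfect_fit`` set.
    """

    n: int
    rmsep: float
    r2v: float
    rpd: float
    rer: float
    excellent: bool
    perfect_fit: bool = False


def calibration_metrics(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    rmsecv_curve: np.ndarray | None = None,
) -> CalibrationReport:
    """Compute RMSEC/R2c on the calibration data and RMSECV/R2cv by LOO.

    Pass the curve from :func:`select_components` to avoid recomputing the
    LOO loop; otherwise it is recomputed at the model's component count.
    """
    y = np.asarray(y_cal, dtype=float).ravel()
    n = y.size
    pred = model.predict(X_cal)
    ss_res = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmsec = float(np.sqrt(ss_res / n))
    r2c = 1.0 - ss_res / ss_tot
    k = model.n_components
    if rmsecv_curve is not None and len(rmsecv_curve) >= k:
        rmsecv = float(rmsecv_curve[k - 1])
    else:
        press = loo_press_curve(X_cal, y, k)
        rmsecv = float(np.sqrt(press[min(k, len(press)) - 1] / n))
    r2cv = 1.0 - (n * rmsecv**2) / ss_tot
    return CalibrationReport(n=n, n_components=k, rmsec=rmsec, r2c=r2c,
                             rmsecv=rmsecv, r2cv=r2cv)


def validation_metrics(model_or_pred, X_val=None, y_val=None) -> ValidationReport:
    """External-validation metric suite.

    Accepts either ``(model, X_val, y_val)`` or a precomputed prediction
    vector as the first argument with ``y_val`` as the reference.
    """
    if isinstance(model_or_pred, (PLSModel, NullModel)):
        pred = model_or_pred.predict(X_val)
    else:
        pred = np.asarray(model_or_pred, dtype=float).ravel()
        if y_val is None:
            y_val = X_val
    y = np.asarray(y_val, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ConfigurationError("validation needs at least 3 samples")
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise ConfigurationError("zero-variance validation reference; R2v undefined")
    rmsep = float(np.sqrt(np.mean((pred - y) ** 2)))
    rng_y = float(y.max() - y.min())
    if rmsep == 0.0:
        return ValidationReport(n=n, rmsep=0.0, r2v=1.0, rpd=float("inf"),
                                rer=float("inf"), excellent=True, perfect_fit=True)
    if np.std(pred) == 0.0:
        r2v = 0.0  # constant prediction carries no correlation information
    else:
        r2v = float(np.corrcoef(pred, y)[0, 1] ** 2)
    rpd = sd / rmsep
    rer = rng_y / rmsep
    return ValidationReport(n=n, rmsep=rmsep, r2v=r2v, rpd=rpd, rer=rer,
                            excellent=(rpd > 3.0 and rer > 15.0))


# ---------------------------------------------------------------------------
# discriminant analysis


@dataclass
class PLSDAModel:
    """PLS-DA: a multi-response PLS model over one-hot class indicators.

    Classes are stored sorted ascending (grade letters A before B, ...), so
    ``argmax`` ties resolve to the better grade.
    """

    pls: PLSModel
    classes: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.pls.n_components

    def predict_indicators(self, X: np.ndarray) -> np.ndarray:
        out = self.pls.predict(X)
        return out[:, None] if out.ndim == 1 else out

    def predict_class(self, X: np.ndarray) -> list[str]:
        scores = self.predict_indicators(X)
        return [self.classes[int(i)] for i in np.argmax(scores, axis=1)]


def one_hot(labels, classes: tuple[str, ...]) -> np.ndarray:
    """Indicator matrix over ``classes``; labels outside get an all-zero row."""
    labels = [str(l) for l in labels]
    Y = np.zeros((len(labels), len(classes)))
    lookup = {c: j for j, c in enumerate(classes)}
    for i, l in enumerate(labels):
        j = lookup.get(l)
        if j is not None:
            Y[i, j] = 1.0
    return Y


def fit_plsda(X: np.ndarray, class_labels, components: int) -> PLSDAModel:
    """Fit PLS-DA on one-hot indicators of the class labels."""
    labels = [str(l) for l in class_labels]
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ConfigurationError(">=2 classes required in calibration")
    Y = one_hot(labels, classes)
    model = fit_plsr(X, Y, components)
    return PLSDAModel(pls=model, classes=classes)


@dataclass
class ClassificationReport:
    """PLS-DA summary: R2 / Q2 over the indicator matrix plus correct rates."""

    n_components: int
    r2: float
    q2: float
    n_calibration: int
    calibration_correct: float  # percent
    n_validation: int
    validation_correct: float  # percent
    confusion: pd.DataFrame = field(repr=False)


def classification_metrics(
    model: PLSDAModel,
    X_cal: np.ndarray,
    labels_cal,
    X_val: np.ndarray,
    labels_val,
) -> ClassificationReport:
    """Correct rates on both subsets, calibration R2 and validation Q2.

    R2 = 1 - SS_res/SS_tot of the fitted indicators on calibration; Q2 =
    1 - PRESS/SS_tot of the predicted indicators on validation, both SS_tot
    against the calibration class frequencies.
    """
    labels_cal = [str(l) for l in labels_cal]
    labels_val = [str(l) for l in labels_val]
    unseen = sorted(set(labels_val) - set(model.classes))
    if unseen:
        warnings.warn(
            f"classes {unseen} absent from calibration; their samples count as errors",
            RuntimeWarning,
            stacklevel=2,
        )
    Y_cal = one_hot(labels_cal, model.classes)
    Y_val = one_hot(labels_val, model.classes)
    y_bar = Y_cal.mean(axis=0)

    fitted = model.predict_indicators(X_cal)
    ss_res = float(np.sum((fitted - Y_cal) ** 2))
    ss_tot = float(np.sum((Y_cal - y_bar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    pred_val = model.predict_indicators(X_val)
    press = float(np.sum((pred_val - Y_val) ** 2))
    ss_tot_val = float(np.sum((Y_val - y_bar) ** 2))
    q2 = 1.0 - press / ss_tot_val if ss_tot_val > 0 else float("nan")

    cal_pred = model.predict_class(X_cal)
    val_pred = model.predict_class(X_val)
    cal_correct = 100.0 * float(np.mean([p == t for p, t in zip(cal_pred, labels_cal)]))
    val_correct = 100.0 * float(np.mean([p == t for p, t in zip(val_pred, labels_val)]))

    all_classes = sorted(set(model.classes) | set(labels_val))
    confusion = pd.DataFrame(0, index=all_classes, columns=list(model.classes))
    for t, p in zip(labels_val, val_pred):
        confusion.loc[t, p] += 1
    return ClassificationReport(
        n_components=model.n_components,
        r2=r2,
        q2=q2,
        n_calibration=len(labels_cal),
        calibration_correct=cal_correct,
        n_validation=len(labels_val),
        validation_correct=val_correct,
        confusion=confusion,
    )
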