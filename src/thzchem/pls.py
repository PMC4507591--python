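"""From-scratch NIPALS partial least squares regression (PLS1).

The response is the integer class code 1..K treated as a single numeric
variable — deliberately so, matching the discrimination-by-regression
design this package implements (not one-hot PLS-DA). Predictors are
mean-centred only; no variance scaling, since all variables share units.

NIPALS extracts one latent factor at a time:

    w_a ∝ X_a' y_a          (weights: covariance direction)
    t_a = X_a w_a           (X scores)
    p_a = X_a' t_a / t_a't_a (X loadings)
    q_a = y_a' t_a / t_a't_a (y loading)
    X_{a+1} = X_a - t_a p_a'
    y_{a+1} = y_a - q_a t_a

and the regression vector mapping centred X to centred y is
B = W (P'W)^{-1} q. Scores t_a are mutually orthogonal by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from .containers import SpectraMatrix

__all__ = [
    "PLSModel",
    "CVResult",
    "ClassAssignment",
    "fit_pls",
    "predict",
    "rmse",
    "correlation",
    "loo_cv",
    "assign_class",
    "split_dataset",
]


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 model and everything needed to apply it."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x A  (W)
    x_loadings: np.ndarray    # p x A  (P)
    y_loadings: np.ndarray    # A      (q)
    x_scores: np.ndarray      # n x A  (T)
    y_scores: np.ndarray      # n x A  (U)
    coefficients: np.ndarray  # p      (B, centred scale)
    variable_frequencies: Optional[np.ndarray] = None
    rmsec: float = float("nan")

    @property
    def n_variables(self) -> int:
        return self.coefficients.size

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


@dataclass(frozen=True)
class CVResult:
    """Assembled cross-validation predictions and summary metrics."""

    predictions: np.ndarray
    rmsecv: float
    r: float
    fold_assignments: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.rmsecv < 0:
            raise ValueError("rmsecv must be >= 0")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation out of [-1, 1]")


@dataclass(frozen=True)
class ClassAssignment:
    classes: np.ndarray
    accuracy: Optional[float] = None


def _unpack(
    X: Union[SpectraMatrix, np.ndarray], y: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    if isinstance(X, SpectraMatrix):
        return X.X, X.y.astype(float), X.variable_frequencies
    if y is None:
        raise ValueError("y required when X is a plain array")
    return np.asarray(X, float), np.asarray(y, float), None


def fit_pls(
    X: Union[SpectraMatrix, np.ndarray],
    n_components: int,
    y: Optional[np.ndarray] = None,
) -> PLSModel:
    """Fit NIPALS PLS1 on mean-centred X and y.

    ``X`` may be a :class:`SpectraMatrix` (labels used as the response) or
    a plain array with ``y`` given separately.
    """
    Xa, ya, freqs = _unpack(X, y)
    n, p = Xa.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    if np.ptp(ya) == 0:
        raise ValueError("response has zero variance")

    x_mean = Xa.mean(axis=0)
    y_mean = float(ya.mean())
    Xc = Xa - x_mean
    yc = ya - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    w0 = t0 = None
    extracted = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wnorm = np.linalg.norm(w)
        if w0 is None:
            w0 = wnorm
        if wnorm <= 1e-12 * w0 or wnorm == 0.0:
            if a == 0:
                raise ValueError("X carries no covariance with the response")
            # collinear variables: effective rank reached; later components
            # would be numerical noise
            warnings.warn(
                f"covariance exhausted after {a} of {n_components} "
                "components; model truncated",
                stacklevel=2,
            )
            break
        w /= wnorm
        t = Xd @ w
        tt = float(t @ t)
        if t0 is None:
            t0 = tt
        if tt <= 1e-24 * t0:
            if a == 0:
                raise ValueError("degenerate scores at the first component")
            warnings.warn(
                f"degenerate score at component {a + 1}; model truncated "
                f"at {a} components",
                stacklevel=2,
            )
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        U[:, a] = yd  # y-side score direction before deflation (PLS1)
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        extracted = a + 1

    n_components = extracted
    W, P, q, T, U = (
        W[:, :extracted],
        P[:, :extracted],
        q[:extracted],
        T[:, :extracted],
        U[:, :extracted],
    )
    B = W @ np.linalg.solve(P.T @ W, q)
    fitted = Xc @ B + y_mean
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        y_scores=U,
        coefficients=B,
        variable_frequencies=freqs,
        rmsec=rmse(ya, fitted),
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Apply a fitted model: y_hat = (X_new - x_mean) B + y_mean."""
    Xn = np.asarray(
        X_new.X if isinstance(X_new, SpectraMatrix) else X_new, dtype=float
    )
    single = Xn.ndim == 1
    Xn = np.atleast_2d(Xn)
    if Xn.shape[1] != model.n_variables:
        raise ValueError(
            f"X_new has {Xn.shape[1]} variables, model expects {model.n_variables}"
        )
    out = (Xn - model.x_mean) @ model.coefficients + model.y_mean
    return out[0] if single else out


def rmse(y_ref, y_pred) -> float:
    """Root-mean-square error sqrt(sum (y_ri - y_pi)^2 / n).

    One formula serves RMSEC (training), RMSECV (cross-validated) and
    RMSEP (held-out prediction set) — only the predictions differ.
    """
    yr = np.asarray(y_ref, float)
    yp = np.asarray(y_pred, float)
    if yr.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if yr.shape != yp.shape:
        raise ValueError("inputs must share shape")
    return float(np.sqrt(np.mean((yr - yp) ** 2)))


def correlation(y_ref, y_pred) -> float:
    """Pearson correlation between reference and predicted values."""
    yr = np.asarray(y_ref, float)
    yp = np.asarray(y_pred, float)
    if yr.size < 2 or yr.shape != yp.shape:
        raise ValueError("need >= 2 paired values")
    if np.ptp(yr) == 0 or np.ptp(yp) == 0:
        raise ValueError("correlation undefined for constant input")
    dr, dp = yr - yr.mean(), yp - yp.mean()
    return float(
        (dr @ dp) / np.sqrt((dr @ dr) * (dp @ dp))
    )


def loo_cv(
    X: Union[SpectraMatrix, np.ndarray],
    n_components: int,
    y: Optional[np.ndarray] = None,
) -> CVResult:
    """Leave-one-out cross-validation: refit without each sample, predict it.

    Deterministic — LOO has no random element.
    """
    Xa, ya, _ = _unpack(X, y)
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        try:
            model = fit_pls(Xa[rest], n_components, y=ya[rest])
        except ValueError as exc:
            raise ValueError(f"LOO fold {i} failed: {exc}") from exc
        preds[i] = predict(model, Xa[i])
    return CVResult(
        predictions=preds,
        rmsecv=rmse(ya, preds),
        r=correlation(ya, preds),
        fold_assignments=idx.copy(),
    )


def assign_class(
    predictions: np.ndarray,
    n_classes: int,
    true_labels: Optional[np.ndarray] = None,
) -> ClassAssignment:
    """Map real-valued predictions to class codes 1..K by nearest integer.

    Half-way points round up (1.5 -> 2); out-of-range predictions clamp to
    the nearest extreme class. If ``true_labels`` is given the fraction of
    correct assignments is reported too.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    p = np.asarray(predictions, float)
    classes = np.clip(np.floor(p + 0.5), 1, n_classes).astype(int)
    acc = None
    if true_labels is not None:
        t = np.asarray(true_labels, int)
        if t.shape != classes.shape:
            raise ValueError("true_labels must match predictions")
        acc = float(np.mean(classes == t))
    return ClassAssignment(classes=classes, accuracy=acc)


def split_dataset(
    X: SpectraMatrix, calibration_fraction: float, seed: int
) -> Tuple[SpectraMatrix, SpectraMatrix]:
    """Stratified random calibration/prediction split, reproducible by seed.

    Each class contributes ``round(fraction * n_c)`` samples to the
    calibration set; both sets must retain every class at least twice.
    """
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    cal_idx, pred_idx = [], []
    for c in np.unique(X.y):
        members = np.flatnonzero(X.y == c)
        n_cal = int(round(calibration_fraction * members.size))
        perm = rng.permutation(members)
        cal_idx.extend(perm[:n_cal].tolist())
        pred_idx.extend(perm[n_cal:].tolist())
        if n_cal < 2 or members.size - n_cal < 2:
            raise ValueError(
                f"class {c}: split {n_cal}/{members.size - n_cal} leaves a "
                "set with fewer than 2 members"
            )
    return (
        X.select_samples(sorted(cal_idx)),
        X.select_samples(sorted(pred_idx)),
    )
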