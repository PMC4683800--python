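"""NIPALS PLS regression, leave-one-out cross-validation and metrics.

Single-response PLS1 with mean-centering of both blocks and no variance
scaling (absorbance units are commensurate across wavelengths).  Latent
factor counts are selected by the lowest predicted residual sum of squares
(PRESS) from leave-one-out cross-validation, ties resolved toward fewer
factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "PressCurve",
    "ModelMetrics",
    "pls_fit",
    "pls_predict",
    "rmse",
    "r_squared",
    "loo_cv",
    "evaluate",
]


@dataclass
class PLSModel:
    n_factors: int
    x_mean: np.ndarray  # over masked variables
    y_mean: float
    weights: np.ndarray  # (p_masked, A)
    x_loadings: np.ndarray  # (p_masked, A)
    y_loadings: np.ndarray  # (A,)
    regression_vector: np.ndarray  # (p_masked,)
    variable_mask: np.ndarray  # indices into the full variable axis
    n_input_columns: int  # full variable axis width the mask refers to
    scores: np.ndarray | None = None  # training scores (n, A), kept for diagnostics

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "variable_mask": self.variable_mask.tolist(),
            "n_input_columns": self.n_input_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_factors=int(d["n_factors"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            variable_mask=np.asarray(d["variable_mask"], dtype=int),
            n_input_columns=int(d["n_input_columns"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PressCurve:
    factors: np.ndarray  # 1..A_max
    press: np.ndarray
    rmsecv: np.ndarray
    chosen: int  # factor count attaining the minimum PRESS (ties -> fewest)


@dataclass
class ModelMetrics:
    rmsec: float
    rmsecv: float
    rmsep: float | None
    r2_cal: float
    r2_cv: float
    r2_pred: float | None
    n_cal: int
    n_val: int

    def to_dict(self) -> dict:
        return {
            "rmsec": self.rmsec,
            "rmsecv": self.rmsecv,
            "rmsep": self.rmsep,
            "r2_cal": self.r2_cal,
            "r2_cv": self.r2_cv,
            "r2_pred": self.r2_pred,
            "n_cal": self.n_cal,
            "n_val": self.n_val,
        }


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """NIPALS deflation on centered blocks; returns (W, P, q, T)."""
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    T = np.zeros((n, n_factors))
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # no covariance left; keep remaining factors inert
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pl = (X.T @ t) / tt
        ql = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - ql * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t
    return W, P, q, T


def pls_fit(
    X: np.ndarray,
    c: np.ndarray,
    n_factors: int,
    variable_mask: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS with mean-centering of X and c.

    ``variable_mask`` restricts the model to a subset of columns of ``X``
    (indices into the full axis); predictions then accept either full-width
    or pre-masked matrices.
    """
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    n, p_full = X.shape
    if variable_mask is None:
        mask = np.arange(p_full)
    else:
        mask = np.asarray(variable_mask, dtype=int)
        if mask.size == 0:
            raise ValueError("variable_mask is empty")
    Xm = X[:, mask]
    if c.size != n:
        raise ValueError("c length does not match X rows")
    if np.ptp(c) == 0:
        raise ValueError("c has zero variance; cannot calibrate")
    max_a = min(n - 1, Xm.shape[1])
    if not 1 <= n_factors <= max_a:
        raise ValueError(f"n_factors must be in [1, {max_a}], got {n_factors}")

    x_mean = Xm.mean(axis=0)
    y_mean = float(c.mean())
    W, P, q, T = _nipals(Xm - x_mean, c - y_mean, n_factors)
    # b = W (P'W)^{-1} q; pinv guards the degenerate case where NIPALS
    # exhausted the covariance before reaching n_factors
    PtW = P.T @ W
    try:
        b = W @ np.linalg.solve(PtW, q)
    except np.linalg.LinAlgError:
        b = W @ (np.linalg.pinv(PtW) @ q)
    return PLSModel(
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
        variable_mask=mask,
        n_input_columns=p_full,
        scores=T,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations: (X_masked - x_mean) @ b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p_masked = model.variable_mask.size
    if X.shape[1] == model.n_input_columns:
        Xm = X[:, model.variable_mask]
    elif X.shape[1] == p_masked:
        Xm = X
    else:
        raise ValueError(
            f"X has {X.shape[1]} columns; expected {model.n_input_columns} "
            f"(full) or {p_masked} (masked)"
        )
    return (Xm - model.x_mean) @ model.regression_vector + model.y_mean


def rmse(c: np.ndarray, c_hat: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum((c_i - chat_i)^2) / I)."""
    c = np.asarray(c, dtype=float).ravel()
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("rmse of empty input")
    if c.size != c_hat.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((c - c_hat) ** 2)))


def r_squared(c: np.ndarray, c_hat: np.ndarray) -> float:
    """1 - SSE/SST (not squared correlation)."""
    c = np.asarray(c, dtype=float).ravel()
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    if c.size != c_hat.size:
        raise ValueError("length mismatch")
    sst = float(np.sum((c - c.mean()) ** 2))
    if sst == 0:
        raise ValueError("c is constant; R^2 undefined")
    return 1.0 - float(np.sum((c - c_hat) ** 2)) / sst


def _factorwise_predictions(
    X_train: np.ndarray, y_train: np.ndarray, x_new: np.ndarray, A_max: int
) -> np.ndarray:
    """Predictions of one new sample for every factor count 1..A_max."""
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    W, P, q, _ = _nipals(X_train - x_mean, y_train - y_mean, A_max)
    x_res = x_new - x_mean
    preds = np.empty(A_max)
    acc = y_mean
    for a in range(A_max):
        t = float(x_res @ W[:, a])
        x_res = x_res - t * P[:, a]
        acc += t * q[a]
        preds[a] = acc
    return preds


def loo_cv(X: np.ndarray, c: np.ndarray, A_max: int) -> PressCurve:
    """Leave-one-out cross-validation PRESS/RMSECV for 1..A_max factors.

    Each fold refits the model (centering recomputed) on the remaining
    samples; ``RMSECV(A) = sqrt(PRESS(A) / n)``.
    """
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    n = X.shape[0]
    if not 1 <= A_max <= n - 2:
        raise ValueError(f"A_max must be in [1, {n - 2}] for n = {n}")
    residuals = np.empty((n, A_max))
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        preds = _factorwise_predictions(X[keep], c[keep], X[i], A_max)
        residuals[i] = c[i] - preds
        keep[i] = True
    press = np.sum(residuals**2, axis=0)
    rmsecv = np.sqrt(press / n)
    chosen = int(np.argmin(press)) + 1  # argmin -> first occurrence -> fewest factors
    return PressCurve(
        factors=np.arange(1, A_max + 1), press=press, rmsecv=rmsecv, chosen=chosen
    )


def evaluate(
    model: PLSModel,
    X_cal: np.ndarray,
    c_cal: np.ndarray,
    X_val: np.ndarray | None = None,
    c_val: np.ndarray | None = None,
) -> ModelMetrics:
    """RMSEC/RMSECV/RMSEP and the matching R^2 family for a fitted model."""
    c_cal = np.asarray(c_cal, dtype=float).ravel()
    pred_cal = pls_predict(model, X_cal)
    rmsec = rmse(c_cal, pred_cal)
    r2_cal = r_squared(c_cal, pred_cal)

    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    Xm = (
        X_cal[:, model.variable_mask]
        if X_cal.shape[1] == model.n_input_columns
        else X_cal
    )
    curve = loo_cv(Xm, c_cal, model.n_factors)
    rmsecv = float(curve.rmsecv[model.n_factors - 1])
    sst = float(np.sum((c_cal - c_cal.mean()) ** 2))
    r2_cv = 1.0 - float(curve.press[model.n_factors - 1]) / sst

    if X_val is None or c_val is None or len(np.atleast_1d(c_val)) == 0:
        rmsep = r2_pred = None
        n_val = 0
    else:
        c_val = np.asarray(c_val, dtype=float).ravel()
        pred_val = pls_predict(model, X_val)
        rmsep = rmse(c_val, pred_val)
        r2_pred = r_squared(c_val, pred_val)
        n_val = c_val.size
    return ModelMetrics(
        rmsec=rmsec,
        rmsecv=rmsecv,
        rmsep=rmsep,
        r2_cal=r2_cal,
        r2_cv=r2_cv,
        r2_pred=r2_pred,
        n_cal=c_cal.size,
        n_val=n_val,
    )
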