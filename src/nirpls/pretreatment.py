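"""Spectral pretreatment ladder as composable fit/apply transforms.

Row-wise transforms (Savitzky-Golay smoothing/derivatives, SNV, wavelet
denoising, unit-norm normalization) are stateless; MSC and OSC carry
calibration-set state (reference spectrum, orthogonal weight/loading
pairs) so that applying a fitted pipeline to new data never consults
new-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from nirpls import _wavelet

__all__ = [
    "PretreatmentSpec",
    "FittedPretreatment",
    "sg_filter",
    "snv",
    "msc_fit",
    "msc_apply",
    "osc_fit",
    "osc_apply",
    "wavelet_denoise",
    "normalize",
    "pipeline_fit",
    "pipeline_apply",
    "default_ladder",
]

METHODS = ("raw", "sg", "sg1d", "sg2d", "snv", "msc", "osc", "wds", "normalize")


@dataclass(frozen=True)
class PretreatmentSpec:
    """One stage of the ladder: a method name plus its parameters."""

    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown pretreatment method {self.method!r}")
        if self.method in ("sg", "sg1d", "sg2d"):
            window = self.params.get("window", 11)
            deriv = {"sg": self.params.get("deriv", 0), "sg1d": 1, "sg2d": 2}[
                self.method
            ]
            polyorder = self.params.get("polyorder", 3 if deriv == 2 else 2)
            if window % 2 == 0:
                raise ValueError(f"SG window must be odd, got {window}")
            if window < polyorder + 2:
                raise ValueError(
                    f"SG window {window} must be >= polyorder + 2 ({polyorder + 2})"
                )
            if deriv not in (0, 1, 2):
                raise ValueError(f"derivative order must be 0, 1 or 2, got {deriv}")
        if self.method == "osc" and self.params.get("n_components", 1) < 1:
            raise ValueError("OSC needs n_components >= 1")

    def resolved(self) -> dict[str, Any]:
        """Parameters with method defaults filled in."""
        p = dict(self.params)
        if self.method in ("sg", "sg1d", "sg2d"):
            p.setdefault("window", 11)
            p["deriv"] = {"sg": p.get("deriv", 0), "sg1d": 1, "sg2d": 2}[self.method]
            p.setdefault("polyorder", 3 if p["deriv"] == 2 else 2)
        elif self.method == "osc":
            p.setdefault("n_components", 1)
            p.setdefault("tol", 1e-6)
            p.setdefault("max_iter", 500)
        elif self.method == "wds":
            p.setdefault("wavelet", "db4")
            p.setdefault("level", None)
            p.setdefault("rule", "universal")
        return p


@dataclass
class FittedPretreatment:
    spec: PretreatmentSpec
    state: dict[str, Any] = field(default_factory=dict)
    n_cal: int = 0


# ---------------------------------------------------------------------------
# stateless row-wise transforms
# ---------------------------------------------------------------------------

def sg_filter(
    X: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int = 0,
    step_nm: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative per row.

    Derivatives are scaled by ``step_nm ** -deriv`` so results are
    grid-invariant; edges use a polynomial fit on the truncated window.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if deriv > polyorder:
        raise ValueError(f"deriv {deriv} must be <= polyorder {polyorder}")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=step_nm, axis=1, mode="interp",
    )


def snv(X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample sd 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= tol):
        bad = int(np.argmax(sd.ravel() <= tol))
        raise ValueError(f"near-constant spectrum at row {bad}; SNV undefined")
    return (X - mean) / sd


def normalize(X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Scale each row to unit Euclidean norm."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms <= tol):
        bad = int(np.argmax(norms.ravel() <= tol))
        raise ValueError(f"zero spectrum at row {bad}; cannot normalize")
    return X / norms


def wavelet_denoise(
    X: np.ndarray,
    wavelet: str = "db4",
    level: int | None = None,
    rule: str = "universal",
) -> np.ndarray:
    """Per-row wavelet shrinkage.

    Soft-thresholds all detail coefficients at the universal threshold
    ``sigma * sqrt(2 ln n)`` with sigma estimated per row from the median
    absolute deviation of the finest-scale details.
    """
    if rule != "universal":
        raise ValueError(f"unknown threshold rule {rule!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_points = X.shape[1]
    if level is None:
        level = max(1, int(np.floor(np.log2(n_points))) - 4)
    coeffs = _wavelet.dwt(X, wavelet, level)
    if len(coeffs) == 1:
        raise ValueError(f"level {level} yields no detail bands for n = {n_points}")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest), axis=1, keepdims=True) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n_points))
    shrunk = [coeffs[0]] + [
        np.sign(d) * np.maximum(np.abs(d) - thresh, 0.0) for d in coeffs[1:]
    ]
    return _wavelet.idwt(shrunk, wavelet, n_points)


# ---------------------------------------------------------------------------
# transforms with calibration state
# ---------------------------------------------------------------------------

def msc_fit(X_cal: np.ndarray, spec: PretreatmentSpec | None = None) -> FittedPretreatment:
    """Multiplicative scatter correction: store the calibration mean spectrum."""
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    if X_cal.shape[0] < 2:
        raise ValueError("MSC needs at least 2 calibration spectra")
    return FittedPretreatment(
        spec=spec or PretreatmentSpec("msc"),
        state={"reference": X_cal.mean(axis=0)},
        n_cal=X_cal.shape[0],
    )


def msc_apply(fitted: FittedPretreatment, X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Regress each row on the stored reference; return (row - intercept)/slope."""
    ref = fitted.state["reference"]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(slope) <= tol):
        bad = int(np.argmax(np.abs(slope) <= tol))
        raise ValueError(f"MSC slope vanishes at row {bad}")
    intercept = X.mean(axis=1) - slope * ref.mean()
    return (X - intercept[:, None]) / slope[:, None]


def osc_fit(
    X_cal: np.ndarray,
    c_cal: np.ndarray,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 500,
    spec: PretreatmentSpec | None = None,
) -> FittedPretreatment:
    """Orthogonal signal correction (Wold's iterative algorithm).

    Extracts score/loading pairs whose scores are orthogonalized against
    the centered response, deflates them from the calibration spectra and
    stores the weight/loading vectors for out-of-set application.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(c_cal, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("c_cal length does not match X_cal rows")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy <= 0:
        raise ValueError("c_cal has zero variance")

    components: list[dict[str, np.ndarray]] = []
    for _ in range(n_components):
        # start from the dominant principal direction
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        t = U[:, 0] * s[0]
        w = np.zeros(Xc.shape[1])
        converged = False
        last_change = np.inf
        for _ in range(max_iter):
            t_orth = t - yc * (float(yc @ t) / yy)
            w_new = Xc.T @ t_orth
            nw = np.linalg.norm(w_new)
            if nw < 1e-14:
                raise ValueError("OSC degenerated: weight vector vanished")
            w_new /= nw
            t_new = Xc @ w_new
            last_change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t, w = t_new, w_new
            if last_change < tol:
                converged = True
                break
        if not converged:
            raise ValueError(
                f"OSC did not converge in {max_iter} iterations "
                f"(last relative score change {last_change:.3e})"
            )
        # deflate with the exactly y-orthogonalized score; out-of-set
        # application reconstructs the score from the stored weights
        t_orth = t - yc * (float(yc @ t) / yy)
        p = Xc.T @ t_orth / float(t_orth @ t_orth)
        Xc = Xc - np.outer(t_orth, p)
        components.append({"weights": w, "loadings": p, "scores": t_orth})

    return FittedPretreatment(
        spec=spec or PretreatmentSpec("osc", {"n_components": n_components}),
        state={
            "x_mean": x_mean,
            "components": components,
            # exactly-deflated calibration spectra: the y-covariance of every
            # column is preserved here, unlike the weight-based apply path
            "calibration_corrected": Xc + x_mean,
        },
        n_cal=X.shape[0],
    )


def osc_apply(fitted: FittedPretreatment, X: np.ndarray) -> np.ndarray:
    """Remove the stored orthogonal components from (new) spectra."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x_mean = fitted.state["x_mean"]
    Xc = X - x_mean
    for comp in fitted.state["components"]:
        t = Xc @ comp["weights"]
        Xc = Xc - np.outer(t, comp["loadings"])
    return Xc + x_mean


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

def _fit_one(
    spec: PretreatmentSpec,
    X: np.ndarray,
    c: np.ndarray | None,
    step_nm: float,
) -> tuple[FittedPretreatment, np.ndarray]:
    p = spec.resolved()
    if spec.method == "raw":
        return FittedPretreatment(spec, {}, X.shape[0]), X
    if spec.method in ("sg", "sg1d", "sg2d"):
        out = sg_filter(X, p["window"], p["polyorder"], p["deriv"], step_nm)
        return FittedPretreatment(spec, {}, X.shape[0]), out
    if spec.method == "snv":
        return FittedPretreatment(spec, {}, X.shape[0]), snv(X)
    if spec.method == "normalize":
        return FittedPretreatment(spec, {}, X.shape[0]), normalize(X)
    if spec.method == "wds":
        out = wavelet_denoise(X, p["wavelet"], p["level"], p["rule"])
        return FittedPretreatment(spec, {}, X.shape[0]), out
    if spec.method == "msc":
        fitted = msc_fit(X, spec)
        return fitted, msc_apply(fitted, X)
    if spec.method == "osc":
        if c is None:
            raise ValueError("OSC requires calibration concentrations")
        fitted = osc_fit(X, c, p["n_components"], p["tol"], p["max_iter"], spec)
        return fitted, fitted.state["calibration_corrected"]
    raise ValueError(f"unknown method {spec.method!r}")  # pragma: no cover


def _apply_one(fitted: FittedPretreatment, X: np.ndarray, step_nm: float) -> np.ndarray:
    spec, p = fitted.spec, fitted.spec.resolved()
    if spec.method == "raw":
        return np.atleast_2d(np.asarray(X, dtype=float))
    if spec.method in ("sg", "sg1d", "sg2d"):
        return sg_filter(X, p["window"], p["polyorder"], p["deriv"], step_nm)
    if spec.method == "snv":
        return snv(X)
    if spec.method == "normalize":
        return normalize(X)
    if spec.method == "wds":
        return wavelet_denoise(X, p["wavelet"], p["level"], p["rule"])
    if spec.method == "msc":
        return msc_apply(fitted, X)
    if spec.method == "osc":
        return osc_apply(fitted, X)
    raise ValueError(f"unknown method {spec.method!r}")  # pragma: no cover


def pipeline_fit(
    specs: list[PretreatmentSpec],
    X_cal: np.ndarray,
    c_cal: np.ndarray | None = None,
    step_nm: float = 1.0,
) -> tuple[list[FittedPretreatment], np.ndarray]:
    """Fit stages left-to-right on calibration data; each stage consumes
    the previous stage's output.  Returns the fitted stages and the fully
    pretreated calibration matrix."""
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    fitted: list[FittedPretreatment] = []
    for spec in specs:
        f, X = _fit_one(spec, X, c_cal, step_nm)
        fitted.append(f)
    return fitted, X


def pipeline_apply(
    fitted: list[FittedPretreatment], X: np.ndarray, step_nm: float = 1.0
) -> np.ndarray:
    """Replay a fitted pipeline on new spectra using only stored state."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    for f in fitted:
        X = _apply_one(f, X, step_nm)
    return X


def default_ladder() -> list[tuple[str, list[PretreatmentSpec]]]:
    """The comparison ladder of candidate pretreatments, simplest first."""
    return [
        ("raw", [PretreatmentSpec("raw")]),
        ("sg9", [PretreatmentSpec("sg", {"window": 9})]),
        ("sg11", [PretreatmentSpec("sg", {"window": 11})]),
        ("sg11+1d", [PretreatmentSpec("sg1d", {"window": 11})]),
        ("sg11+2d", [PretreatmentSpec("sg2d", {"window": 11})]),
        ("snv", [PretreatmentSpec("snv")]),
        ("msc", [PretreatmentSpec("msc")]),
        ("osc1", [PretreatmentSpec("osc", {"n_components": 1})]),
        ("wds", [PretreatmentSpec("wds")]),
        ("normalize", [PretreatmentSpec("normalize")]),
    ]
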