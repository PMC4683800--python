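"""Minimal periodized orthogonal discrete wavelet transform.

Only what soft-threshold denoising of spectra needs: analysis/synthesis
with orthonormal Daubechies filters under circular boundary handling.
With an orthonormal filter bank the periodized analysis operator is
orthogonal, so synthesis is its exact transpose and round-trips are
lossless to machine precision.  Decomposition stops early when a level's
length turns odd or drops below the filter length.
"""

from __future__ import annotations

import numpy as np

# orthonormal scaling (low-pass) filters; wavelet filter derived by QMF
_SCALING_FILTERS: dict[str, list[float]] = {
    "haar": [0.7071067811865476, 0.7071067811865476],
    "db2": [
        0.48296291314469025,
        0.836516303737469,
        0.22414386804185735,
        -0.12940952255092145,
    ],
    "db4": [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ],
}
_SCALING_FILTERS["db1"] = _SCALING_FILTERS["haar"]


def filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        h = np.asarray(_SCALING_FILTERS[wavelet], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown wavelet {wavelet!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None
    L = h.size
    g = ((-1.0) ** np.arange(L)) * h[::-1]
    return h, g


def _analysis_index(n: int, L: int) -> np.ndarray:
    return (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n


def dwt(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Multi-level periodized DWT of each row.

    Returns ``[a_J, d_J, d_{J-1}, ..., d_1]`` (coarse first), where the
    realized depth J may be smaller than ``level`` if lengths turn odd.
    """
    h, g = filters(wavelet)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    approx = X
    details: list[np.ndarray] = []
    for _ in range(level):
        n = approx.shape[1]
        if n % 2 != 0 or n < h.size:
            break
        idx = _analysis_index(n, h.size)
        windows = approx[:, idx]  # (rows, n/2, L)
        details.append(windows @ g)
        approx = windows @ h
    return [approx] + details[::-1]


def idwt(coeffs: list[np.ndarray], wavelet: str, n_points: int) -> np.ndarray:
    """Inverse of :func:`dwt` (exact transpose reconstruction)."""
    h, g = filters(wavelet)
    L = h.size
    approx = coeffs[0]
    for d in coeffs[1:]:
        n = 2 * approx.shape[1]
        idx = _analysis_index(n, L)
        rows = approx.shape[0]
        out = np.zeros((rows, n))
        contrib = approx[:, :, None] * h[None, None, :] + d[:, :, None] * g[None, None, :]
        np.add.at(
            out,
            (np.arange(rows)[:, None, None], idx[None, :, :]),
            contrib,
        )
        approx = out
    if approx.shape[1] != n_points:
        raise ValueError(
            f"reconstructed length {approx.shape[1]} != expected {n_points}"
        )
    return approx
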