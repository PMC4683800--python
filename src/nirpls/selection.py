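"""Wavelength-region selection: moving-window PLS scanning and
synergy-interval PLS exhaustive combination search.

Both searches score candidate variable subsets by leave-one-out RMSECV
with PRESS-selected factor counts, and report regions in nm through the
single-sourced grid arithmetic of :mod:`nirpls.data_model`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from nirpls.data_model import WavelengthGrid, interval_slices, make_grid, subinterval_bounds
from nirpls.pls import PLSModel, loo_cv, pls_fit

__all__ = [
    "WindowScanResult",
    "MwplsVerdict",
    "IntervalCombinationResult",
    "thin_spectra",
    "intervals_to_mask",
    "mwpls_scan",
    "mwpls_verdict",
    "sipls_search",
    "build_final_model",
]


@dataclass
class WindowScanResult:
    window_size: int  # H
    centers: np.ndarray  # center variable index per window position
    rmsecv: np.ndarray  # (n_windows, A_max)
    best_window: dict  # center index, H, n_factors, rmsecv
    full_spectrum_rmsecv: float


@dataclass
class MwplsVerdict:
    appropriate: bool
    best_window: dict | None
    benchmark: float
    message: str


@dataclass
class IntervalCombinationResult:
    n_intervals: int
    k: int
    ranking: list[tuple[tuple[int, ...], int, float]]  # (1-based set, factors, rmsecv)
    best: dict  # intervals, n_factors, rmsecv, nm_ranges
    grid: WavelengthGrid | None = None


def thin_spectra(
    X: np.ndarray, grid: WavelengthGrid, factor: int
) -> tuple[np.ndarray, WavelengthGrid]:
    """Average ``factor`` adjacent points per variable (fast mode for the
    combinatorial searches).  Requires the point count to divide evenly."""
    if factor == 1:
        return np.asarray(X, dtype=float), grid
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p % factor != 0:
        raise ValueError(f"{p} variables not divisible by thinning factor {factor}")
    X2 = X.reshape(n, p // factor, factor).mean(axis=2)
    grid2 = make_grid(grid.start_nm, grid.stop_nm, grid.step_nm * factor)
    return X2, grid2


def intervals_to_mask(
    grid: WavelengthGrid, n_intervals: int, intervals: tuple[int, ...]
) -> np.ndarray:
    """Variable-index mask for a union of 1-based equidistant subintervals."""
    slices = interval_slices(grid, n_intervals)
    parts = []
    for i in sorted(intervals):
        if not 1 <= i <= n_intervals:
            raise ValueError(f"interval index {i} out of range 1..{n_intervals}")
        parts.append(np.arange(slices[i - 1].start, slices[i - 1].stop))
    return np.concatenate(parts)


def _benchmark(X: np.ndarray, c: np.ndarray, A_max: int) -> float:
    n = X.shape[0]
    curve = loo_cv(X, c, min(A_max, n - 2))
    return float(curve.rmsecv[curve.chosen - 1])


def mwpls_scan(
    X: np.ndarray,
    c: np.ndarray,
    H_values: tuple[int, ...] | None = None,
    A_max: int = 10,
    step: int = 1,
    benchmark: float | None = None,
) -> list[WindowScanResult]:
    """Scan contiguous windows of each size H across the variable axis.

    For every window position a PLS model is cross-validated for factor
    counts 1..A_max; the per-H result records the RMSECV surface and the
    window/factor pair attaining its minimum.  ``step`` strides the window
    start (1 = the exhaustive scan).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    n, p = X.shape
    if H_values is None:
        H_values = tuple(range(13, 42, 2))
    if benchmark is None:
        benchmark = _benchmark(X, c, A_max)
    results = []
    for H in H_values:
        if H > p:
            raise ValueError(f"window size {H} exceeds {p} variables")
        starts = np.arange(0, p - H + 1, step)
        a_cap = min(A_max, H - 1, n - 2)
        surface = np.full((starts.size, a_cap), np.inf)
        for w, s in enumerate(starts):
            curve = loo_cv(X[:, s : s + H], c, a_cap)
            surface[w] = curve.rmsecv
        flat = int(np.argmin(surface))  # row-major: lowest window, then fewest factors
        w_best, a_best = divmod(flat, a_cap)
        results.append(
            WindowScanResult(
                window_size=H,
                centers=starts + H // 2,
                rmsecv=surface,
                best_window={
                    "center_index": int(starts[w_best] + H // 2),
                    "start_index": int(starts[w_best]),
                    "H": H,
                    "n_factors": a_best + 1,
                    "rmsecv": float(surface[w_best, a_best]),
                },
                full_spectrum_rmsecv=benchmark,
            )
        )
    return results


def mwpls_verdict(
    results: list[WindowScanResult], benchmark: float | None = None
) -> MwplsVerdict:
    """Accept the best window only if it beats the full-spectrum RMSECV
    strictly; otherwise declare moving-window selection inappropriate."""
    if not results:
        raise ValueError("no scan results")
    if benchmark is None:
        benchmark = results[0].full_spectrum_rmsecv
    best = min(results, key=lambda r: r.best_window["rmsecv"]).best_window
    if best["rmsecv"] < benchmark:
        return MwplsVerdict(
            appropriate=True,
            best_window=best,
            benchmark=benchmark,
            message=(
                f"window H={best['H']} at variable {best['center_index']} beats "
                f"full spectrum ({best['rmsecv']:.6g} < {benchmark:.6g})"
            ),
        )
    return MwplsVerdict(
        appropriate=False,
        best_window=None,
        benchmark=benchmark,
        message=(
            "inappropriate: no window achieves an RMSECV below the "
            f"full-spectrum value {benchmark:.6g}"
        ),
    )


def sipls_search(
    X: np.ndarray,
    c: np.ndarray,
    grid: WavelengthGrid,
    n_intervals: int = 20,
    k: int = 3,
    A_max: int = 10,
) -> IntervalCombinationResult:
    """Exhaustive synergy-interval search over all C(n_intervals, k)
    combinations of equidistant subintervals.

    Each combination concatenates its interval columns, selects the factor
    count by lowest leave-one-out PRESS (capped at ``A_max`` and the
    combination's variable count minus one) and is ranked by RMSECV,
    ties toward the lexicographically smaller index set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    if k > n_intervals:
        raise ValueError(f"k={k} exceeds n_intervals={n_intervals}")
    if X.shape[1] != grid.n_points:
        raise ValueError("X column count does not match grid")
    slices = interval_slices(grid, n_intervals)
    n = X.shape[0]
    ranking: list[tuple[tuple[int, ...], int, float]] = []
    for combo in itertools.combinations(range(1, n_intervals + 1), k):
        cols = np.concatenate([np.arange(slices[i - 1].start, slices[i - 1].stop) for i in combo])
        a_cap = min(A_max, cols.size - 1, n - 2)
        curve = loo_cv(X[:, cols], c, a_cap)
        ranking.append(
            (combo, curve.chosen, float(curve.rmsecv[curve.chosen - 1]))
        )
    ranking.sort(key=lambda r: (r[2], r[0], r[1]))
    best_combo, best_a, best_rmsecv = ranking[0]
    best = {
        "intervals": best_combo,
        "n_factors": best_a,
        "rmsecv": best_rmsecv,
        "nm_ranges": [subinterval_bounds(i, n_intervals, grid) for i in best_combo],
    }
    return IntervalCombinationResult(
        n_intervals=n_intervals, k=k, ranking=ranking, best=best, grid=grid
    )


def build_final_model(
    X_cal: np.ndarray,
    c_cal: np.ndarray,
    selection,
    n_factors: int,
    grid: WavelengthGrid | None = None,
    n_intervals: int | None = None,
) -> PLSModel:
    """Fit the masked PLS model for a chosen selection.

    ``selection`` is either an explicit variable-index array or an iterable
    of 1-based interval indices (then ``grid`` and ``n_intervals`` are
    required).
    """
    sel = np.asarray(list(selection) if not isinstance(selection, np.ndarray) else selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    if grid is not None and n_intervals is not None:
        mask = intervals_to_mask(grid, n_intervals, tuple(int(i) for i in sel))
    else:
        mask = sel.astype(int)
    return pls_fit(X_cal, c_cal, n_factors, variable_mask=mask)
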