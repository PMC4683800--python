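"""Core data types, wavelength-grid arithmetic and delimited-text I/O.

The wavelength grid follows a half-open convention ``[start_nm, stop_nm)``:
an 800-2200 nm span at a 0.5 nm increment therefore contains exactly 2800
variables (a closed grid would contain 2801).  Equidistant subinterval
arithmetic is single-sourced here so that interval reports in nm always
agree with the point slices used for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ANALYTES = (
    "glycyrrhizic_acid",
    "liquiritin",
    "isoliquiritin",
    "total_flavonoids",
)

#: metadata columns preceding the spectral block in wide-format tables
_META_COLS = ("sample_id", "phase", "time_min", "temperature_c")

_VALID_PHASES = frozenset({1, 2, 3})


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis under the half-open convention [start, stop)."""

    start_nm: float
    stop_nm: float
    step_nm: float
    n_points: int

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def wavelength(self, index: int) -> float:
        if not 0 <= index < self.n_points:
            raise IndexError(f"grid index {index} out of range [0, {self.n_points})")
        return self.start_nm + index * self.step_nm

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform half-open wavelength grid.

    Parameters
    ----------
    start_nm, stop_nm : float
        Span in nm; ``stop_nm`` is exclusive.
    step_nm : float
        Increment in nm; must divide the span exactly.

    Returns
    -------
    WavelengthGrid
        Grid with ``n_points = (stop_nm - start_nm) / step_nm``; the
        wavelength of 0-based index ``j`` is ``start_nm + j * step_nm``.
    """
    if stop_nm <= start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    span = stop_nm - start_nm
    ratio = span / step_nm
    n_points = int(round(ratio))
    remainder = span - n_points * step_nm
    if n_points < 1 or abs(remainder) > 1e-9 * max(1.0, abs(span)):
        raise ValueError(
            f"step_nm={step_nm} does not divide span {span} nm "
            f"(remainder {span - np.floor(ratio) * step_nm:g} nm)"
        )
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), n_points)


def interval_slices(grid: WavelengthGrid, n_intervals: int) -> list[slice]:
    """Partition grid point indices into ``n_intervals`` equidistant slices.

    When ``n_points`` is not divisible by ``n_intervals``, trailing intervals
    absorb one extra point each (rightmost-first), keeping widths within one
    point of equal.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if n_intervals > grid.n_points:
        raise ValueError(
            f"cannot split {grid.n_points} points into {n_intervals} intervals"
        )
    base, extra = divmod(grid.n_points, n_intervals)
    sizes = [base] * n_intervals
    for i in range(extra):
        sizes[n_intervals - 1 - i] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(n_intervals)]


def subinterval_bounds(
    index: int, n_intervals: int, grid: WavelengthGrid
) -> tuple[float, float]:
    """Wavelength range in nm of the ``index``-th (1-based) equidistant subinterval.

    Under the half-open convention interval ``i`` spans
    ``[start + (i-1)*w, start + i*w)`` with ``w = span / n_intervals``
    whenever the point count divides evenly; otherwise bounds follow the
    rightmost-first remainder policy of :func:`interval_slices`.
    """
    if not 1 <= index <= n_intervals:
        raise ValueError(f"interval index {index} out of range 1..{n_intervals}")
    sl = interval_slices(grid, n_intervals)[index - 1]
    lo = grid.start_nm + sl.start * grid.step_nm
    hi = grid.start_nm + sl.stop * grid.step_nm
    return (lo, hi)


@dataclass
class SpectralDataset:
    """Absorbance matrix bound to a wavelength grid and per-sample metadata."""

    grid: WavelengthGrid
    absorbance: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str]
    phase: np.ndarray  # int, in {1, 2, 3}
    time_min: np.ndarray
    temperature_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.phase = np.asarray(self.phase, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.temperature_c is not None:
            self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        n, p = self.absorbance.shape
        if p != self.grid.n_points:
            raise ValueError(
                f"absorbance has {p} columns but grid declares {self.grid.n_points} points"
            )
        if not (len(self.sample_ids) == len(self.phase) == len(self.time_min) == n):
            raise ValueError("metadata length does not match number of spectra")
        bad = set(np.unique(self.phase)) - _VALID_PHASES
        if bad:
            raise ValueError(f"unknown extraction phase labels: {sorted(bad)}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        idx = list(indices)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            phase=self.phase[idx],
            time_min=self.time_min[idx],
            temperature_c=None if self.temperature_c is None else self.temperature_c[idx],
        )


@dataclass
class ReferenceTable:
    """Per-sample analyte concentrations in mg/mL (long format, NaN = missing)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "analyte", "concentration_mg_per_ml"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table lacks columns: {sorted(missing)}")
        conc = self.table["concentration_mg_per_ml"]
        if (conc.dropna() < 0).any():
            bad = self.table.loc[conc < 0, "sample_id"].tolist()
            raise ValueError(f"negative concentrations for samples {bad}")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.table["analyte"].unique())

    def concentrations(self, analyte: str) -> pd.Series:
        sub = self.table[self.table["analyte"] == analyte]
        if sub.empty:
            raise KeyError(f"analyte {analyte!r} not present in reference table")
        return sub.set_index("sample_id")["concentration_mg_per_ml"]


# ---------------------------------------------------------------------------
# delimited-text I/O (UTF-8, comma-delimited, '.' decimal, NA for missing)
# ---------------------------------------------------------------------------

def write_spectra(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a wide-format spectral table: metadata columns then one column
    per wavelength, values at 12 significant digits."""
    wl = dataset.grid.wavelengths
    cols = {
        "sample_id": dataset.sample_ids,
        "phase": dataset.phase,
        "time_min": dataset.time_min,
        "temperature_c": (
            dataset.temperature_c
            if dataset.temperature_c is not None
            else [np.nan] * dataset.n_samples
        ),
    }
    frame = pd.DataFrame(cols)
    spec = pd.DataFrame(dataset.absorbance, columns=[f"{w:.10g}" for w in wl])
    pd.concat([frame, spec], axis=1).to_csv(
        path, index=False, float_format="%.12g", na_rep="NA"
    )


def read_spectra(path: str | Path) -> SpectralDataset:
    """Read a wide-format spectral table written by :func:`write_spectra`.

    The wavelength header is validated as strictly increasing and uniform;
    the grid is inferred under the half-open convention.
    """
    frame = pd.read_csv(path, na_values=["NA"])
    for col in _META_COLS:
        if col not in frame.columns:
            raise ValueError(f"spectral table missing metadata column {col!r}")
    spec_cols = [c for c in frame.columns if c not in _META_COLS]
    if len(spec_cols) < 2:
        raise ValueError("spectral table holds fewer than 2 wavelength columns")
    try:
        wl = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column header: {exc}") from exc
    dif = np.diff(wl)
    if np.any(dif <= 0):
        j = int(np.argmax(dif <= 0))
        raise ValueError(
            f"wavelengths not strictly increasing at column {spec_cols[j + 1]!r}"
        )
    step = dif[0]
    if not np.allclose(dif, step, rtol=0, atol=1e-6 * step):
        j = int(np.argmax(np.abs(dif - step) > 1e-6 * step))
        raise ValueError(f"non-uniform wavelength spacing near column {spec_cols[j]!r}")
    grid = make_grid(wl[0], wl[0] + step * len(wl), step)
    absorb = frame[spec_cols].to_numpy(dtype=float)
    if np.isnan(absorb).any():
        row = int(np.argmax(np.isnan(absorb).any(axis=1)))
        raise ValueError(f"missing/ragged absorbance values in row {row}")
    phase_raw = frame["phase"]
    try:
        phase = phase_raw.astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer phase label: {exc}") from exc
    temp = frame["temperature_c"].to_numpy(dtype=float)
    return SpectralDataset(
        grid=grid,
        absorbance=absorb,
        sample_ids=frame["sample_id"].astype(str).tolist(),
        phase=phase,
        time_min=frame["time_min"].to_numpy(dtype=float),
        temperature_c=None if np.isnan(temp).all() else temp,
    )


def write_references(refs: ReferenceTable, path: str | Path) -> None:
    refs.table.to_csv(path, index=False, float_format="%.12g", na_rep="NA")


def read_references(path: str | Path) -> ReferenceTable:
    frame = pd.read_csv(path, na_values=["NA"])
    frame["sample_id"] = frame["sample_id"].astype(str)
    return ReferenceTable(frame)


def align(
    dataset: SpectralDataset, refs: ReferenceTable, analyte: str
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Pair spectra with reference concentrations for one analyte.

    Returns ``(X, c, kept_ids, dropped_ids)`` restricted to samples that have
    a present reference value, preserving the dataset's row order.
    """
    conc = refs.concentrations(analyte)
    keep_idx: list[int] = []
    dropped: list[str] = []
    for i, sid in enumerate(dataset.sample_ids):
        if sid in conc.index and not np.isnan(conc.loc[sid]):
            keep_idx.append(i)
        else:
            dropped.append(sid)
    if not keep_idx:
        raise ValueError(
            f"no overlap between dataset sample ids and references for {analyte!r}"
        )
    kept_ids = [dataset.sample_ids[i] for i in keep_idx]
    X = dataset.absorbance[keep_idx]
    c = conc.loc[kept_ids].to_numpy(dtype=float)
    return X, c, kept_ids, dropped
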