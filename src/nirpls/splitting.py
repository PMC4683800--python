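"""Kennard-Stone calibration/validation sample-set partitioning."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SplitResult", "ks_split", "save_split", "load_split"]


@dataclass
class SplitResult:
    calibration_ids: list[str]
    validation_ids: list[str]
    selection_order: list[int]  # row indices in the order they were picked

    def save(self, path: str | Path) -> None:
        save_split(self, path)


def _resolve_n_cal(n_cal: int | float, n_samples: int) -> int:
    if isinstance(n_cal, float) and 0 < n_cal < 1:
        # fraction -> count, round half up
        n_cal = int(np.floor(n_cal * n_samples + 0.5))
    n_cal = int(n_cal)
    if not 2 <= n_cal < n_samples:
        raise ValueError(
            f"n_cal must satisfy 2 <= n_cal < n_samples, got {n_cal} of {n_samples}"
        )
    return n_cal


def ks_split(
    X: np.ndarray,
    n_cal: int | float,
    sample_ids: Sequence[str] | None = None,
) -> SplitResult:
    """Kennard-Stone max-min-distance partition.

    The first two calibration samples are the pair at maximal Euclidean
    distance; every subsequent pick maximizes the minimum distance to the
    already-selected set.  Ties are broken toward the lowest original row
    index, making the procedure deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    elif len(sample_ids) != n:
        raise ValueError("sample_ids length does not match X rows")
    k = _resolve_n_cal(n_cal, n)

    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    # seed pair: maximal distance, lexicographically smallest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = d2[iu]
    best = int(np.argmax(flat))  # argmax returns first occurrence = lexicographic
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    order = [i0, j0]
    selected = np.zeros(n, dtype=bool)
    selected[[i0, j0]] = True
    min_d2 = np.minimum(d2[i0], d2[j0])

    while len(order) < k:
        cand = np.where(~selected)[0]
        pick = int(cand[np.argmax(min_d2[cand])])  # first occurrence = lowest index
        order.append(pick)
        selected[pick] = True
        np.minimum(min_d2, d2[pick], out=min_d2)

    cal_idx = sorted(order)
    val_idx = [i for i in range(n) if not selected[i]]
    return SplitResult(
        calibration_ids=[sample_ids[i] for i in cal_idx],
        validation_ids=[sample_ids[i] for i in val_idx],
        selection_order=order,
    )


def save_split(split: SplitResult, path: str | Path) -> None:
    rows = [(sid, "calibration") for sid in split.calibration_ids] + [
        (sid, "validation") for sid in split.validation_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "role"]).to_csv(path, index=False)


def load_split(path: str | Path) -> SplitResult:
    frame = pd.read_csv(path)
    cal = frame.loc[frame["role"] == "calibration", "sample_id"].astype(str).tolist()
    val = frame.loc[frame["role"] == "validation", "sample_id"].astype(str).tolist()
    return SplitResult(calibration_ids=cal, validation_ids=val, selection_order=[])
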