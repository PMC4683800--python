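"""Phase-wise model assessment: relative errors, F test, detection limit.

Relative error is |predicted - reference| / reference * 100.  Phase means
retain full precision internally and are displayed at two decimals with
round-half-up.  Model-vs-reference agreement is tested with the regression
F statistic of predicted on reference at df (1, n - 2).  The multivariate
detection limit uses the pseudounivariate variant: the prediction standard
error of the predicted-vs-reference regression extrapolated to zero
concentration, scaled by Delta(alpha, beta) ~ 3.30 and divided by the
regression slope.

A published per-sample relative-error benchmark table (three extraction
phases x four analytes, NA = sample unavailable in that phase) ships with
the package for validation of the phase-mean arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nirpls.pls import PLSModel, pls_predict

__all__ = [
    "PhaseAssessment",
    "FTestResult",
    "MDLResult",
    "relative_error",
    "phase_mean",
    "display_round",
    "assess_phases",
    "f_test",
    "critical_f",
    "mdl_estimate",
    "build_report",
    "load_published_phase_errors",
]

#: Delta(alpha=0.05, beta=0.05) for the detection decision, ~ z_a + z_b
DELTA_0505 = 3.30


@dataclass
class PhaseAssessment:
    analyte: str
    per_sample: list[dict]  # sample_id, phase, reference, predicted, rel_error_pct
    phase_means: dict[int, float]  # full precision
    excluded: list[str]  # ids lacking a reference value

    def phase_means_display(self) -> dict[int, float]:
        return {p: display_round(v) for p, v in self.phase_means.items()}


@dataclass
class FTestResult:
    f_statistic: float
    df: tuple[int, int]
    critical_value: float
    alpha: float
    significant: bool


@dataclass
class MDLResult:
    mdl_mg_per_ml: float
    mdl_ppm: float  # assumes extract density 1 g/mL: 1 mg/mL = 1000 ppm
    method: str
    inputs: dict = field(default_factory=dict)


def relative_error(reference: float, predicted: float) -> float:
    """|predicted - reference| / reference * 100 (percent)."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return abs(predicted - reference) / reference * 100.0


def phase_mean(errors: Sequence[float | None]) -> float:
    """Arithmetic mean of the present (non-missing) relative errors."""
    present = [
        float(e)
        for e in errors
        if e is not None and not (isinstance(e, float) and np.isnan(e))
    ]
    if not present:
        raise ValueError("no present values to average")
    return float(np.mean(present))


def display_round(x: float, ndigits: int = 2) -> float:
    """Round half up at ``ndigits`` decimals (table display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def assess_phases(
    analyte: str,
    sample_ids: Sequence[str],
    phases: Sequence[int],
    reference: Sequence[float],
    predicted: Sequence[float],
) -> PhaseAssessment:
    """Per-sample relative errors and per-phase means; samples with a
    missing reference are excluded from both."""
    per_sample = []
    excluded = []
    by_phase: dict[int, list[float]] = {}
    for sid, ph, ref, pred in zip(sample_ids, phases, reference, predicted):
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            excluded.append(sid)
            continue
        err = relative_error(float(ref), float(pred))
        per_sample.append(
            {
                "sample_id": sid,
                "phase": int(ph),
                "reference": float(ref),
                "predicted": float(pred),
                "rel_error_pct": err,
            }
        )
        by_phase.setdefault(int(ph), []).append(err)
    if not per_sample:
        raise ValueError(f"no assessable samples for {analyte}")
    means = {ph: phase_mean(v) for ph, v in sorted(by_phase.items())}
    return PhaseAssessment(
        analyte=analyte, per_sample=per_sample, phase_means=means, excluded=excluded
    )


def critical_f(alpha: float, df: tuple[int, int]) -> float:
    """Upper-tail F quantile at significance level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    dfn, dfd = df
    if dfn < 1 or dfd < 1:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return float(stats.f.isf(alpha, dfn, dfd))


def f_test(
    predicted: np.ndarray, reference: np.ndarray, alpha: float = 0.01
) -> FTestResult:
    """Regression F statistic of predicted on reference, df (1, n - 2)."""
    pred = np.asarray(predicted, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    n = ref.size
    if n < 3:
        raise ValueError("F test needs at least 3 samples")
    if pred.size != n:
        raise ValueError("length mismatch")
    sxx = float(np.sum((ref - ref.mean()) ** 2))
    if sxx == 0:
        raise ValueError("reference values have zero variance")
    sxy = float(np.sum((ref - ref.mean()) * (pred - pred.mean())))
    slope = sxy / sxx
    ssr = slope * sxy
    sse = float(np.sum((pred - pred.mean()) ** 2)) - ssr
    df = (1, n - 2)
    crit = critical_f(alpha, df)
    if sse <= 0 or sse < 1e-14 * ssr:
        f_stat = np.inf
    else:
        f_stat = ssr / (sse / (n - 2))
    return FTestResult(
        f_statistic=float(f_stat),
        df=df,
        critical_value=crit,
        alpha=alpha,
        significant=bool(f_stat > crit),
    )


def mdl_estimate(
    model: PLSModel,
    X_cal: np.ndarray,
    c_cal: np.ndarray,
    delta: float = DELTA_0505,
) -> MDLResult:
    """Pseudounivariate multivariate detection limit.

    Regresses calibration predictions on reference concentrations; the MDL
    is ``delta * s0 / slope`` with ``s0`` the prediction standard error at
    zero concentration.
    """
    c = np.asarray(c_cal, dtype=float).ravel()
    pred = pls_predict(model, X_cal)
    n = c.size
    if n < 3:
        raise ValueError("MDL estimation needs at least 3 calibration samples")
    sxx = float(np.sum((c - c.mean()) ** 2))
    sxy = float(np.sum((c - c.mean()) * (pred - pred.mean())))
    slope = sxy / sxx
    if slope <= 0:
        raise ValueError(f"predicted-vs-reference slope must be > 0, got {slope:g}")
    intercept = pred.mean() - slope * c.mean()
    resid = pred - (intercept + slope * c)
    s_res = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    s0 = s_res * float(np.sqrt(1.0 + 1.0 / n + c.mean() ** 2 / sxx))
    mdl = delta * s0 / slope
    return MDLResult(
        mdl_mg_per_ml=mdl,
        mdl_ppm=mdl * 1000.0,
        method="pseudounivariate (prediction SE at zero concentration)",
        inputs={
            "slope": slope,
            "intercept": intercept,
            "s_residual": s_res,
            "s0": s0,
            "delta": delta,
            "n": n,
        },
    )


def load_published_phase_errors() -> pd.DataFrame:
    """Published per-sample relative-error benchmark table (percent), wide
    format with NA for samples absent in a phase."""
    with resources.files("nirpls.data").joinpath(
        "published_phase_relative_errors.csv"
    ).open() as fh:
        return pd.read_csv(fh, na_values=["NA"])


def build_report(
    analyte_sections: dict[str, dict],
    config_echo: dict | None = None,
) -> dict:
    """Assemble the machine-readable run report.

    ``analyte_sections`` maps analyte name to a dict that may contain
    ``pretreatment_metrics`` (ladder comparison), ``selected_pretreatment``,
    ``mwpls``, ``sipls``, ``final_metrics``, ``phase_assessment``,
    ``f_test`` and ``mdl`` entries.  The output is JSON-serializable and
    deterministic for identical inputs.
    """
    report: dict = {"schema_version": 1, "analytes": {}}
    if config_echo is not None:
        report["config"] = config_echo
    for analyte, section in sorted(analyte_sections.items()):
        out: dict = {}
        for key, value in section.items():
            out[key] = _jsonable(value)
        report["analytes"][analyte] = out
    return report


def _jsonable(value):
    if isinstance(value, PhaseAssessment):
        return {
            "analyte": value.analyte,
            "per_sample": value.per_sample,
            "phase_means": {str(k): v for k, v in value.phase_means.items()},
            "phase_means_display": {
                str(k): v for k, v in value.phase_means_display().items()
            },
            "excluded": value.excluded,
        }
    if isinstance(value, FTestResult):
        return {
            "f_statistic": value.f_statistic,
            "df": list(value.df),
            "critical_value": value.critical_value,
            "alpha": value.alpha,
            "significant": value.significant,
        }
    if isinstance(value, MDLResult):
        return {
            "mdl_mg_per_ml": value.mdl_mg_per_ml,
            "mdl_ppm": value.mdl_ppm,
            "method": value.method,
            "inputs": value.inputs,
        }
    if hasattr(value, "to_dict"):
        return value.to_dict()
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if value is None or isinstance(value, (str, int, float, bool)):
        return value
    return str(value)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
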