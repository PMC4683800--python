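"""Synthetic extraction-process NIR dataset generator.

Builds Beer-Lambert mixture spectra for a multi-phase batch extraction:
Gaussian pure-component bands scaled by first-order extraction kinetics,
a dominant water band near 1950 nm, temperature-coupled baseline drift,
per-spectrum multiplicative/additive scatter, and heteroscedastic noise
that is elevated in the 2000-2200 nm combination region.  Every stochastic
draw is governed by a single seed, and noise terms are drawn in a fixed
order so that two configs differing only in noise scales share all other
randomness at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nirpls.data_model import (
    ReferenceTable,
    SpectralDataset,
    WavelengthGrid,
    make_grid,
)

__all__ = [
    "PureComponentSpec",
    "KineticProfileSpec",
    "GeneratorConfig",
    "pure_spectrum",
    "concentration_profiles",
    "simulate_dataset",
    "default_config",
    "noiseless",
]


@dataclass(frozen=True)
class PureComponentSpec:
    """Gaussian-band pure-component spectrum at unit concentration.

    ``bands`` is a list of ``(center_nm, width_nm, height)`` tuples with
    height in absorbance * mL/mg.
    """

    analyte: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.analyte}: at least one band required")
        for center, width, height in self.bands:
            if width <= 0:
                raise ValueError(f"{self.analyte}: band width must be > 0, got {width}")
            if height < 0:
                raise ValueError(f"{self.analyte}: band height must be >= 0")


@dataclass(frozen=True)
class KineticProfileSpec:
    """First-order extraction kinetics, restarted per phase with diminishing yield."""

    analyte: str
    c_max: tuple[float, float, float]  # mg/mL attainable per phase
    rate_k: tuple[float, float, float]  # 1/min per phase
    t_lag: float = 0.0  # min

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.c_max):
            raise ValueError(f"{self.analyte}: c_max must be >= 0")
        if any(k <= 0 for k in self.rate_k):
            raise ValueError(f"{self.analyte}: rate_k must be > 0")


@dataclass
class GeneratorConfig:
    grid: WavelengthGrid
    n_per_phase: tuple[int, int, int]
    components: tuple[PureComponentSpec, ...]
    kinetics: tuple[KineticProfileSpec, ...]
    water_bands: tuple[tuple[float, float, float], ...] = (
        (1950.0, 70.0, 1.0),
        (1450.0, 50.0, 0.25),
    )
    phase_duration_min: float = 150.0
    # optional explicit sampling times per phase (overrides the default
    # denser-early schedule); lengths must match n_per_phase
    sampling_times: tuple[tuple[float, ...], ...] | None = None
    baseline_const: float = 0.0
    baseline_temp_coeff: float = 0.002  # absorbance per deg C, ramped over the span
    gain_sd: float = 0.01
    offset_sd: float = 0.002
    noise_sd: float = 0.002
    noise_extra_sd: float = 0.008  # added in the noisy combination region
    noise_region_nm: tuple[float, float] = (2000.0, 2200.0)
    # per-sample compositional variability around the kinetic ideal; without
    # it the analyte profiles are collinear in time and a weak analyte could
    # be predicted from the strong analytes' signal alone
    kinetic_jitter_rel_sd: float = 0.10
    assay_error_rel_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_sd", "offset_sd", "noise_sd", "noise_extra_sd",
                     "assay_error_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(n < 2 for n in self.n_per_phase):
            raise ValueError("each phase needs at least 2 samples")
        names = [c.analyte for c in self.components]
        if sorted(names) != sorted(k.analyte for k in self.kinetics):
            raise ValueError("components and kinetics must cover the same analytes")


def pure_spectrum(spec: PureComponentSpec, grid: WavelengthGrid) -> np.ndarray:
    """Unit-concentration absorbance vector: sum of Gaussian bands."""
    wl = grid.wavelengths
    out = np.zeros(grid.n_points)
    for center, width, height in spec.bands:
        out += height * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return out


def concentration_profiles(
    kinetics: KineticProfileSpec, times_per_phase: list[np.ndarray]
) -> np.ndarray:
    """Concentrations c(t) = c_max * (1 - exp(-k * max(0, t - t_lag))),
    restarted in each phase with that phase's asymptote and rate."""
    if len(times_per_phase) != 3:
        raise ValueError("expected times for exactly 3 phases")
    parts = []
    for phase_idx, times in enumerate(times_per_phase):
        t = np.asarray(times, dtype=float)
        if (t < 0).any():
            raise ValueError("sampling times must be non-negative")
        cmax = kinetics.c_max[phase_idx]
        k = kinetics.rate_k[phase_idx]
        dt = np.maximum(0.0, t - kinetics.t_lag)
        parts.append(cmax * (1.0 - np.exp(-k * dt)))
    return np.concatenate(parts)


def _default_times(n: int, duration: float) -> np.ndarray:
    # denser sampling early in the phase, when contents vary fastest
    return duration * (np.arange(1, n + 1) / n) ** 1.6


def simulate_dataset(config: GeneratorConfig) -> tuple[SpectralDataset, ReferenceTable]:
    """Simulate one multi-phase extraction run.

    Row ``i`` of the absorbance matrix is
    ``a_i * (sum_a c_{i,a} * pure_a + water + drift_i) + b_i + eps_i`` with
    gain ``a_i ~ 1 + N(0, gain_sd)``, offset ``b_i ~ N(0, offset_sd)`` and
    heteroscedastic noise ``eps_i`` (extra variance inside
    ``noise_region_nm``).  Reference concentrations are the true values
    perturbed by a relative assay error.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    wl = grid.wavelengths
    n_total = sum(config.n_per_phase)

    if config.sampling_times is not None:
        if tuple(len(t) for t in config.sampling_times) != tuple(config.n_per_phase):
            raise ValueError("sampling_times lengths must match n_per_phase")
        times_per_phase = [np.asarray(t, dtype=float) for t in config.sampling_times]
    else:
        times_per_phase = [
            _default_times(n, config.phase_duration_min) for n in config.n_per_phase
        ]
    phase = np.concatenate(
        [np.full(n, p + 1, dtype=int) for p, n in enumerate(config.n_per_phase)]
    )
    time_min = np.concatenate(times_per_phase)

    analytes = [c.analyte for c in config.components]
    kin = {k.analyte: k for k in config.kinetics}
    conc = np.column_stack(
        [concentration_profiles(kin[a], times_per_phase) for a in analytes]
    )  # (n, m)
    pures = np.vstack(
        [pure_spectrum(c, grid) for c in config.components]
    )  # (m, p)
    water = pure_spectrum(
        PureComponentSpec("water", config.water_bands), grid
    )

    # deterministic heating profile plus measurement jitter (drawn first)
    temp_base = 100.0 - 40.0 * np.exp(-time_min / 10.0)
    temperature = temp_base + 0.5 * rng.standard_normal(n_total)

    # compositional jitter (second draw): true concentrations scatter
    # around the kinetic ideal sample by sample
    jitter_z = rng.standard_normal(conc.shape)
    conc = np.maximum(0.0, conc * (1.0 + config.kinetic_jitter_rel_sd * jitter_z))

    ramp = (wl - grid.start_nm) / (grid.stop_nm - grid.start_nm)
    drift_amp = config.baseline_const + config.baseline_temp_coeff * (
        temperature - 100.0
    )
    signal = conc @ pures + water[None, :] + drift_amp[:, None] * ramp[None, :]

    # remaining draws in fixed order: gain, offset, spectral noise, assay noise
    gain = 1.0 + config.gain_sd * rng.standard_normal(n_total)
    offset = config.offset_sd * rng.standard_normal(n_total)
    noise_z = rng.standard_normal((n_total, grid.n_points))
    lo, hi = config.noise_region_nm
    noisy_region = (wl >= lo) & (wl < hi)
    noise_scale = np.where(
        noisy_region,
        np.hypot(config.noise_sd, config.noise_extra_sd),
        config.noise_sd,
    )
    absorbance = gain[:, None] * signal + offset[:, None] + noise_z * noise_scale[None, :]

    sample_ids = [
        f"P{p}S{i + 1:02d}"
        for p, n in zip((1, 2, 3), config.n_per_phase)
        for i in range(n)
    ]
    dataset = SpectralDataset(
        grid=grid,
        absorbance=absorbance,
        sample_ids=sample_ids,
        phase=phase,
        time_min=time_min,
        temperature_c=temperature,
    )

    assay_z = rng.standard_normal(conc.shape)
    conc_ref = np.maximum(0.0, conc * (1.0 + config.assay_error_rel_sd * assay_z))
    rows = []
    for j, analyte in enumerate(analytes):
        for i, sid in enumerate(sample_ids):
            rows.append((sid, analyte, conc_ref[i, j]))
    refs = ReferenceTable(
        pd.DataFrame(rows, columns=["sample_id", "analyte", "concentration_mg_per_ml"])
    )
    return dataset, refs


def default_config(seed: int = 0, grid: WavelengthGrid | None = None) -> GeneratorConfig:
    """Shipped default: 93 samples over three phases (40/30/23) and four
    analytes whose weakest member is ~20x below the strongest, mirroring the
    hard low-concentration case the workflow must cope with."""
    if grid is None:
        grid = make_grid(800.0, 2200.0, 0.5)
    components = (
        PureComponentSpec(
            "glycyrrhizic_acid",
            ((1190.0, 25.0, 0.35), (1460.0, 35.0, 0.55), (1730.0, 30.0, 0.45)),
        ),
        PureComponentSpec(
            "liquiritin",
            ((1050.0, 20.0, 0.30), (1390.0, 30.0, 0.50), (1680.0, 25.0, 0.40)),
        ),
        # deliberately faint bands: lowest concentration AND weakest
        # absorptivity, reproducing the hard low-content case
        PureComponentSpec(
            "isoliquiritin",
            ((1260.0, 20.0, 0.16), (1550.0, 25.0, 0.20), (1820.0, 30.0, 0.14)),
        ),
        PureComponentSpec(
            "total_flavonoids",
            ((980.0, 25.0, 0.20), (1330.0, 35.0, 0.30), (1620.0, 30.0, 0.35),
             (1900.0, 40.0, 0.25)),
        ),
    )
    # distinct rates and non-proportional phase maxima keep the analyte
    # concentration profiles linearly independent across the run
    kinetics = (
        KineticProfileSpec("glycyrrhizic_acid", (2.2, 1.1, 0.45), (0.05, 0.04, 0.03)),
        KineticProfileSpec("liquiritin", (0.75, 0.40, 0.15), (0.07, 0.045, 0.035)),
        KineticProfileSpec("isoliquiritin", (0.10, 0.06, 0.015), (0.085, 0.055, 0.04)),
        KineticProfileSpec("total_flavonoids", (1.9, 1.0, 0.40), (0.10, 0.06, 0.045)),
    )
    return GeneratorConfig(
        grid=grid,
        n_per_phase=(40, 30, 23),
        components=components,
        kinetics=kinetics,
        seed=seed,
    )


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with every stochastic/instrumental term zeroed."""
    from dataclasses import replace

    return replace(
        config,
        gain_sd=0.0,
        offset_sd=0.0,
        noise_sd=0.0,
        noise_extra_sd=0.0,
        baseline_const=0.0,
        baseline_temp_coeff=0.0,
        assay_error_rel_sd=0.0,
    )
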