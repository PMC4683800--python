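from dataclasses import replace

import numpy as np
import pytest

from nirpls import default_config, make_grid, simulate_dataset
from nirpls.selection import sipls_search, thin_spectra
from nirpls.synthetic import (
    GeneratorConfig,
    KineticProfileSpec,
    PureComponentSpec,
    noiseless,
)


@pytest.fixture(scope="session")
def grid_full():
    return make_grid(800.0, 2200.0, 0.5)


@pytest.fixture(scope="session")
def default93():
    """The default 93-sample fixture at seed 1."""
    return simulate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def default93_thin(default93):
    """Seed-1 fixture thinned 8x (350 variables) for the heavier searches."""
    dataset, refs = default93
    X, grid = thin_spectra(dataset.absorbance, dataset.grid, 8)
    return dataset, refs, X, grid


@pytest.fixture(scope="session")
def small20():
    """A 20-sample dataset for cheap end-to-end exercises."""
    cfg = replace(default_config(seed=42), n_per_phase=(8, 6, 6))
    return simulate_dataset(cfg)


def band_limited_config(intervals=(4, 8, 14), seed=5):
    """Generator whose informative signal is confined to the given 1-based
    subintervals of a 20-way split, with everything else noise.

    Two interferents chain the intervals together (target + interferent A
    share the first interval, A + B the second, B alone the third), so the
    target is only identifiable from ALL of the listed intervals jointly --
    the exhaustive search must return exactly that set.  Uses a coarse
    400-point grid (800-2200 nm at 3.5 nm; 20 points per interval) to keep
    the 1140-combination search fast.
    """
    i1, i2, i3 = intervals
    grid = make_grid(800.0, 2200.0, 3.5)
    width_nm = (grid.stop_nm - grid.start_nm) / 20.0

    def center(i):
        return grid.start_nm + (i - 0.5) * width_nm

    target = PureComponentSpec("target", ((center(i1), 6.0, 0.5),))
    interf_a = PureComponentSpec(
        "interferent_a", ((center(i1), 6.0, 0.5), (center(i2), 6.0, 0.5))
    )
    interf_b = PureComponentSpec(
        "interferent_b", ((center(i2), 6.0, 0.5), (center(i3), 6.0, 0.5))
    )
    kin = [
        KineticProfileSpec(name, (2.0, 1.0, 0.5), (0.05, 0.04, 0.03))
        for name in ("target", "interferent_a", "interferent_b")
    ]
    return GeneratorConfig(
        grid=grid,
        n_per_phase=(16, 12, 12),
        components=(target, interf_a, interf_b),
        kinetics=tuple(kin),
        water_bands=((1950.0, 70.0, 0.0),),  # no water: keep signal confined
        baseline_const=0.0,
        baseline_temp_coeff=0.0,
        gain_sd=0.0,
        offset_sd=0.0,
        noise_sd=0.004,
        noise_extra_sd=0.0,
        kinetic_jitter_rel_sd=0.4,  # decorrelate target from interferents
        seed=seed,
    )


@pytest.fixture(scope="session")
def sipls_recovery():
    """Shared result of the synergy-interval search on the band-limited
    fixture (used by both the unit test and the acceptance criterion)."""
    cfg = band_limited_config()
    dataset, refs = simulate_dataset(cfg)
    conc = refs.concentrations("target").loc[dataset.sample_ids].to_numpy()
    result = sipls_search(
        dataset.absorbance, conc, dataset.grid, n_intervals=20, k=3, A_max=4
    )
    return result


@pytest.fixture(scope="session")
def noiseless93():
    return simulate_dataset(noiseless(default_config(seed=1)))
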