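import datetime as dt

import numpy as np
import pytest

import firecycles as fc

MONDAY = dt.date(2002, 7, 8)  # series origin used throughout


@pytest.fixture(scope="session")
def preset():
    return fc.global_fire_preset(seed=1)


@pytest.fixture(scope="session")
def annual_only_terms(preset):
    """Harmonic terms without the weekly/3.5-day cycles (null weekday effect)."""
    return preset.harmonic_terms[:4]


@pytest.fixture(scope="session")
def toy_grid():
    """2x3 grid: left column Croplands (31), middle Rangelands (41), right Seminatural (51)."""
    return fc.make_toy_anthrome_grid(
        2, 3, {(0, 2, 0, 1): 31, (0, 2, 1, 2): 41, (0, 2, 2, 3): 51}, cellsize=0.5
    )


@pytest.fixture(scope="session")
def small_record_set(toy_grid):
    specs = {
        "Croplands": fc.SimulationSpec(
            intercept=np.log(30), n_days=21, innovation_sd=1e-9, seed=1, start_date=MONDAY
        ),
        "Rangelands": fc.SimulationSpec(
            intercept=np.log(8), n_days=21, innovation_sd=1e-9, seed=2, start_date=MONDAY
        ),
    }
    return fc.simulate_fire_records(specs, toy_grid, seed=5), specs


def fit_preset_series(seed, weekday_offsets=(0.0,) * 7, harmonic_terms=None):
    """Simulate a preset series and fit the harmonic-AR model (shared helper)."""
    spec = fc.global_fire_preset(seed=seed, weekday_offsets=weekday_offsets)
    if harmonic_terms is not None:
        spec = fc.SimulationSpec(
            intercept=spec.intercept,
            trend=spec.trend,
            harmonic_terms=harmonic_terms,
            weekday_offsets=weekday_offsets,
            ar_coefficients=spec.ar_coefficients,
            innovation_sd=spec.innovation_sd,
            n_days=spec.n_days,
            seed=seed,
        )
    logs, mean = fc.simulate_log_series(spec)
    return spec, logs, mean, fc.fit_bayes_harmonic_ar(logs)
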