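"""Shared fixtures: light-weight simulation conditions sized so the full
suite runs on one CPU in a few minutes while keeping enough statistics for
the stated tolerances."""

from __future__ import annotations

import pytest

from polfcs import (
    FitSpec,
    RigidMultimer,
    SimulationConfig,
    average_curves,
    fit_curve,
    multitau_correlate,
    simulate_photon_traces,
)

#: a fast-rotating, fast-diffusing test condition: tau_r = 100 ns,
#: tau_d = 5 us at w = 0.1 um, mean occupancy ~1; box at 6 s w keeps the
#: periodic-box distortion of the diffusion spectrum below one percent
LIGHT = dict(
    d_t=5e-10,
    d_r=1.0 / (6 * 100e-9),
    beam_waist=0.1e-6,
    s=1.0,
    box_half_width=6 * 0.1e-6,
    n_molecules_box=310,
)

#: default free/fixed parameter sets for fitting simulated monomer curves
SPEC4 = dict(
    free_params=("n_molecules", "tau_d", "f_r", "tau_r"),
    fixed_params={"s": 1.0, "f_tri": 0.0},
    weighting="uniform",
)


def light_config(**overrides) -> SimulationConfig:
    kw = {**LIGHT, "duration": 10e-3, "config": "X-XX", "seed": 0}
    kw.update(overrides)
    return SimulationConfig(**kw)


def simulate_and_fit(multimer, n_repeats=2, seed=0, max_lag=4e-4,
                     fit_kwargs=None, **cfg_overrides):
    """Simulate repeats, average the multi-tau curves, fit the model."""
    curves = []
    for k in range(n_repeats):
        cfg = light_config(seed=seed + 17 * k, **cfg_overrides)
        trace = simulate_photon_traces(multimer, cfg)
        curves.append(multitau_correlate(trace, max_lag=max_lag))
    curve = average_curves(curves) if n_repeats > 1 else curves[0]
    spec = FitSpec(**(fit_kwargs or SPEC4))
    return fit_curve(curve, spec), curve


@pytest.fixture(scope="session")
def monomer() -> RigidMultimer:
    return RigidMultimer.monomer()


@pytest.fixture(scope="session")
def light_xx_fit(monomer):
    """One fitted light-scale X-XX monomer run, shared across tests."""
    result, curve = simulate_and_fit(monomer, n_repeats=2, seed=601)
    return result, curve, light_config(seed=601)
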