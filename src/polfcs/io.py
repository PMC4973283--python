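"""Structured run configuration and file round-tripping.

A single YAML file describes a run, with one section per pipeline stage.
Physical quantities carry explicit SI unit suffixes in their field names
(``_s``, ``_m``, ``_m2_s``, ``_per_s``, ``_pa_s``, ``_k``) to prevent
ns/us/nm confusion.  See ``example_config()`` for the full schema with
defaults.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .hydrodynamics import HydroEnvironment
from .simulator import OpticsModel, RigidMultimer, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "load_config",
    "build_multimer",
    "build_simulation_config",
    "read_viscosity_series",
    "example_config",
]


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    return cfg


def build_multimer(section: dict) -> RigidMultimer:
    """Construct a RigidMultimer from its config mapping.

    ``type`` is one of monomer, parallel, orthogonal, random, custom;
    ``n`` the number of dipoles; ``custom`` takes explicit ``dipoles``
    (rows normalized on input) and optional ``dark_flags``.
    """
    kind = section.get("type", "monomer")
    brightness = float(section.get("brightness_per_s", 5e7))
    n = int(section.get("n", 1))
    if kind == "monomer":
        return RigidMultimer.monomer(brightness)
    if kind == "parallel":
        return RigidMultimer.parallel(n, brightness)
    if kind == "orthogonal":
        return RigidMultimer.orthogonal(n, brightness)
    if kind == "random":
        return RigidMultimer.random(n, rng=int(section.get("geometry_seed", 0)),
                                    brightness=brightness)
    if kind == "custom":
        d = np.asarray(section["dipoles"], dtype=float)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        return RigidMultimer(d, brightness, dark_flags=section.get("dark_flags"))
    raise ValueError(f"unknown multimer type {kind!r}")


def build_simulation_config(section: dict, seed: Optional[int] = None) -> SimulationConfig:
    """Construct a SimulationConfig from the ``simulate`` config section."""
    optics_sec = section.get("optics", {})
    if optics_sec.get("ideal"):
        optics = OpticsModel.ideal()
    else:
        optics = OpticsModel(
            excitation_isotropic_fraction=float(
                optics_sec.get("excitation_isotropic_fraction", 0.35)
            ),
            na=float(optics_sec.get("na", 1.2)),
            n_medium=float(optics_sec.get("n_medium", 1.33)),
        )
    triplet = section.get("triplet", {})
    return SimulationConfig(
        d_t=float(section["d_t_m2_s"]),
        d_r=float(section["d_r_per_s"]),
        beam_waist=float(section.get("beam_waist_m", 0.2e-6)),
        s=float(section.get("s", 1.0)),
        box_half_width=section.get("box_half_width_m"),
        n_molecules_box=int(section.get("n_molecules_box", 64)),
        dt=section.get("dt_s"),
        duration=float(section.get("duration_s", 0.01)),
        bin_width=section.get("bin_width_s"),
        config=section.get("config", "X-XX"),
        optics=optics,
        triplet_on=bool(triplet.get("on", False)),
        k_isc=float(triplet.get("k_isc_per_s", 0.0)),
        k_t=float(triplet.get("k_t_per_s", 0.0)),
        background_rate=float(section.get("background_rate_per_s", 0.0)),
        seed=int(section.get("seed", 0) if seed is None else seed),
    )


def build_environment(section: dict) -> HydroEnvironment:
    return HydroEnvironment(
        viscosity=float(section.get("viscosity_pa_s", 8.9e-4)),
        temperature=float(section.get("temperature_k", 298.15)),
    )


def read_viscosity_series(path) -> pd.DataFrame:
    """Read a viscosity-series CSV: viscosity_pa_s, tau_d_s, tau_r_s."""
    df = pd.read_csv(path)
    required = {"viscosity_pa_s", "tau_d_s", "tau_r_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def example_config() -> str:
    """A complete example YAML configuration with defaults."""
    return """\
seed: 1
output_dir: polfcs_out

simulate:
  d_t_m2_s: 1.0e-10        # translational diffusion coefficient
  d_r_per_s: 4.386e6       # rotational diffusion coefficient (1/(6*38ns))
  beam_waist_m: 2.0e-7
  s: 1.0                   # axial/lateral ratio of the observation volume
  n_molecules_box: 92
  duration_s: 0.01
  config: X-XX             # one of X-XX, X-YY, X-NN, X-XY
  background_rate_per_s: 0.0
  optics:
    excitation_isotropic_fraction: 0.35
    na: 1.2
    n_medium: 1.33
  triplet:
    on: false
    k_isc_per_s: 0.0
    k_t_per_s: 0.0
  multimer:
    type: monomer          # monomer | parallel | orthogonal | random | custom
    n: 1
    brightness_per_s: 5.0e7

correlate:
  m: 16
  p: 2
  max_lag_s: null

fit:
  free: [n_molecules, tau_d, f_r, tau_r]
  shared: []               # e.g. [tau_r] for a global fit
  fixed: {s: 1.0, f_tri: 0.0, tau_t: 1.24e-6}
  weighting: auto

hydro:
  beam_waist_m: 2.0e-7
  viscosity_pa_s: 8.9e-4
  temperature_k: 298.15
  through_origin: false
  # series_csv: viscosity_series.csv   # viscosity_pa_s, tau_d_s, tau_r_s
  # slope_m2: 4.88e16                  # skip the series and use this slope

sweep:
  family:
    - {type: monomer}
    - {type: parallel, n: 4}
    - {type: orthogonal, n: 2}
    - {type: orthogonal, n: 3}
    - {type: random, n: 3, geometry_seed: 1}
    - {type: random, n: 5, geometry_seed: 2}

pipeline:
  radius_m: 3.9e-9
  temperature_k: 298.15
  viscosities_pa_s: [8.9e-4, 1.78e-3, 2.67e-3]
  n_repeats: 2
"""
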