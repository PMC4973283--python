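"""Diffusion coefficients and Stokes-Einstein hydrodynamic radius.

Fitted relaxation times convert to diffusion coefficients as

    D_T = w^2 / (4 tau_D),        D_R = 1 / (6 tau_R),

with ``w`` the lateral 1/e^2 radius of the confocal volume; note that D_R
needs no knowledge of the observation volume.  For a stick-boundary sphere of
radius r in a fluid of viscosity eta at temperature T,

    D_T = k_B T / (6 pi eta r),   D_R = k_B T / (8 pi eta r^3),

so the ratio D_R / D_T = 3 / (4 r^2) eliminates viscosity and temperature,
and a linear fit of D_R against D_T over a viscosity series yields the radius
as r = sqrt(3 / (4 * slope)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.constants
import scipy.stats

__all__ = [
    "BOLTZMANN",
    "HydroEnvironment",
    "DiffusionEstimate",
    "diffusion_from_times",
    "stokes_einstein_radius",
    "fit_dr_dt_slope",
    "radius_from_slope",
    "viscosity_series_report",
]

#: CODATA Boltzmann constant, J/K
BOLTZMANN: float = scipy.constants.k


@dataclass(frozen=True)
class HydroEnvironment:
    """Solvent environment: dynamic viscosity (Pa s) and temperature (K)."""

    viscosity: float
    temperature: float = 298.15
    k_b: float = BOLTZMANN

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity!r}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature!r}")

    def d_t_sphere(self, radius: float) -> float:
        """Translational diffusion coefficient of a sphere of given radius."""
        return self.k_b * self.temperature / (6 * np.pi * self.viscosity * radius)

    def d_r_sphere(self, radius: float) -> float:
        """Rotational diffusion coefficient of a sphere of given radius."""
        return self.k_b * self.temperature / (8 * np.pi * self.viscosity * radius**3)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Translational/rotational diffusion coefficients and optional radius."""

    d_t: float
    d_r: float
    beam_waist: float
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.d_t > 0 or not self.d_r > 0:
            raise ValueError("diffusion coefficients must be > 0")
        if self.radius is not None and not self.radius > 0:
            raise ValueError("radius must be > 0 when present")


def diffusion_from_times(tau_d: float, tau_r: float, beam_waist: float) -> DiffusionEstimate:
    """Convert relaxation times to diffusion coefficients.

    D_T = w^2/(4 tau_D); D_R = 1/(6 tau_R), independent of the beam waist.
    """
    if not (tau_d > 0 and tau_r > 0 and beam_waist > 0):
        raise ValueError("tau_d, tau_r and beam_waist must all be > 0")
    return DiffusionEstimate(
        d_t=beam_waist**2 / (4.0 * tau_d),
        d_r=1.0 / (6.0 * tau_r),
        beam_waist=beam_waist,
    )


def stokes_einstein_radius(d_t: float, env: HydroEnvironment) -> float:
    """Hydrodynamic radius r = k_B T / (6 pi eta D_T) of a Stokes sphere."""
    if not d_t > 0:
        raise ValueError(f"d_t must be > 0, got {d_t!r}")
    return env.k_b * env.temperature / (6 * np.pi * env.viscosity * d_t)


def fit_dr_dt_slope(points: Sequence, through_origin: bool = False) -> float:
    """Least-squares slope of D_R against D_T over a viscosity series.

    Parameters
    ----------
    points:
        Sequence of (d_t, d_r) pairs, one per solvent condition; all positive.
    through_origin:
        If True, force a zero intercept (the spherical-particle relation
        implies one); the default fits an ordinary line with free intercept
        and reports its slope.

    Returns
    -------
    Slope in m^-2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (d_t, d_r) points")
    if np.any(pts <= 0):
        raise ValueError("all diffusion coefficients must be > 0")
    d_t, d_r = pts[:, 0], pts[:, 1]
    if np.ptp(d_t) == 0:
        raise ValueError("degenerate series: all d_t values identical")
    if through_origin:
        return float(d_t @ d_r / (d_t @ d_t))
    return float(scipy.stats.linregress(d_t, d_r).slope)


def radius_from_slope(slope: float) -> float:
    """Hydrodynamic radius from the D_R/D_T slope: r = sqrt(3/(4*slope)).

    Viscosity and temperature cancel in the ratio, so the radius depends on
    the slope alone.
    """
    if not slope > 0:
        raise ValueError(f"slope must be > 0, got {slope!r}")
    return float(np.sqrt(3.0 / (4.0 * slope)))


def viscosity_series_report(
    series: pd.DataFrame,
    beam_waist: float,
    through_origin: bool = False,
) -> pd.DataFrame:
    """Convert a viscosity series of fitted times to diffusion coefficients.

    ``series`` must have columns ``viscosity_pa_s``, ``tau_d_s``, ``tau_r_s``
    (one row per solvent condition).  Returns the input augmented with
    ``d_t_m2_s`` and ``d_r_per_s`` columns plus ``slope_m2`` / ``radius_m``
    attrs when the series has at least two distinct conditions.
    """
    required = {"viscosity_pa_s", "tau_d_s", "tau_r_s"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"viscosity series missing columns: {sorted(missing)}")
    out = series.copy()
    est = [
        diffusion_from_times(row.tau_d_s, row.tau_r_s, beam_waist)
        for row in series.itertuples()
    ]
    out["d_t_m2_s"] = [e.d_t for e in est]
    out["d_r_per_s"] = [e.d_r for e in est]
    if len(out) >= 2 and np.ptp(out["d_t_m2_s"]) > 0:
        slope = fit_dr_dt_slope(out[["d_t_m2_s", "d_r_per_s"]].to_numpy(),
                                through_origin=through_origin)
        out.attrs["slope_m2"] = slope
        out.attrs["radius_m"] = radius_from_slope(slope)
    return out
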