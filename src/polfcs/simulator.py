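"""Brownian-dynamics forward model of a pol-FCS measurement.

Rigid fluorophore multimers — sets of unit transition dipoles fixed in a
common body frame — translate through a 3D-Gaussian observation volume in a
periodic box and undergo isotropic rotational diffusion.  Channel intensities
follow the polarized excitation/detection model:

* excitation probability proportional to ``(mu . e_x)^2``, with a fraction of
  the focal excitation treated as unpolarized (high-NA depolarization);
* emission reaching an analyzer/polarizing-splitter axis ``p`` with weight
  ``(mu . p)^2``, mixed with the orthogonal and axial dipole components
  according to collection coefficients integrated over the objective
  aperture; a non-polarizing splitter halves each arm first, and an ``N``
  (analyzer-free) channel accepts both pupil polarizations.

Photon counts per bin are Poisson draws of the accumulated intensity plus a
uniform background.  With the default optics the four standard
configurations reproduce the instrument's sign rule for the rotational
fraction: positive for X-XX, X-YY and X-NN, negative for crossed X-XY.

The orientational parameter OP summarises multimer dipole geometry as the
mean squared cosine over distinct non-dark dipole pairs: 1 when all dipoles
are parallel, 0 when every pair is orthogonal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .correlator import PhotonTrace, multitau_correlate
from .model import PolarizationConfig, get_config

logger = logging.getLogger(__name__)

__all__ = [
    "RigidMultimer",
    "OpticsModel",
    "SimulationConfig",
    "orientational_parameter",
    "rotate_step",
    "rotate_dipoles",
    "simulate_photon_traces",
    "op_fr_sweep",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidMultimer:
    """A rigid set of unit transition dipoles in a body frame.

    ``dark_flags`` marks dipoles that are non-fluorescent (quenched or
    misfolded units); dark dipoles are excluded both from photon emission and
    from the orientational parameter.
    """

    dipoles: np.ndarray
    brightness: float | np.ndarray = 5e7
    dark_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 1:
            raise ValueError("dipoles must be an (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("every dipole must have unit norm within 1e-12")
        object.__setattr__(self, "dipoles", d)
        b = np.broadcast_to(np.asarray(self.brightness, dtype=float), (d.shape[0],)).copy()
        if np.any(b < 0):
            raise ValueError("brightness must be >= 0")
        object.__setattr__(self, "brightness", b)
        if self.dark_flags is None:
            flags = np.zeros(d.shape[0], dtype=bool)
        else:
            flags = np.asarray(self.dark_flags, dtype=bool)
            if flags.shape != (d.shape[0],):
                raise ValueError("dark_flags must match the number of dipoles")
        if flags.all():
            raise ValueError("multimer needs at least one non-dark dipole")
        object.__setattr__(self, "dark_flags", flags)

    @property
    def n_dipoles(self) -> int:
        return self.dipoles.shape[0]

    @property
    def active_dipoles(self) -> np.ndarray:
        return self.dipoles[~self.dark_flags]

    @property
    def active_brightness(self) -> np.ndarray:
        return self.brightness[~self.dark_flags]

    # -- common geometries -------------------------------------------------
    @classmethod
    def monomer(cls, brightness: float = 5e7) -> "RigidMultimer":
        return cls(np.array([[0.0, 0.0, 1.0]]), brightness)

    @classmethod
    def parallel(cls, n: int, brightness: float = 5e7) -> "RigidMultimer":
        return cls(np.tile([0.0, 0.0, 1.0], (n, 1)), brightness)

    @classmethod
    def orthogonal(cls, n: int, brightness: float = 5e7) -> "RigidMultimer":
        if not 2 <= n <= 3:
            raise ValueError("mutually orthogonal sets exist only for n = 2 or 3")
        return cls(np.eye(3)[:n], brightness)

    @classmethod
    def random(cls, n: int, rng=None, brightness: float = 5e7) -> "RigidMultimer":
        rng = np.random.default_rng(rng)
        v = rng.standard_normal((n, 3))
        return cls(v / np.linalg.norm(v, axis=1, keepdims=True), brightness)


def orientational_parameter(multimer: RigidMultimer) -> float:
    """Degree of dipole co-orientation, OP in [0, 1].

    Mean of ``(mu_n . mu_m)^2`` over distinct non-dark dipole pairs; a
    single-dipole multimer has OP = 1 by convention.  Invariant under global
    rotations and under flipping the sign of any dipole.
    """
    d = multimer.active_dipoles
    n = d.shape[0]
    if n == 1:
        return 1.0
    c2 = (d @ d.T) ** 2
    return float((c2.sum() - n) / (n * (n - 1)))


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _collection_coefficients(na: float, n_medium: float) -> tuple:
    """Pupil-polarization mixing of a dipole's emission over the aperture.

    Integrates the far-field of x/y/z-oriented dipoles, mapped through an
    aplanatic objective of the given NA, against an x-analyzer.  Returns
    ``(k_par, k_perp, k_axial)`` normalized so k_par = 1: the x-analyzer
    channel weight of the mux^2, muy^2 and muz^2 dipole components.
    """
    if na <= 0:
        return (1.0, 0.0, 0.0)
    alpha = math.asin(min(na / n_medium, 1.0))
    th = np.linspace(0.0, alpha, 512)
    ph = np.linspace(0.0, 2 * np.pi, 1024, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    st, ct, sp, cp = np.sin(T), np.cos(T), np.sin(P), np.cos(P)
    wq = st * (th[1] - th[0]) * (ph[1] - ph[0]) * np.sqrt(np.abs(ct))
    K = np.zeros(3)
    for i, mu in enumerate(np.eye(3)):
        m_etheta = mu[0] * ct * cp + mu[1] * ct * sp - mu[2] * st
        m_ephi = -mu[0] * sp + mu[1] * cp
        amp = m_etheta * cp - m_ephi * sp
        K[i] = float(np.sum(amp**2 * wq))
    return (1.0, K[1] / K[0], K[2] / K[0])


@dataclass(frozen=True)
class OpticsModel:
    """Polarization response of the instrument.

    ``excitation_isotropic_fraction`` is the fraction of the focal excitation
    that photoselects isotropically rather than along x (depolarization by
    high-NA focusing and the epi-illumination path); ``na``/``n_medium``
    set the collection-side mixing via the objective aperture.  The defaults
    describe a water-immersion NA 1.2 objective and reproduce the standard
    sign rule of the four polarization configurations.  ``OpticsModel.ideal()``
    gives pure cos^2 photoselection with no mixing.
    """

    excitation_isotropic_fraction: float = 0.35
    na: float = 1.2
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if not 0.0 <= self.excitation_isotropic_fraction < 1.0:
            raise ValueError("excitation_isotropic_fraction must be in [0, 1)")
        if self.na < 0 or self.n_medium <= 0 or self.na > self.n_medium:
            raise ValueError("need 0 <= na <= n_medium")

    @classmethod
    def ideal(cls) -> "OpticsModel":
        return cls(excitation_isotropic_fraction=0.0, na=0.0)

    def excitation_coefficients(self) -> tuple:
        """(a, b) such that the excitation factor is a + b*mux^2, with the
        x-aligned dipole normalized to 1."""
        me = self.excitation_isotropic_fraction
        norm = (1.0 - me) + me / 3.0
        return (me / 3.0 / norm, (1.0 - me) / norm)

    def detection_coefficients(self) -> tuple:
        return _collection_coefficients(self.na, self.n_medium)


def _channel_coefficients(config: PolarizationConfig, optics: OpticsModel):
    """Per-channel quadratic detection weights (cx, cy, cz) incl. splitter."""
    kp, kq, ka = optics.detection_coefficients()
    axes = {
        "X": np.array([kp, kq, ka]),
        "Y": np.array([kq, kp, ka]),
    }
    axes["N"] = axes["X"] + axes["Y"]
    split = 0.5 if config.splitter == "NPBS" else 1.0
    return split * axes[config.detector1_pol], split * axes[config.detector2_pol]


# ---------------------------------------------------------------------------
# rotational diffusion steps
# ---------------------------------------------------------------------------

def rotate_step(orientation: np.ndarray, d_r: float, dt: float, rng) -> np.ndarray:
    """One isotropic rotational-diffusion step of a rigid-body orientation.

    Rotates the orientation matrix about a uniformly random axis by a
    Gaussian angle of variance ``6 * d_r * dt`` (which gives a dipole
    tangent-displacement variance of ``4 * d_r * dt`` and the diffusive
    P2 relaxation ``exp(-6 d_r t)`` in the small-step limit).  Returns a new
    proper rotation matrix; ``d_r = 0`` returns the input unchanged.
    """
    R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    if d_r == 0.0:
        return R.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    theta = math.sqrt(6.0 * d_r * dt) * rng.standard_normal()
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    dR = np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)
    return dR @ R


def rotate_dipoles(dipoles: np.ndarray, d_r: float, dt: float, rng) -> np.ndarray:
    """Vectorized single rotational step of an ensemble of unit vectors.

    Same axis-angle scheme as :func:`rotate_step`, one independent rotation
    per vector; used for ensemble relaxation checks.
    """
    v = np.asarray(dipoles, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    axis = rng.standard_normal(v.shape)
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
    theta = math.sqrt(6.0 * d_r * dt) * rng.standard_normal(v.shape[:-1] + (1,))
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    cross = np.cross(axis, v)
    out = v * cos_t + cross * sin_t + axis * dot * (1.0 - cos_t)
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# simulation configuration and driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical controls of a photon-stream simulation.

    Timescales: the fine timestep must resolve the fastest relaxation,
    ``dt <= min(1/(6 d_r), w^2/(4 d_t)) / 50``; the periodic box must be
    large against the observation volume, ``box_half_width >= 4 s w``; the
    photon bin width must be an integer multiple of dt.
    """

    d_t: float = 1e-10
    d_r: float = 1.0 / (6 * 38e-9)
    beam_waist: float = 0.2e-6
    s: float = 1.0
    box_half_width: Optional[float] = None
    n_molecules_box: int = 64
    dt: Optional[float] = None
    duration: float = 0.01
    bin_width: Optional[float] = None
    config: PolarizationConfig | str = "X-XX"
    optics: OpticsModel = field(default_factory=OpticsModel)
    triplet_on: bool = False
    k_isc: float = 0.0
    k_t: float = 0.0
    background_rate: float = 0.0
    seed: int = 0
    weight_cutoff: float = 1e-4

    def __post_init__(self) -> None:
        if self.d_t <= 0 or self.d_r < 0 or self.beam_waist <= 0 or self.s < 1:
            raise ValueError("need d_t > 0, d_r >= 0, beam_waist > 0, s >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_molecules_box < 1:
            raise ValueError("need at least one molecule in the box")
        object.__setattr__(self, "config", get_config(self.config))
        dt_max = self.max_timestep()
        if self.dt is None:
            object.__setattr__(self, "dt", dt_max)
        elif self.dt > dt_max * (1 + 1e-9):
            raise ValueError(
                f"dt={self.dt:g} too coarse: must be <= "
                f"min(1/(6 d_r), w^2/(4 d_t))/50 = {dt_max:g}"
            )
        if self.bin_width is None:
            object.__setattr__(self, "bin_width", 2 * self.dt)
        spb = self.bin_width / self.dt
        if self.bin_width < self.dt or abs(spb - round(spb)) > 1e-6:
            raise ValueError("bin_width must be an integer multiple of dt")
        min_box = 4.0 * self.s * self.beam_waist
        if self.box_half_width is None:
            object.__setattr__(self, "box_half_width", min_box)
        elif self.box_half_width < min_box * (1 - 1e-12):
            raise ValueError(f"box_half_width must be >= 4*s*w = {min_box:g}")
        if self.triplet_on and (self.k_isc <= 0 or self.k_t <= 0):
            raise ValueError("triplet_on requires positive k_isc and k_t")

    def max_timestep(self) -> float:
        """Largest fine timestep the resolution invariant allows."""
        tau_rot = 1.0 / (6.0 * self.d_r) if self.d_r > 0 else math.inf
        tau_trans = self.beam_waist**2 / (4.0 * self.d_t)
        return min(tau_rot, tau_trans) / 50.0

    @property
    def tau_d(self) -> float:
        return self.beam_waist**2 / (4.0 * self.d_t)

    @property
    def tau_r(self) -> float:
        return math.inf if self.d_r == 0 else 1.0 / (6.0 * self.d_r)

    def mean_occupancy(self) -> float:
        """Expected molecule count in the effective observation volume."""
        v_eff = np.pi**1.5 * self.beam_waist**3 * self.s
        return self.n_molecules_box * v_eff / (2 * self.box_half_width) ** 3

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def simulate_photon_traces(
    multimer: RigidMultimer,
    cfg: SimulationConfig,
    initial_positions: Optional[np.ndarray] = None,
) -> PhotonTrace:
    """Simulate a two-channel binned photon trace for one multimer species.

    All molecules in the box are independent copies of ``multimer``.
    Deterministic for a fixed ``cfg.seed``.  Returns a
    :class:`~polfcs.correlator.PhotonTrace` carrying the polarization
    configuration and the seed.
    """
    from . import _kernels  # deferred: numba compilation on first use

    steps_per_bin = int(round(cfg.bin_width / cfg.dt))
    n_bins = int(round(cfg.duration / cfg.bin_width))
    if n_bins < 2:
        raise ValueError("duration must cover at least two photon bins")
    # translation updates every block; block span <= tau_d / 100
    block_bins = max(1, min(int(cfg.tau_d / (100.0 * cfg.bin_width)), 4096, n_bins))
    n_bins = (n_bins // block_bins) * block_bins

    slowest = max(cfg.tau_d, 0.0 if math.isinf(cfg.tau_r) else cfg.tau_r)
    if n_bins * cfg.bin_width < 100 * slowest:
        logger.warning(
            "duration %.3g s < 100 * slowest relaxation %.3g s; "
            "correlation estimates may be unreliable",
            n_bins * cfg.bin_width, slowest,
        )

    exc_a, exc_b = cfg.optics.excitation_coefficients()
    c0, c1 = _channel_coefficients(cfg.config, cfg.optics)
    if initial_positions is None:
        init = np.zeros((0, 3))
    else:
        init = np.asarray(initial_positions, dtype=float).reshape(-1, 3)
        if init.shape[0] != cfg.n_molecules_box:
            raise ValueError("initial_positions must provide one row per molecule")

    lam0 = np.zeros(n_bins)
    lam1 = np.zeros(n_bins)
    _kernels.accumulate_intensity(
        lam0, lam1,
        int(cfg.seed), int(cfg.n_molecules_box), steps_per_bin, block_bins,
        float(cfg.dt), float(cfg.d_t), float(cfg.d_r),
        float(cfg.beam_waist), float(cfg.s), float(cfg.box_half_width),
        np.ascontiguousarray(multimer.active_dipoles),
        np.ascontiguousarray(multimer.active_brightness),
        float(exc_a), float(exc_b),
        float(c0[0]), float(c0[1]), float(c0[2]),
        float(c1[0]), float(c1[1]), float(c1[2]),
        bool(cfg.triplet_on), float(cfg.k_isc), float(cfg.k_t),
        float(cfg.weight_cutoff), init,
    )
    bg = cfg.background_rate * cfg.bin_width
    rng = np.random.default_rng([int(cfg.seed), 0x9E3779B9])
    counts0 = rng.poisson(lam0 + bg).astype(np.int32)
    counts1 = rng.poisson(lam1 + bg).astype(np.int32)
    return PhotonTrace(
        counts_ch0=counts0,
        counts_ch1=counts1,
        bin_width=cfg.bin_width,
        config=cfg.config,
        seed=int(cfg.seed),
    )


def op_fr_sweep(
    multimer_family: Sequence[RigidMultimer],
    cfg: SimulationConfig,
    m: int = 16,
    p: int = 2,
    max_lag: Optional[float] = None,
) -> pd.DataFrame:
    """Simulate each multimer under identical conditions; tabulate OP vs f_R.

    Each family member is simulated (seed offset per row), correlated with
    the multi-tau estimator and fitted with the combined model, holding the
    rotational time fixed at the configured set-point 1/(6 d_r) so the fitted
    rotational fraction is directly comparable across geometries.  Returns a
    DataFrame with columns op, f_r, tau_d, n_molecules, converged; Spearman
    rank correlation between OP and f_R over converged rows is stored in
    ``df.attrs['spearman_r']``.
    """
    from .fitting import FitSpec, fit_curve

    if max_lag is None:
        max_lag = 10.0 * cfg.tau_d
    rows = []
    for i, multimer in enumerate(multimer_family):
        run_cfg = cfg.replace(seed=cfg.seed + 1013 * (i + 1))
        trace = simulate_photon_traces(multimer, run_cfg)
        curve = multitau_correlate(trace, m=m, p=p, max_lag=max_lag)
        spec = FitSpec(
            curves=[curve],
            free_params=("n_molecules", "tau_d", "f_r"),
            fixed_params={"tau_r": cfg.tau_r, "s": cfg.s, "f_tri": 0.0},
        )
        res = fit_curve(curve, spec)
        fitted = res.params_per_curve[0]
        rows.append(
            {
                "op": orientational_parameter(multimer),
                "f_r": fitted.f_r,
                "tau_d": fitted.tau_d,
                "n_molecules": fitted.n_molecules,
                "converged": bool(res.success),
                "seed": run_cfg.seed,
            }
        )
    df = pd.DataFrame(rows)
    ok = df[df.converged]
    if len(ok) >= 2 and ok.op.nunique() > 1:
        rho = scipy.stats.spearmanr(ok.op, ok.f_r).statistic
        df.attrs["spearman_r"] = float(rho)
    return df
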