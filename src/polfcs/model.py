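"""Closed-form correlation model for polarization-dependent FCS.

The measured cross-correlation of the two detection channels is modelled as a
product of three relaxation factors,

    G(tau) = G_D(tau) * (1 + f_R exp(-tau/tau_R)) * (1 + f_tri exp(-tau/tau_T)),

where ``G_D`` is the ordinary 3D-Gaussian translational-diffusion ACF

    G_D(tau) = (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(s^2 tau_D))^-1/2,

``f_R`` and ``f_tri`` are the rotational and triplet amplitudes expressed as
fractions of the translational amplitude, and ``tau_R``, ``tau_T`` the
corresponding relaxation times.  ``f_R`` may be negative: with crossed
analyzers (the X-XY configuration) the rotational component of the two
channels is anti-correlated and the factor dips below one at short lags.

All quantities are SI (delay times in seconds); the model is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FCSModelParams",
    "PolarizationConfig",
    "POLARIZATION_CONFIGS",
    "CorrelationCurve",
    "g_translational",
    "model_ccf",
]

#: names of the model parameters, in canonical order
PARAM_NAMES = ("n_molecules", "tau_d", "s", "f_r", "tau_r", "f_tri", "tau_t")


@dataclass(frozen=True)
class FCSModelParams:
    """Full parameter set of the combined pol-FCS correlation model.

    Parameters
    ----------
    n_molecules:
        Mean number of molecules in the observation volume (> 0).
    tau_d:
        Translational diffusion relaxation time in seconds (> 0).
    s:
        Structural parameter, ratio of the axial to the lateral 1/e^2 radius
        of the observation volume (>= 1).
    f_r:
        Rotational amplitude relative to the translational amplitude.  May be
        negative (crossed-analyzer detection) but must stay above -1 so the
        model remains positive at every lag.
    tau_r:
        Rotational relaxation time in seconds (> 0).
    f_tri:
        Triplet amplitude relative to the translational amplitude (>= 0).
    tau_t:
        Triplet relaxation time in seconds (> 0).
    """

    n_molecules: float
    tau_d: float
    s: float = 5.0
    f_r: float = 0.0
    tau_r: float = 38e-9
    f_tri: float = 0.0
    tau_t: float = 1.24e-6

    def __post_init__(self) -> None:
        for name in ("n_molecules", "tau_d", "tau_r", "tau_t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.s) or self.s < 1:
            raise ValueError(f"s must be >= 1, got {self.s!r}")
        if not np.isfinite(self.f_r) or self.f_r <= -1:
            raise ValueError(f"f_r must be > -1, got {self.f_r!r}")
        if not np.isfinite(self.f_tri) or self.f_tri < 0:
            raise ValueError(f"f_tri must be >= 0, got {self.f_tri!r}")

    def replace(self, **changes) -> "FCSModelParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class PolarizationConfig:
    """One of the four excitation/detection polarization configurations.

    The label encodes excitation polarization and the analyzers in front of
    the two detectors: e.g. ``X-XY`` means x-polarized excitation, channel 0
    behind an x-analyzer and channel 1 behind a y-analyzer (realised by a
    polarizing beam splitter).  ``N`` means no analyzer.  The expected sign of
    the fitted rotational fraction follows the co-/anti-variation of the two
    channels' polarization response: positive for X-XX, X-YY and X-NN,
    negative for the crossed X-XY arrangement.
    """

    label: str
    excitation_axis: tuple = (1.0, 0.0, 0.0)
    detector1_pol: str = "X"
    detector2_pol: str = "X"
    splitter: str = "NPBS"
    expected_fr_sign: str = "+"

    def __post_init__(self) -> None:
        if self.detector1_pol not in ("X", "Y", "N") or self.detector2_pol not in ("X", "Y", "N"):
            raise ValueError("detector polarizations must be one of X, Y, N")
        if self.splitter not in ("NPBS", "PBS"):
            raise ValueError("splitter must be NPBS or PBS")
        if self.expected_fr_sign not in ("+", "-"):
            raise ValueError("expected_fr_sign must be '+' or '-'")
        ax = np.asarray(self.excitation_axis, dtype=float)
        if ax.shape != (3,) or not np.isclose(np.linalg.norm(ax), 1.0):
            raise ValueError("excitation_axis must be a 3-vector of unit norm")


#: the four standard configurations: analyzer/splitter assignments and the
#: sign of the rotational fraction each is expected to produce
POLARIZATION_CONFIGS: dict[str, PolarizationConfig] = {
    "X-XX": PolarizationConfig("X-XX", detector1_pol="X", detector2_pol="X",
                               splitter="NPBS", expected_fr_sign="+"),
    "X-YY": PolarizationConfig("X-YY", detector1_pol="Y", detector2_pol="Y",
                               splitter="NPBS", expected_fr_sign="+"),
    "X-NN": PolarizationConfig("X-NN", detector1_pol="N", detector2_pol="N",
                               splitter="NPBS", expected_fr_sign="+"),
    "X-XY": PolarizationConfig("X-XY", detector1_pol="X", detector2_pol="Y",
                               splitter="PBS", expected_fr_sign="-"),
}


def get_config(config) -> PolarizationConfig:
    """Resolve a configuration given as label or PolarizationConfig."""
    if isinstance(config, PolarizationConfig):
        return config
    if isinstance(config, str):
        try:
            return POLARIZATION_CONFIGS[config]
        except KeyError:
            raise ValueError(
                f"unknown polarization configuration {config!r}; "
                f"expected one of {sorted(POLARIZATION_CONFIGS)}"
            ) from None
    raise TypeError(f"cannot interpret {config!r} as a polarization configuration")


@dataclass
class CorrelationCurve:
    """A correlation curve: lag grid, values, optional per-lag dispersion.

    ``errors`` holds the per-lag standard deviation across repeated
    measurements when the curve is an average of ``n_repeats`` runs.
    ``g_zero`` optionally records the (shot-noise dominated) zero-lag value,
    which is reported but excluded from the fitted lag grid.
    """

    lags: np.ndarray
    values: np.ndarray
    errors: Optional[np.ndarray] = None
    config: Optional[PolarizationConfig] = None
    n_repeats: int = 1
    g_zero: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if self.lags.size and (np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.lags.shape:
                raise ValueError("errors must match lags in length")
            if np.any(self.errors < 0):
                raise ValueError("errors must be >= 0")
        if self.config is not None:
            self.config = get_config(self.config)

    def __len__(self) -> int:
        return self.lags.size

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV with columns lag_s, g, g_sd, config_label, n_repeats."""
        df = pd.DataFrame(
            {
                "lag_s": self.lags,
                "g": self.values,
                "g_sd": self.errors if self.errors is not None else np.full(len(self), np.nan),
                "config_label": self.config.label if self.config else "",
                "n_repeats": self.n_repeats,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationCurve":
        df = pd.read_csv(path)
        errors = df["g_sd"].to_numpy()
        if np.all(np.isnan(errors)):
            errors = None
        label = str(df["config_label"].iloc[0]) if "config_label" in df else ""
        config = get_config(label) if label and label != "nan" else None
        return cls(
            lags=df["lag_s"].to_numpy(),
            values=df["g"].to_numpy(),
            errors=errors,
            config=config,
            n_repeats=int(df["n_repeats"].iloc[0]) if "n_repeats" in df else 1,
        )


def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if not np.all(np.isfinite(tau)) or np.any(tau < 0):
        raise ValueError("tau must be finite and >= 0")
    return tau


def g_translational(tau, params: FCSModelParams):
    """Translational 3D-Gaussian diffusion ACF.

    ``(1/N) (1 + tau/tau_D)^-1 (1 + tau/(s^2 tau_D))^-1/2``.  Equals 1/N at
    zero lag and decays monotonically to zero.
    """
    tau = _check_tau(tau)
    x = tau / params.tau_d
    out = (1.0 / params.n_molecules) / ((1.0 + x) * np.sqrt(1.0 + x / params.s**2))
    return out if out.ndim else float(out)


def model_ccf(tau, params: FCSModelParams):
    """Combined pol-FCS correlation model.

    Translational ACF multiplied by the rotational factor
    ``1 + f_r exp(-tau/tau_r)`` and the triplet factor
    ``1 + f_tri exp(-tau/tau_t)``.  With ``f_r = f_tri = 0`` this reduces to
    :func:`g_translational` exactly; the zero-lag amplitude is
    ``(1/N)(1 + f_r)(1 + f_tri)``.
    """
    tau = _check_tau(tau)
    g = g_translational(tau, params)
    rot = 1.0 + params.f_r * np.exp(-tau / params.tau_r)
    tri = 1.0 + params.f_tri * np.exp(-tau / params.tau_t)
    out = g * rot * tri
    return out if np.ndim(out) else float(out)


def model_curve(lags, params: FCSModelParams, config=None) -> CorrelationCurve:
    """Evaluate the model on a lag grid and wrap as a CorrelationCurve."""
    lags = np.asarray(lags, dtype=float)
    return CorrelationCurve(
        lags=lags,
        values=np.asarray(model_ccf(lags, params), dtype=float),
        config=config,
    )
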