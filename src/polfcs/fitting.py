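"""Single-curve and global least-squares fitting of the pol-FCS model.

The fitting protocol mirrors common practice for polarization-resolved FCS:
curves measured under different optical configurations are fitted together
with the rotational relaxation time shared (it is a molecular property,
independent of the optics), the triplet time fixed to an independently
measured value, and per-curve amplitudes and fractions free — including the
sign of the rotational fraction, so crossed-analyzer curves can fit
negative.

Built on lmfit's bounded trust-region least squares.  Shared parameters are
implemented as a single varying parameter that per-curve parameters are
expression-bound to, which makes them bit-identical across curves in the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .model import CorrelationCurve, FCSModelParams, PARAM_NAMES, model_ccf

__all__ = ["FitSpec", "FitResult", "fit_curve", "fit_global"]

#: default bounds keeping every parameter in its physical domain
DEFAULT_BOUNDS: dict[str, tuple] = {
    "n_molecules": (1e-12, 1e12),
    "tau_d": (1e-12, 1e6),
    "s": (1.0, 1e3),
    "f_r": (-0.999, 1e3),
    "tau_r": (1e-12, 1e3),
    "f_tri": (0.0, 1e3),
    "tau_t": (1e-12, 1e3),
}

#: parameters varied when the caller does not say otherwise
DEFAULT_FREE = ("n_molecules", "tau_d", "f_r", "tau_r")


@dataclass
class FitSpec:
    """What to fit, what to share, what to hold fixed.

    Parameters not listed in ``free_params`` are held at their fixed or
    initial values.  ``shared_params`` (a subset of the free ones) take a
    single common value across all curves.  ``initial`` may map a name to a
    scalar (same start for every curve) or to a sequence with one start per
    curve.  ``weighting`` is ``"inverse_variance"`` (used when curves carry
    per-lag errors) or ``"uniform"``.
    """

    curves: Sequence[CorrelationCurve] = ()
    free_params: Sequence[str] = DEFAULT_FREE
    shared_params: Sequence[str] = ()
    fixed_params: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    weighting: str = "auto"
    lag_floor: float = 0.0
    max_nfev: int = 20000

    def __post_init__(self) -> None:
        for name in (*self.free_params, *self.shared_params,
                     *self.fixed_params, *self.bounds, *self.initial):
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown model parameter {name!r}")
        bad = set(self.shared_params) - set(self.free_params)
        if bad:
            raise ValueError(f"shared parameters must be free: {sorted(bad)}")
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if self.weighting not in ("auto", "uniform", "inverse_variance"):
            raise ValueError("weighting must be auto, uniform or inverse_variance")
        for name, value in self.fixed_params.items():
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not lo <= value <= hi:
                raise ValueError(f"fixed value {name}={value} outside bounds ({lo}, {hi})")


@dataclass
class FitResult:
    """Fitted parameters per curve plus convergence diagnostics."""

    params_per_curve: list
    stderr_per_curve: list
    redchi: float
    success: bool
    nfev: int
    message: str = ""
    shared_values: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    init_residual_norm: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (params, err) in enumerate(zip(self.params_per_curve, self.stderr_per_curve)):
            for name in PARAM_NAMES:
                rows.append(
                    {
                        "curve": i,
                        "parameter": name,
                        "value": getattr(params, name),
                        "stderr": err.get(name, np.nan),
                        "shared": name in self.shared_values,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _guess_initials(curve: CorrelationCurve) -> dict:
    """Heuristic starting values derived from the curve itself."""
    g = curve.values
    lags = curve.lags
    g0 = max(g[0], 1e-9)
    # translational time: first lag at which the curve falls to half its
    # early amplitude, searched on the decades beyond the rotational bump
    half = 0.5 * g0
    below = np.nonzero(g <= half)[0]
    tau_d = lags[below[0]] if below.size else lags[-1] / 3.0
    # translational amplitude read off the plateau after the fast
    # (rotational/triplet) components have relaxed but before the
    # translational decay sets in
    i_plateau = np.searchsorted(lags, tau_d / 20.0)
    plateau = max(float(g[min(i_plateau, len(g) - 1)]), 1e-9)
    excess = g0 / plateau - 1.0
    sign = -1.0 if (curve.config is not None and curve.config.expected_fr_sign == "-") else 1.0
    return {
        "n_molecules": 1.0 / plateau,
        "tau_d": tau_d,
        "s": 5.0,
        "f_r": sign * float(np.clip(abs(excess), 0.05, 5.0)),
        "tau_r": 30e-9,
        # a triplet fraction that is fitted must start away from zero: at
        # f_tri = 0 the model has no gradient along tau_t
        "f_tri": 0.0,
        "f_tri_free": 0.2,
        "tau_t": 1.24e-6,
    }


def _initial_for(spec: FitSpec, name: str, i: int, guess: dict) -> float:
    if name in spec.fixed_params:
        return float(spec.fixed_params[name])
    if name in spec.initial:
        v = spec.initial[name]
        return float(v[i]) if np.ndim(v) else float(v)
    if name in spec.free_params and f"{name}_free" in guess:
        return float(guess[f"{name}_free"])
    return float(guess[name])


def _fit(spec: FitSpec) -> FitResult:
    result = _fit_once(spec)
    # Staged refinement when triplet parameters are fitted without
    # user-supplied starts: the triplet shoulder is easily absorbed by the
    # translational term from a cold start, so fit diffusion and rotation
    # first, then release the triplet terms from that solution and keep the
    # better of the two minima.
    triplet_free = {"f_tri", "tau_t"} & set(spec.free_params)
    if triplet_free and not (triplet_free & set(spec.initial)):
        base = FitSpec(
            curves=spec.curves,
            free_params=tuple(n for n in spec.free_params if n not in triplet_free),
            shared_params=tuple(n for n in spec.shared_params if n not in triplet_free),
            fixed_params={**spec.fixed_params, "f_tri": 0.0},
            bounds=spec.bounds,
            initial={k: v for k, v in spec.initial.items() if k not in triplet_free},
            weighting=spec.weighting,
            lag_floor=spec.lag_floor,
            max_nfev=spec.max_nfev,
        )
        try:
            stage_a = _fit_once(base)
        except ValueError:
            return result
        initial = dict(spec.initial)
        for name in PARAM_NAMES:
            if name in base.free_params:
                initial[name] = [getattr(p, name) for p in stage_a.params_per_curve]
        initial.setdefault("f_tri", 0.2)
        initial.setdefault("tau_t", 1.24e-6)
        staged = _fit_once(
            FitSpec(
                curves=spec.curves,
                free_params=spec.free_params,
                shared_params=spec.shared_params,
                fixed_params=spec.fixed_params,
                bounds=spec.bounds,
                initial=initial,
                weighting=spec.weighting,
                lag_floor=spec.lag_floor,
                max_nfev=spec.max_nfev,
            )
        )
        if staged.residual_norm < result.residual_norm:
            result = staged
    return result


def _fit_once(spec: FitSpec) -> FitResult:
    curves = list(spec.curves)
    if not curves:
        raise ValueError("no curves to fit")
    for c in curves:
        if len(c) < 10:
            raise ValueError("each curve needs at least 10 lags")
        if np.ptp(c.values) == 0:
            raise ValueError("degenerate curve: constant correlation values")

    masks = [c.lags >= spec.lag_floor for c in curves]
    if any(m.sum() < 10 for m in masks):
        raise ValueError("lag_floor leaves fewer than 10 lags on some curve")

    use_errors = spec.weighting == "inverse_variance" or (
        spec.weighting == "auto" and all(c.errors is not None for c in curves)
    )
    if spec.weighting == "inverse_variance" and any(c.errors is None for c in curves):
        raise ValueError("inverse_variance weighting needs per-lag errors on every curve")

    params = lmfit.Parameters()
    for name in spec.shared_params:
        lo, hi = spec.bounds.get(name, DEFAULT_BOUNDS[name])
        params.add(f"g_{name}",
                   value=_initial_for(spec, name, 0, _guess_initials(curves[0])),
                   min=lo, max=hi, vary=True)
    for i, curve in enumerate(curves):
        guess = _guess_initials(curve)
        for name in PARAM_NAMES:
            lo, hi = spec.bounds.get(name, DEFAULT_BOUNDS[name])
            pname = f"c{i}_{name}"
            if name in spec.shared_params:
                params.add(pname, expr=f"g_{name}")
            elif name in spec.free_params:
                params.add(pname, value=_initial_for(spec, name, i, guess),
                           min=lo, max=hi, vary=True)
            else:
                params.add(pname, value=_initial_for(spec, name, i, guess), vary=False)

    weights = []
    for curve, mask in zip(curves, masks):
        if use_errors:
            err = curve.errors[mask].copy()
            positive = err[err > 0]
            floor = positive.min() if positive.size else 1.0
            err[err <= 0] = floor
            weights.append(1.0 / err)
        else:
            weights.append(np.ones(mask.sum()))

    def residual(p):
        parts = []
        for i, (curve, mask, wgt) in enumerate(zip(curves, masks, weights)):
            kwargs = {name: p[f"c{i}_{name}"].value for name in PARAM_NAMES}
            model = model_ccf(curve.lags[mask], FCSModelParams(**kwargs))
            parts.append((model - curve.values[mask]) * wgt)
        return np.concatenate(parts)

    init_norm = float(np.linalg.norm(residual(params)))
    minimizer = lmfit.Minimizer(residual, params)
    result = minimizer.minimize(
        method="least_squares",
        max_nfev=spec.max_nfev,
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )

    per_curve, per_err = [], []
    for i in range(len(curves)):
        values = {name: result.params[f"c{i}_{name}"].value for name in PARAM_NAMES}
        # fixed parameters are reported exactly as fixed
        for name, v in spec.fixed_params.items():
            values[name] = float(v)
        per_curve.append(FCSModelParams(**values))
        per_err.append(
            {
                name: result.params[f"c{i}_{name}"].stderr
                for name in PARAM_NAMES
                if result.params[f"c{i}_{name}"].stderr is not None
            }
        )
    shared = {name: result.params[f"g_{name}"].value for name in spec.shared_params}
    final_norm = float(np.linalg.norm(result.residual))
    return FitResult(
        params_per_curve=per_curve,
        stderr_per_curve=per_err,
        redchi=float(result.redchi),
        success=bool(result.success) and final_norm <= init_norm * (1 + 1e-9),
        nfev=int(result.nfev),
        message=str(result.message),
        shared_values=shared,
        residual_norm=final_norm,
        init_residual_norm=init_norm,
    )


def fit_curve(curve: CorrelationCurve, spec: Optional[FitSpec] = None, **spec_kwargs) -> FitResult:
    """Fit the combined model to a single correlation curve.

    ``spec`` (or keyword arguments forwarded to :class:`FitSpec`) selects
    free/fixed parameters, bounds, initial values and weighting; sharing is
    meaningless for one curve and must be empty.
    """
    if spec is None:
        spec = FitSpec(curves=[curve], **spec_kwargs)
    else:
        spec = FitSpec(
            curves=[curve],
            free_params=spec.free_params,
            shared_params=(),
            fixed_params=spec.fixed_params,
            bounds=spec.bounds,
            initial=spec.initial,
            weighting=spec.weighting,
            lag_floor=spec.lag_floor,
            max_nfev=spec.max_nfev,
        )
    return _fit(spec)


def fit_global(spec: FitSpec) -> FitResult:
    """Global fit of several curves with shared parameters.

    Shared parameters (typically ``tau_r``) take one common value across all
    curves; per-curve parameters remain free, including the sign of ``f_r``.
    A single-curve spec degenerates to :func:`fit_curve`.
    """
    if len(spec.curves) >= 2 and not spec.shared_params:
        raise ValueError("global fit of several curves needs shared_params")
    return _fit(spec)
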