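# polfcs

Polarization-dependent fluorescence correlation spectroscopy (pol-FCS) in
Python: simulate polarized two-channel photon streams from diffusing and
rotating fluorophore multimers, correlate them with a multi-tau estimator,
fit the combined correlation model globally, and estimate hydrodynamic radii
from the ratio of rotational to translational diffusion.

## The problem

Ordinary FCS measures how long fluorescent molecules dwell in a confocal
volume and yields the translational diffusion coefficient `D_T`.  Rotational
diffusion is far more sensitive to molecular size (`D_R ∝ r⁻³` against
`D_T ∝ r⁻¹`) and, unlike `D_T`, needs no volume calibration — but it only
becomes visible when excitation is polarized and the two detection channels
are polarization-resolved.  Cross-correlating two detectors also removes
after-pulsing artifacts in the crucial 10–100 ns window.  The package is
for biophysicists who want to plan, simulate or analyze such measurements:
which polarization configuration produces which signature, how the fitted
rotational fraction `f_R` reflects the mutual orientation of fluorophores in
an oligomer, and how a viscosity series turns fitted times into a radius.

## The model

The two-channel cross-correlation is fitted as

    G(τ) = (1/N) · (1 + τ/τ_D)⁻¹ (1 + τ/(s²τ_D))⁻¹ᐟ² · (1 + f_R e^(−τ/τ_R)) · (1 + f_tri e^(−τ/τ_T))

with `N` the mean occupancy, `τ_D` the dwell time, `s` the axial ratio of
the observation volume, `f_R`/`τ_R` the rotational fraction and relaxation
time, and `f_tri`/`τ_T` the triplet term.  Diffusion coefficients follow as
`D_T = w²/(4τ_D)` and `D_R = 1/(6τ_R)`; for a Stokes sphere
`D_R/D_T = 3/(4r²)`, so a linear fit of `D_R` against `D_T` over a
viscosity series gives the hydrodynamic radius `r = √(3/(4·slope))` with
viscosity and temperature cancelling.

The sign of `f_R` encodes the optics: co-polarized detection (X-XX, X-YY,
X-NN) correlates positively, crossed analyzers (X-XY) anti-correlate.  The
orientational parameter `OP` — the mean squared cosine between distinct
dipole pairs of a multimer — is 1 for perfectly co-oriented fluorophores and
0 for mutually orthogonal ones, and correlates positively with the fitted
`f_R` (see `docs/methods.md` for the detection model and its assumptions).

## Worked example

Simulate an EGFP-like monomer (τ_D = 100 µs, τ_R = 38 ns) in the X-XX
configuration, correlate, fit, and convert to diffusion coefficients:

```python
import numpy as np
from polfcs import (RigidMultimer, SimulationConfig, simulate_photon_traces,
                    multitau_correlate, average_curves, FitSpec, fit_curve,
                    diffusion_from_times, radius_from_slope)

curves = []
for k in range(4):
    cfg = SimulationConfig(d_t=1e-10, d_r=1 / (6 * 38e-9), beam_waist=0.2e-6,
                           s=1.0, box_half_width=1.2e-6, n_molecules_box=310,
                           duration=25e-3, config="X-XX", seed=101 + 17 * k)
    trace = simulate_photon_traces(RigidMultimer.monomer(), cfg)
    curves.append(multitau_correlate(trace, max_lag=2e-3))

fit = fit_curve(average_curves(curves),
                FitSpec(free_params=("n_molecules", "tau_d", "f_r", "tau_r"),
                        fixed_params={"s": 1.0, "f_tri": 0.0, "tau_t": 1.24e-6}))
p = fit.params_per_curve[0]
est = diffusion_from_times(p.tau_d, p.tau_r, beam_waist=0.2e-6)
print(f"tau_D = {p.tau_d*1e6:.1f} us   tau_R = {p.tau_r*1e9:.1f} ns   f_R = {p.f_r:+.2f}")
print(f"D_T = {est.d_t:.3e} m2/s   D_R = {est.d_r:.3e} 1/s")
print(f"radius from D_R/D_T: {radius_from_slope(est.d_r / est.d_t)*1e9:.2f} nm")
```

prints (about two minutes on one CPU)

```
tau_D = 95.8 us   tau_R = 34.5 ns   f_R = +1.24
D_T = 1.044e-10 m2/s   D_R = 4.830e+06 1/s
radius from D_R/D_T: 4.03 nm
```

recovering the simulation set-points `τ_D = 100 µs` and `τ_R = 38 ns`
within a few percent.  `f_R ≈ +1.2` is the co-polarized rotational fraction
of a monomer under the default high-NA optics.  (The radius line combines a
single condition's `D_R/D_T`; with a real viscosity series you would fit the
slope across conditions — see the pipeline below.)  The measured slope
`4.88 × 10¹⁶ m⁻²` reported for EGFP corresponds to

```python
>>> radius_from_slope(4.88e16)
3.9203128011698754e-09        # 3.9 nm
```

## Command line

The same workflows are scriptable via `polfcs` (see
`polfcs.io.example_config()` for the full YAML schema):

```sh
polfcs simulate  -c run.yaml --seed 1 --out out/trace.csv
polfcs correlate out/trace.csv -c run.yaml --out out/curve.csv
polfcs fit       out/curve.csv -c run.yaml --out out/fit.csv
polfcs hydro     -c run.yaml --out out/hydro.csv
polfcs sweep     -c run.yaml --seed 1 --out out/sweep.csv
polfcs pipeline  -c run.yaml --seed 1 --out out/
```

`pipeline` chains the full viscosity-series workflow: simulate each
viscosity at a known radius, correlate and average repeats, fit, regress
`D_R` on `D_T` and report the recovered radius.  `sweep` simulates a family
of multimer geometries and tabulates `OP` against fitted `f_R`.

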