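# Methods

`polfcs` models a polarization-resolved fluorescence correlation
spectroscopy (pol-FCS) measurement end to end: a Brownian-dynamics photon
simulator, a multi-tau correlator, a global fitting layer for the combined
correlation model, and the hydrodynamic analysis that turns fitted
relaxation times into a molecular radius.  This note documents the model,
its assumptions, the numerical choices, and what the synthetic data do and
do not capture.

## The correlation model

The cross-correlation of the two detector channels is modelled as

```
G(tau) = G_D(tau) * (1 + f_R exp(-tau/tau_R)) * (1 + f_tri exp(-tau/tau_T))

G_D(tau) = (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(s^2 tau_D))^-1/2
```

* `N` — mean molecule count in the effective observation volume
  (dimensionless, > 0).
* `tau_D` — translational dwell time (s); `D_T = w^2/(4 tau_D)` with `w`
  the lateral 1/e^2 beam radius.
* `s` — axial/lateral ratio of the 3D-Gaussian observation volume (>= 1).
* `f_R`, `tau_R` — rotational fraction (relative to the translational
  amplitude; sign free) and rotational relaxation time; `D_R = 1/(6 tau_R)`
  requires no volume calibration.
* `f_tri`, `tau_T` — triplet (dark-state) fraction and relaxation time.
  The triplet term is written amplitude-relative, i.e. `1 + f_tri e^-t/tauT`
  rather than the `T/(1-T)` parameterization; conversion is
  `f_tri = T/(1-T)`.

Assumptions: a single diffusing species; one rotational exponential (the
rank-2 orientational spectrum of an isotropic rotor has a single 6·D_R
rate; products of cos^2 responses also contain a 20·D_R rank-4 component
whose weight is small — about 5% of the rank-2 weight in the X-XX
configuration — so a single fitted time lands within a few percent of
1/(6 D_R)); a single two-state triplet; no anomalous diffusion; no
photobleaching or antibunching.

## Polarization configurations and the sign of f_R

The four standard configurations assign analyzers and the beam splitter as

| label | detector 1 | detector 2 | splitter | f_R sign |
|-------|-----------|-----------|----------|----------|
| X-XX  | X         | X         | 50:50    | +        |
| X-YY  | Y         | Y         | 50:50    | +        |
| X-NN  | none      | none      | 50:50    | +        |
| X-XY  | X         | Y         | polarizing | −      |

Co-polarized channels see the same orientational modulation and correlate
positively; crossed channels anti-correlate, producing a rotational dip
(`f_R < 0`).

**A point that is easy to get wrong:** the textbook idealization —
excitation photoselection `(mu.x)^2` and detection `(mu.p)^2` with no
optical mixing — does *not* produce a negative X-XY term.  Expanding the
channel-rate functions in spherical harmonics, the crossed configuration has
rank-2 weight +0.41 and rank-4 weight −0.22 (relative to the product of the
mean rates): the common excitation factor dominates and the net rotational
cross-correlation is *positive*.  The observed negative sign of crossed
detection in real instruments requires partial depolarization of the
excitation at the focus.  The default `OpticsModel` therefore represents a
high-NA epi-illumination instrument:

* **Collection mixing** is computed, not assumed: the far field of x-, y-
  and z-oriented dipoles is propagated through an aplanatic objective
  (NA 1.2, water, collection half-angle 64°) and projected on the analyzer,
  giving channel weights `(1, 0.016, 0.28)` for the parallel, perpendicular
  and axial dipole components.
* **Excitation depolarization** is a single parameter, the isotropic
  fraction of the focal photoselection, default 0.35.  Below ≈0.3 the
  crossed X-XY rank-2 term is still positive; at 0.35 all four
  configurations reproduce the instrument sign rule (X-XX/X-YY/X-NN
  positive, X-XY negative), which is how the default was fixed.  It is a
  property of the simulated instrument, not of the molecule.

`OpticsModel.ideal()` restores the textbook model for studies of the
idealized geometry.

## The Brownian photon simulator

Rigid multimers (unit transition dipoles fixed in a body frame, optional
per-dipole brightness and dark flags) move in a periodic cubic box through a
3D-Gaussian observation volume and rotate isotropically.  Photon counts per
bin are Poisson draws of the accumulated channel intensity plus background.

Numerical scheme and shortcuts (all validated in the test suite):

* **Rotation.** Each fine step applies a rotation vector with independent
  zero-mean increments of variance `2 D_R dt` per axis; this multiplies the
  rank-l orientational modes by `1 − l(l+1) D_R dt` per step, giving the
  P2 relaxation `exp(−6 D_R t)` in the small-step limit (verified to ~1.5%
  at the default `dt = tau_R/50`, consistent with the O(D_R dt) step bias).
  The increments are variance-matched uniforms from an inline splitmix64
  stream: with ≥ 50 steps per relaxation time the accumulated rotation is
  Gaussian by the central limit theorem, and the relaxation factor depends
  only on the increment variance.  The public `rotate_step` uses the
  equivalent Gaussian axis-angle form (angle variance `6 D_R dt`, i.e.
  tangent-displacement variance `4 D_R dt`).
* **Translation** updates once per block (at most `tau_D/100`), since the
  molecule moves a negligible fraction of the beam waist within a block.
  Block increments are variance-matched uniforms as well (≥ 100 per dwell
  time).
* **Observation-region gating.** While a molecule's Gaussian weight is
  below `weight_cutoff` (default 1e-4, with a 4x hysteresis band so that
  boundary grazing does not thrash) its rotation is not integrated; on
  re-entry the kernel applies an equivalent catch-up diffusion, or a fresh
  isotropic orientation if the absence exceeded 12 relaxation times, and
  propagates the triplet state with the exact two-state closed form.  These
  shortcuts are statistically faithful because orientation and blinking are
  ergodic on their own timescales and emit no photons while the molecule is
  dark; the cutoff excludes less than 0.1% of the collected intensity.
* **Timestep and box invariants.** `dt <= min(1/(6 D_R), w^2/(4 D_T))/50`
  and `box_half_width >= 4 s w` are enforced.  The tests use a box of
  6 s w: the discrete diffusion spectrum of the minimal 4 s w periodic box
  biases a fitted `tau_D` by −2.9%, the 6 s w box by −0.9% (computed from
  the exact reciprocal-space correlation of the periodic box).
* **Determinism.** Every molecule derives independent, well-separated
  streams from the master seed; identical seeds give byte-identical traces.

## Orientational parameter

For a multimer with non-dark unit dipoles `mu_n`,

```
OP = mean over distinct pairs (n < m) of (mu_n . mu_m)^2
```

OP = 1 when all dipoles are parallel, 0 when every pair is orthogonal, and
1 for a monomer by convention; it is invariant under global rotations and
per-dipole sign flips.  Note a structural property: because OP is a mean
over *distinct* pairs, its expectation for i.i.d. uniformly random dipoles
is exactly 1/3 for every n ≥ 2 — random n-mers of any size are equally
(dis)oriented on average, and only the monomer (OP = 1) stands above.  The
quantity that *does* decrease systematically with oligomer size is the
fitted rotational fraction, whose orientational variance carries self-pair
terms that scale as 1/n.  Any definition that vanishes for an orthogonal
dimer must exclude self-pairs and therefore shares the flat-mean property;
this is a mathematical constraint, not an implementation choice.

The OP-vs-f_R sweep simulates each family member under identical
conditions, fits with the rotational time held at the configured set-point,
and reports Spearman rank correlation between OP and fitted f_R.

## Fitting protocol

Bounded trust-region least squares (lmfit/`least_squares`, tolerances
1e-12, max 20000 evaluations).  Parameters outside `free_params` are held
fixed (e.g. the triplet time fixed to an independently measured 1.24 us, as
in the standard protocol); `shared_params` (typically `tau_r`) are bound to
a single parameter across curves, making them bit-identical in the result.
Weighting is inverse-variance when per-lag errors from repeat averaging are
present, else uniform.  Initial values are derived from each curve
(amplitude from the post-rotational plateau, `tau_D` from the half-decay
lag, rotational fraction from the short-lag excess, sign from the
configuration).  When triplet parameters are fitted without user starts the
fit is staged — diffusion and rotation first, triplet released second —
because from a cold start the optimizer can absorb the triplet shoulder
into the translational term (a basin with visibly worse chi-square); the
better of the two minima is returned.

## Hydrodynamics

`D_T = w^2/(4 tau_D)`, `D_R = 1/(6 tau_R)`; for a stick-boundary sphere
`D_T = k_B T/(6 pi eta r)` and `D_R = k_B T/(8 pi eta r^3)`, so
`D_R/D_T = 3/(4 r^2)` and `r = sqrt(3/(4 slope))`, independent of viscosity
and temperature.  The slope of `D_R` against `D_T` over a viscosity series
is fitted by ordinary least squares with a free intercept by default (a
through-origin option exists, since the spherical relation implies zero
intercept; which the published analyses use is typically unstated).
Constants are CODATA (`scipy.constants`); temperature defaults to 298.15 K.

## Problem sizes used by the tests

The real measurement protocol this emulates integrates 30 s × 10 repeats.
The test suite scales the photon statistics down and compensates with
brightness (5e7 counts/s per dipole at the volume centre): shot noise only
adds an uncorrelated pedestal, so raising brightness trades the long
integration time for tractable durations without touching the correlation
shape.  Conditions used:

* EGFP-like set-point (w = 0.2 um, tau_D = 100 us, tau_R = 38 ns):
  4 × 25 ms repeats, occupancy ~1, box 6 s w.  Monte Carlo SE of the fitted
  tau_D ≈ 5–7%, tau_R ≈ 4%.
* Fast test condition (w = 0.1 um, tau_D = 5 us, tau_R = 100 ns): 10 ms
  runs (~2000 dwell times) for the sign structure, OP sweep and
  viscosity-scaling checks.
* Triplet runs use w = 0.3 um (tau_D = 45 us) so that the 1.25 us triplet
  shoulder is spectrally separated from both rotation and diffusion.

What the synthetic data do not emulate: detector after-pulsing and dead
time (the cross-correlation design exists to remove after-pulses; they are
not modelled), photobleaching, flexible-linker internal motion of tandem
oligomers (each multimer is one rigid body), saturation, and the axial
elongation of real confocal volumes in most tests (s = 1 keeps the periodic
box small; the model and fits support s > 1 throughout).  Passing tests
therefore demonstrate the correctness of the estimator chain and the
qualitative instrument physics, not instrument-specific artifact handling.

## Known limitations

* The effective single-exponential rotational time of a fitted curve sits
  1–3% below 1/(6 D_R) because of the small rank-4 admixture; this is
  within the quoted tolerances but visible at high precision.
* The excitation depolarization default (0.35 isotropic fraction) is an
  effective instrument parameter chosen to reproduce the standard sign
  rule; it is not derived from vectorial focusing theory, and quantitative
  f_R magnitudes depend on it.
* `f_R` magnitudes from the ideal-optics model are much larger than
  measured values in the literature (e.g. +1.78 relative amplitude for a
  monomer in X-XX); real instruments sit closer to the mixed-optics
  defaults.
* The periodic box leaves a sub-percent bias in fitted dwell times at the
  default box size (see above); quadrupling the box removes it at linear
  cost in molecule count.
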