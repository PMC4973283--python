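"""Numba kernels for the Brownian photon-stream simulator.

The expensive inner loop — rotational diffusion of each rigid body at the
fine timestep, polarized channel intensities, accumulation into photon bins —
lives here.  Translation is updated once per block (the molecule moves a
negligible fraction of the beam waist within a block), and rotation is only
integrated while the molecule is inside the observation region: while the
Gaussian detection weight is below a cutoff the kernel records the elapsed
time and, on re-entry, either applies an equivalent catch-up diffusion or
draws a fresh isotropic orientation when the absence exceeded many
rotational relaxation times.  Both shortcuts are statistically exact to the
accuracy of the small-step integrator because orientation is ergodic on the
rotational timescale and emits no photons while the molecule is dark.

Rotational step.  Each fine step applies the rotation vector
``omega = (wx, wy, wz)`` with independent zero-mean increments of variance
``2 D_R dt`` per axis, which multiplies the rank-l orientational modes by
``1 - l(l+1) D_R dt`` per step and therefore reproduces the rotational
diffusion spectrum (P2 decay ``exp(-6 D_R t)``) in the small-step limit.
The increments are variance-matched uniforms from an inline splitmix64
stream rather than Gaussians: with >= 50 steps per rotational relaxation
time (enforced by the timestep invariant) the accumulated rotation is
Gaussian by the central limit theorem, and the per-step relaxation factor
depends only on the increment variance to O((D_R dt)^2).  The ensemble
relaxation test validates the scheme against the closed form.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["accumulate_intensity", "dipole_p2_relaxation"]

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53
_SQRT3 = math.sqrt(3.0)


@njit(cache=True, inline="always")
def _sm_next(state):
    """splitmix64: returns (new_state, uniform in [0, 1))."""
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    return state, float(z >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _rot_coeffs(state, sig):
    """Draw a rotation vector; return state, axis (unit) and sin/cos terms.

    Increments are uniform with standard deviation ``sig`` per axis; the
    angle is small (|omega| <= 3 sig), so sin/cos use a short series.
    """
    state, u1 = _sm_next(state)
    state, u2 = _sm_next(state)
    state, u3 = _sm_next(state)
    amp = sig * _SQRT3
    wx = amp * (2.0 * u1 - 1.0)
    wy = amp * (2.0 * u2 - 1.0)
    wz = amp * (2.0 * u3 - 1.0)
    t2 = wx * wx + wy * wy + wz * wz
    if t2 < 1e-300:
        return state, 1.0, 0.0, 0.0, 0.0, 1.0
    theta = math.sqrt(t2)
    inv = 1.0 / theta
    t4 = t2 * t2
    st = theta * (1.0 - t2 / 6.0 + t4 / 120.0)
    ct = 1.0 - t2 * 0.5 + t4 / 24.0 - t4 * t2 / 720.0
    return state, wx * inv, wy * inv, wz * inv, st, ct


@njit(cache=True, inline="always")
def _rotate_vec3(vx, vy, vz, ax, ay, az, st, ct):
    dot = ax * vx + ay * vy + az * vz
    cx = ay * vz - az * vy
    cy = az * vx - ax * vz
    cz = ax * vy - ay * vx
    omc = 1.0 - ct
    return (
        vx * ct + cx * st + ax * dot * omc,
        vy * ct + cy * st + ay * dot * omc,
        vz * ct + cz * st + az * dot * omc,
    )


@njit(cache=True, inline="always")
def _renorm_mat(R):
    # Gram-Schmidt on the columns, right-handed
    n0 = math.sqrt(R[0, 0] ** 2 + R[1, 0] ** 2 + R[2, 0] ** 2)
    for i in range(3):
        R[i, 0] /= n0
    d = R[0, 0] * R[0, 1] + R[1, 0] * R[1, 1] + R[2, 0] * R[2, 1]
    for i in range(3):
        R[i, 1] -= d * R[i, 0]
    n1 = math.sqrt(R[0, 1] ** 2 + R[1, 1] ** 2 + R[2, 1] ** 2)
    for i in range(3):
        R[i, 1] /= n1
    R[0, 2] = R[1, 0] * R[2, 1] - R[2, 0] * R[1, 1]
    R[1, 2] = R[2, 0] * R[0, 1] - R[0, 0] * R[2, 1]
    R[2, 2] = R[0, 0] * R[1, 1] - R[1, 0] * R[0, 1]


@njit(cache=True, inline="always")
def _rotate_mat(R, ax, ay, az, st, ct):
    for j in range(3):
        x, y, z = _rotate_vec3(R[0, j], R[1, j], R[2, j], ax, ay, az, st, ct)
        R[0, j] = x
        R[1, j] = y
        R[2, j] = z


@njit(cache=True, inline="always")
def _random_orientation(R):
    """Uniform random rotation matrix from a random unit quaternion."""
    qw = np.random.standard_normal()
    qx = np.random.standard_normal()
    qy = np.random.standard_normal()
    qz = np.random.standard_normal()
    n = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    qw, qx, qy, qz = qw / n, qx / n, qy / n, qz / n
    R[0, 0] = 1 - 2 * (qy * qy + qz * qz)
    R[0, 1] = 2 * (qx * qy - qz * qw)
    R[0, 2] = 2 * (qx * qz + qy * qw)
    R[1, 0] = 2 * (qx * qy + qz * qw)
    R[1, 1] = 1 - 2 * (qx * qx + qz * qz)
    R[1, 2] = 2 * (qy * qz - qx * qw)
    R[2, 0] = 2 * (qx * qz - qy * qw)
    R[2, 1] = 2 * (qy * qz + qx * qw)
    R[2, 2] = 1 - 2 * (qx * qx + qy * qy)


@njit(cache=True, inline="always")
def _diffuse_orientation(R, var_total, rs):
    """Catch-up rotational diffusion by total angle variance var_total.

    Uniform-increment rotation-vector sub-steps of total variance <= 0.5
    rad^2 each (same scheme as the fine step, coarser).  Catch-up happens
    only at the dim edge of the observation region, so the coarser accuracy
    has no visible effect on the correlation functions.
    """
    n_sub = int(var_total / 0.5) + 1
    sig_axis = math.sqrt(var_total / (3.0 * n_sub))
    for _ in range(n_sub):
        rs, ax, ay, az, st, ct = _rot_coeffs(rs, sig_axis)
        _rotate_mat(R, ax, ay, az, st, ct)
    _renorm_mat(R)
    return rs


@njit(cache=True)
def accumulate_intensity(
    lam0,            # (n_bins,) float64, in/out: channel-0 expected counts
    lam1,            # (n_bins,) float64, in/out: channel-1 expected counts
    seed,            # int, master seed; molecule m derives its own streams
    n_mol,           # number of molecules in the box
    steps_per_bin,   # fine steps per photon bin
    block_bins,      # photon bins per translation block
    dt,              # fine timestep, s
    d_t,             # translational diffusion coefficient, m^2/s
    d_r,             # rotational diffusion coefficient, 1/s
    w,               # lateral 1/e^2 beam radius, m
    s_ax,            # axial/lateral ratio of the observation volume
    box_half,        # half width of the periodic cubic box, m
    dip_body,        # (nd, 3) body-frame unit dipoles (non-dark only)
    bright,          # (nd,) per-dipole peak emission rate, counts/s
    exc_a, exc_b,    # excitation factor: exc(mu) = exc_a + exc_b * mux^2
    c0x, c0y, c0z,   # channel-0 detection factor: c0 . (mux^2, muy^2, muz^2)
    c1x, c1y, c1z,   # channel-1 detection factor
    triplet_on,      # bool
    k_isc, k_t,      # triplet entry / exit rates, 1/s
    w_cutoff,        # Gaussian weight below which the molecule is skipped
    init_pos,        # (n_mol, 3) initial positions, or shape (0, 3) for random
):
    nd = dip_body.shape[0]
    n_bins = lam0.shape[0]
    block_steps = block_bins * steps_per_bin
    n_blocks = n_bins // block_bins
    sig_rot = math.sqrt(2.0 * d_r * dt)      # per-axis increment SD
    sig_tr = math.sqrt(2.0 * d_t * (block_steps * dt))
    inv_w2 = 2.0 / (w * w)
    inv_z2 = 2.0 / (s_ax * s_ax * w * w)
    var_limit = 12.0  # re-randomize orientation beyond this total variance
    p_on_eq = k_t / (k_isc + k_t) if triplet_on else 1.0
    k_relax = k_isc + k_t
    p_off = k_isc * dt
    p_on = k_t * dt

    R = np.empty((3, 3))
    on = np.ones(nd, dtype=np.bool_)

    for m in range(n_mol):
        # distinct, well-separated streams for every (seed, molecule) pair
        np.random.seed((seed * 1000003 + (m + 1) * 19349663) & 0x7FFFFFFF)
        rs = (np.uint64(seed) * np.uint64(0x100000001B3)) ^ (
            np.uint64(m + 1) * np.uint64(0xD6E8FEB86659FD93)
        )
        if init_pos.shape[0] > 0:
            x, y, z = init_pos[m, 0], init_pos[m, 1], init_pos[m, 2]
        else:
            x = (2.0 * np.random.random() - 1.0) * box_half
            y = (2.0 * np.random.random() - 1.0) * box_half
            z = (2.0 * np.random.random() - 1.0) * box_half
        _random_orientation(R)
        vx, vy, vz = R[0, 2], R[1, 2], R[2, 2]  # lab dipole of a monomer
        for d in range(nd):
            on[d] = True
            if triplet_on:
                on[d] = np.random.random() < p_on_eq
        skipped_steps = 0
        active = True

        amp_tr = sig_tr * _SQRT3  # variance-matched uniform increments (CLT)
        # hysteresis band around the weight cutoff: a molecule stops being
        # integrated below w_cutoff/4 and resumes above w_cutoff, so grazing
        # the boundary does not trigger a catch-up every block
        w_lo = 0.25 * w_cutoff
        for blk in range(n_blocks):
            if blk > 0:
                rs, u1 = _sm_next(rs)
                rs, u2 = _sm_next(rs)
                rs, u3 = _sm_next(rs)
                x += amp_tr * (2.0 * u1 - 1.0)
                y += amp_tr * (2.0 * u2 - 1.0)
                z += amp_tr * (2.0 * u3 - 1.0)
                if x > box_half:
                    x -= 2.0 * box_half
                elif x < -box_half:
                    x += 2.0 * box_half
                if y > box_half:
                    y -= 2.0 * box_half
                elif y < -box_half:
                    y += 2.0 * box_half
                if z > box_half:
                    z -= 2.0 * box_half
                elif z < -box_half:
                    z += 2.0 * box_half
            wgt = math.exp(-(x * x + y * y) * inv_w2 - z * z * inv_z2)
            if (active and wgt < w_lo) or (not active and wgt < w_cutoff):
                active = False
                skipped_steps += block_steps
                continue
            active = True
            if skipped_steps > 0:
                var_tot = 6.0 * d_r * (skipped_steps * dt)
                if var_tot > var_limit:
                    _random_orientation(R)
                elif var_tot > 0.0:
                    rs = _diffuse_orientation(R, var_tot, rs)
                vx, vy, vz = R[0, 2], R[1, 2], R[2, 2]
                if triplet_on:
                    decay = math.exp(-k_relax * skipped_steps * dt)
                    for d in range(nd):
                        rs, u = _sm_next(rs)
                        p = p_on_eq + ((1.0 if on[d] else 0.0) - p_on_eq) * decay
                        on[d] = u < p
                skipped_steps = 0

            base_bin = blk * block_bins
            scale = wgt * dt
            if nd == 1:
                # monomer fast path: track the lab dipole directly
                b0 = bright[0]
                for bi in range(block_bins):
                    acc0 = 0.0
                    acc1 = 0.0
                    for _ in range(steps_per_bin):
                        if sig_rot > 0.0:
                            rs, ax, ay, az, st, ct = _rot_coeffs(rs, sig_rot)
                            vx, vy, vz = _rotate_vec3(vx, vy, vz, ax, ay, az, st, ct)
                        if triplet_on:
                            rs, u = _sm_next(rs)
                            if on[0]:
                                if u < p_off:
                                    on[0] = False
                            else:
                                if u < p_on:
                                    on[0] = True
                            if not on[0]:
                                continue
                        mx2 = vx * vx
                        my2 = vy * vy
                        mz2 = vz * vz
                        bexc = b0 * (exc_a + exc_b * mx2)
                        acc0 += bexc * (c0x * mx2 + c0y * my2 + c0z * mz2)
                        acc1 += bexc * (c1x * mx2 + c1y * my2 + c1z * mz2)
                    lam0[base_bin + bi] += acc0 * scale
                    lam1[base_bin + bi] += acc1 * scale
                # keep R consistent for catch-up/randomization bookkeeping
                nrm = math.sqrt(vx * vx + vy * vy + vz * vz)
                vx /= nrm
                vy /= nrm
                vz /= nrm
                R[0, 2] = vx
                R[1, 2] = vy
                R[2, 2] = vz
            else:
                for bi in range(block_bins):
                    acc0 = 0.0
                    acc1 = 0.0
                    for _ in range(steps_per_bin):
                        if sig_rot > 0.0:
                            rs, ax, ay, az, st, ct = _rot_coeffs(rs, sig_rot)
                            _rotate_mat(R, ax, ay, az, st, ct)
                        for d in range(nd):
                            if triplet_on:
                                rs, u = _sm_next(rs)
                                if on[d]:
                                    if u < p_off:
                                        on[d] = False
                                else:
                                    if u < p_on:
                                        on[d] = True
                                if not on[d]:
                                    continue
                            bx = dip_body[d, 0]
                            by = dip_body[d, 1]
                            bz = dip_body[d, 2]
                            mx = R[0, 0] * bx + R[0, 1] * by + R[0, 2] * bz
                            my = R[1, 0] * bx + R[1, 1] * by + R[1, 2] * bz
                            mz = R[2, 0] * bx + R[2, 1] * by + R[2, 2] * bz
                            mx2 = mx * mx
                            my2 = my * my
                            mz2 = mz * mz
                            bexc = bright[d] * (exc_a + exc_b * mx2)
                            acc0 += bexc * (c0x * mx2 + c0y * my2 + c0z * mz2)
                            acc1 += bexc * (c1x * mx2 + c1y * my2 + c1z * mz2)
                    lam0[base_bin + bi] += acc0 * scale
                    lam1[base_bin + bi] += acc1 * scale
                _renorm_mat(R)


@njit(cache=True)
def dipole_p2_relaxation(seed, d_r, dt, n_steps, n_traj, record_every):
    """Ensemble mean P2(mu(0) . mu(t)) under the kernel's rotation scheme.

    Independent single dipoles, all starting along z; returns the P2
    autocorrelation sampled every ``record_every`` steps (including t=0).
    Used to validate the uniform-increment integrator against exp(-6 D_R t).
    """
    n_rec = n_steps // record_every + 1
    acc = np.zeros(n_rec)
    sig = math.sqrt(2.0 * d_r * dt)
    for m in range(n_traj):
        rs = (np.uint64(seed) * np.uint64(0x100000001B3)) ^ (
            np.uint64(m + 1) * np.uint64(0xD6E8FEB86659FD93)
        )
        vx, vy, vz = 0.0, 0.0, 1.0
        acc[0] += 1.0
        r = 1
        for i in range(1, n_steps + 1):
            rs, ax, ay, az, st, ct = _rot_coeffs(rs, sig)
            vx, vy, vz = _rotate_vec3(vx, vy, vz, ax, ay, az, st, ct)
            if i % record_every == 0:
                acc[r] += 1.5 * vz * vz - 0.5
                r += 1
    return acc / n_traj
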