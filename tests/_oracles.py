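"""Independent brute-force references used only by the test suite.

The dense integrator below advances the full Bloch--McConnell equations for
the 4-dimensional MQ coherence vector (DQ_A, DQ_B, ZQ_A, ZQ_B) on a dense
time grid (RK4, step <= 1 us) with exactly the same pulse placements and
pulse actions as the analytical propagator: ncyc repetitions of
(tau - piC - tau) where the 13C pi swaps DQ <-> ZQ, and a single 1H pi at
Trelax/2 implemented as DQ/ZQ swap plus complex conjugation.  It shares no
code with the propagator (no matrix exponentials, no binary powers), so
agreement validates the spin-evolution integration numerically.
"""

from __future__ import annotations

import numpy as np

from methylex.exchange import GAMMA_RATIO_C_H, snap_ncyc

_PC = np.zeros((4, 4))
_PC[0, 2] = _PC[1, 3] = _PC[2, 0] = _PC[3, 1] = 1.0  # DQ <-> ZQ swap


def _generator(kex, pm, dw_c_rad, dw_h_rad, r20):
    """Stacked 4x4 free-precession generators, shape (nset, 4, 4)."""
    kex, pm, dw_c_rad, dw_h_rad, r20 = np.broadcast_arrays(
        kex, pm, dw_c_rad, dw_h_rad, r20
    )
    n = kex.shape[0] if kex.ndim else 1
    kf = pm * kex
    kb = (1.0 - pm) * kex
    L = np.zeros((n, 4, 4), dtype=complex)
    for blk, omega in ((0, dw_h_rad + dw_c_rad), (2, dw_h_rad - dw_c_rad)):
        L[:, blk, blk] = -kf - r20
        L[:, blk, blk + 1] = kb
        L[:, blk + 1, blk] = kf
        L[:, blk + 1, blk + 1] = -kb - r20 - 1j * omega
    return L


def _rk4_segment(L, v, duration, max_dt=1e-6):
    nstep = max(int(np.ceil(duration / max_dt)), 1)
    dt = duration / nstep
    for _ in range(nstep):
        k1 = np.einsum("sij,sj->si", L, v)
        k2 = np.einsum("sij,sj->si", L, v + 0.5 * dt * k1)
        k3 = np.einsum("sij,sj->si", L, v + 0.5 * dt * k2)
        k4 = np.einsum("sij,sj->si", L, v + dt * k3)
        v = v + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return v


def dense_mq_r2eff(kex, pm, dw_c_ppm, dw_h_ppm, r20, trelax, nu, field_mhz,
                   max_dt=1e-6):
    """R2,eff by dense RK4 integration; parameters may be 1-d arrays.

    All parameter sets must share the same (nu, trelax, field) so the pulse
    timeline is common; returns an array of rates, one per set.
    """
    kex = np.atleast_1d(np.asarray(kex, dtype=float))
    pm, dw_c_ppm, dw_h_ppm, r20 = (
        np.broadcast_to(np.asarray(x, dtype=float), kex.shape)
        for x in (pm, dw_c_ppm, dw_h_ppm, r20)
    )
    dw_c = 2 * np.pi * field_mhz * GAMMA_RATIO_C_H * dw_c_ppm
    dw_h = 2 * np.pi * field_mhz * dw_h_ppm
    L = _generator(kex, pm, dw_c, dw_h, r20)

    ncyc = snap_ncyc(nu, trelax)
    tau = trelax / (2 * ncyc)
    v = np.zeros((kex.shape[0], 4), dtype=complex)
    v[:, 0] = 1.0 - pm  # equilibrium start, detected on the major state
    v[:, 1] = pm

    def half_element(v):
        for _ in range(ncyc // 2):
            v = _rk4_segment(L, v, tau, max_dt)
            v = np.einsum("ij,sj->si", _PC, v)
            v = _rk4_segment(L, v, tau, max_dt)
        return v

    v = half_element(v)
    v = np.conj(np.einsum("ij,sj->si", _PC, v))  # 1H pi at Trelax/2
    v = half_element(v)
    return -np.log(np.abs(v[:, 0] + v[:, 2]) / (1.0 - pm)) / trelax


def sq_numeric_r2eff(kex, pm, dw_rad, r20, nu, trelax):
    """Single-quantum two-state CPMG by direct 2x2 propagation.

    Independent reduction check: with dwH = 0 the MQ propagator must agree
    with the plain single-quantum case driven by dwC alone.  Pulses are
    implemented as complex conjugation of the magnetisation vector.
    """
    from scipy.linalg import expm

    n = snap_ncyc(nu, trelax)
    tau = trelax / (2 * n)
    kf, kb = pm * kex, (1 - pm) * kex
    L = np.array([[-kf - r20, kb], [kf, -kb - r20 - 1j * dw_rad]])
    U = expm(L * tau)
    v = np.array([1.0 - pm + 0j, pm + 0j])
    for _ in range(n):
        v = U @ v
        v = np.conj(v)
        v = U @ v
    return -np.log(abs(v[0]) / (1.0 - pm)) / trelax


def carver_richards_sq_r2eff(kex, pm, dw_rad, r20, nu, trelax):
    """Closed-form single-quantum two-state R2,eff (Carver--Richards).

    With dwH = 0 the MQ propagator must reduce to the single-quantum case
    driven by dwC alone, for which this classical closed form is an
    independent reference (exact for equal intrinsic rates).
    """
    ncyc = snap_ncyc(nu, trelax)
    tau_cp = trelax / (2 * ncyc)  # delay on either side of each pulse
    pa = 1.0 - pm
    psi = kex**2 - dw_rad**2
    zeta = -2.0 * dw_rad * kex * (pa - pm)
    root = np.sqrt(psi**2 + zeta**2)
    eta_p = np.sqrt(0.5 * (psi + root)) * tau_cp
    eta_m = np.sqrt(0.5 * (-psi + root)) * tau_cp
    d_p = 0.5 * ((psi + 2 * dw_rad**2) / root + 1.0)
    d_m = 0.5 * ((psi + 2 * dw_rad**2) / root - 1.0)
    lam = np.arccosh(d_p * np.cosh(2 * eta_p) - d_m * np.cos(2 * eta_m))
    return r20 + 0.5 * (kex - lam / (2 * tau_cp))
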