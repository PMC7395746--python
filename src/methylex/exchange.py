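"""Two-state multiple-quantum CPMG forward model.

Methyl-TROSY MQ-CPMG relaxation dispersion reports on microsecond--millisecond
exchange between a major (observed) conformational state and a sparsely
populated minor state.  During the constant-time CPMG element the combined
1H-13C multiple-quantum coherence evolves as a superposition of double-quantum
(DQ) and zero-quantum (ZQ) components; 13C refocusing pulses interconvert the
two, and a single 1H refocusing pulse at the midpoint conjugates the proton
part.  This module propagates the resulting 4-dimensional complex coherence
vector (DQ and ZQ, each in states A and B) through the pulse train and returns
the effective transverse relaxation rate

    R2,eff(nu) = -ln(|M(Trelax)| / |M(0)|) / Trelax

as a function of the CPMG frequency nu.  The major state defines the
rotating-frame reference (zero offset); the full chemical-shift difference is
carried by the minor state, whose DQ component precesses at dwH + dwC and ZQ
component at dwH - dwC (rad/s).

Conventions
-----------
* nu_cpmg = n / Trelax with n the number of 13C pi pulses, arranged as n
  repetitions of (tau - pi - tau); the single 1H pi sits at Trelax/2, which
  requires n even.  Requested frequencies are snapped to the nearest
  realisable even n (minimum 2) and the realised frequency is reported
  alongside the requested one.
* Pulses are ideal and instantaneous.
* ppm -> rad/s uses the gyromagnetic ratio of 13C relative to 1H,
  gamma_C/gamma_H = 0.25143, so dwC[rad/s] = 2*pi * field_MHz * 0.25143 * ppm.
* The intrinsic MQ rate R2,0 is one value per site per field, identical for
  the DQ and ZQ coherences and for both states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GAMMA_RATIO_C_H = 0.25143  # gamma(13C)/gamma(1H)

__all__ = [
    "GAMMA_RATIO_C_H",
    "SiteParams",
    "ExchangeParams",
    "CPMGSchedule",
    "snap_ncyc",
    "mq_r2eff",
    "mq_r2eff_curve",
    "rex_amplitude",
    "alpha_value",
    "fast_exchange_shift",
]


@dataclass(frozen=True)
class SiteParams:
    """Residue-specific exchange parameters for one methyl site."""

    dw_c_ppm: float
    dw_h_ppm: float = 0.0
    #: intrinsic MQ rate per static field (1H MHz -> s^-1)
    r20: Mapping[float, float] = field(default_factory=dict)

    def r20_at(self, field_mhz: float) -> float:
        try:
            return float(self.r20[field_mhz])
        except KeyError:
            raise KeyError(
                f"no intrinsic rate R2,0 defined at {field_mhz} MHz "
                f"(available: {sorted(self.r20)})"
            ) from None


@dataclass(frozen=True)
class ExchangeParams:
    """Global two-state exchange model: kex = k_forward + k_backward.

    ``pm`` is the fractional population of the minor state; rates decompose
    as k_forward = pm*kex (major -> minor) and k_backward = (1-pm)*kex.
    """

    kex: float
    pm: float
    sites: Mapping[str, SiteParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kex > 0:
            raise ValueError(f"kex must be positive, got {self.kex}")
        if not 0 <= self.pm < 0.5:
            raise ValueError(f"pm must lie in [0, 0.5), got {self.pm}")

    @property
    def k_forward(self) -> float:
        return self.pm * self.kex

    @property
    def k_backward(self) -> float:
        return (1.0 - self.pm) * self.kex


@dataclass(frozen=True)
class CPMGSchedule:
    """Constant-time CPMG acquisition design at one static field."""

    trelax: float  # s
    nu_cpmg: tuple[float, ...]  # Hz, as requested
    field_mhz: float  # static field as 1H Larmor frequency

    def __post_init__(self) -> None:
        if not self.trelax > 0:
            raise ValueError("Trelax must be positive")
        if any(nu <= 0 for nu in self.nu_cpmg):
            raise ValueError("all CPMG frequencies must be positive")
        if not self.field_mhz > 0:
            raise ValueError("static field must be positive")

    @property
    def realised_nu(self) -> tuple[float, ...]:
        """Requested frequencies snapped to realisable even pulse counts."""
        return tuple(snap_ncyc(nu, self.trelax) / self.trelax for nu in self.nu_cpmg)


def snap_ncyc(nu: float, trelax: float) -> int:
    """Nearest even number of 13C pi pulses realising ``nu`` within ``trelax``.

    The midpoint 1H pulse must fall in a delay, so the pulse count is even
    (minimum 2).
    """
    n = int(round(nu * trelax / 2.0)) * 2
    return max(n, 2)


def _dw_rad(dw_ppm: float, field_mhz: float, nucleus: str) -> float:
    scale = GAMMA_RATIO_C_H if nucleus == "C" else 1.0
    return 2.0 * np.pi * field_mhz * scale * dw_ppm


def _expm2(mat: np.ndarray) -> np.ndarray:
    """Closed-form matrix exponential of stacked complex 2x2 matrices.

    exp(A) = e^mu (cosh(s) I + sinh(s)/s (A - mu I)) with mu = tr(A)/2 and
    s^2 = mu^2 - det(A); the s -> 0 limit is handled via sinch.
    """
    a = mat[..., 0, 0]
    b = mat[..., 0, 1]
    c = mat[..., 1, 0]
    d = mat[..., 1, 1]
    mu = 0.5 * (a + d)
    s2 = 0.25 * (a - d) ** 2 + b * c
    s = np.sqrt(s2.astype(complex))
    small = np.abs(s) < 1e-8
    s_safe = np.where(small, 1.0, s)
    sinch = np.where(small, 1.0 + s2 / 6.0, np.sinh(s_safe) / s_safe)
    cosh = np.cosh(s)
    emu = np.exp(mu)
    out = np.empty(mat.shape, dtype=complex)
    out[..., 0, 0] = emu * (cosh + sinch * (a - mu))
    out[..., 0, 1] = emu * sinch * b
    out[..., 1, 0] = emu * sinch * c
    out[..., 1, 1] = emu * (cosh + sinch * (d - mu))
    return out


def _free_block(kex, pm, omega_b, r20):
    """Evolution+exchange generator for one 2-state coherence block.

    Basis (state A, state B); the minor state B precesses at omega_b rad/s.
    Arrays broadcast; returns (..., 2, 2) complex.
    """
    kf = pm * kex
    kb = (1.0 - pm) * kex
    shape = np.broadcast_shapes(
        np.shape(kex), np.shape(pm), np.shape(omega_b), np.shape(r20)
    )
    L = np.zeros(shape + (2, 2), dtype=complex)
    L[..., 0, 0] = -kf - r20
    L[..., 0, 1] = kb
    L[..., 1, 0] = kf
    L[..., 1, 1] = -kb - r20 - 1j * omega_b
    return L


def _mq_amplitude(kex, pm, dw_c_rad, dw_h_rad, r20, trelax, ncyc):
    """|M_A(Trelax)| for stacked parameter sets and pulse counts.

    All arguments broadcast against ``ncyc`` (integer array).  Propagates the
    (DQ_A, DQ_B, ZQ_A, ZQ_B) vector starting from pure major-state DQ through
    ncyc repetitions of (tau - piC - tau) with the 1H pi at Trelax/2, and
    returns the magnitude of the final major-state DQ component.
    """
    ncyc = np.asarray(ncyc)
    tau = trelax / (2.0 * ncyc)
    L_dq = _free_block(kex, pm, dw_h_rad + dw_c_rad, r20)
    L_zq = _free_block(kex, pm, dw_h_rad - dw_c_rad, r20)
    tau_b = tau[..., None, None]
    U_dq = _expm2(L_dq * tau_b)
    U_zq = _expm2(L_zq * tau_b)

    shape = np.broadcast_shapes(U_dq.shape[:-2], U_zq.shape[:-2])
    U_dq = np.broadcast_to(U_dq, shape + (2, 2))
    U_zq = np.broadcast_to(U_zq, shape + (2, 2))

    # One cycle tau - piC - tau in the 4-dim basis; piC swaps DQ <-> ZQ:
    #   [DQ']   [0  U_dq] [U_dq  0 ] [DQ]
    #   [ZQ'] = [U_zq  0] [0  U_zq] [ZQ]
    # i.e. block form  [[0, U_dq @ U_zq], [U_zq @ U_dq, 0]].
    cyc = np.zeros(shape + (4, 4), dtype=complex)
    cyc[..., 0:2, 2:4] = U_dq @ U_zq
    cyc[..., 2:4, 0:2] = U_zq @ U_dq

    # Half the element = ncyc/2 cycles, via binary exponentiation with
    # per-entry exponents (ncyc varies across the stack).
    m = np.broadcast_to(ncyc, shape).astype(int) // 2
    half = np.broadcast_to(np.eye(4, dtype=complex), shape + (4, 4)).copy()
    base = cyc
    mm = m.copy()
    while np.any(mm > 0):
        odd = (mm & 1).astype(bool)
        if np.any(odd):
            half[odd] = base[odd] @ half[odd]
        mm >>= 1
        if np.any(mm > 0):
            base = base @ base

    # DQ coherence created on both states in proportion to their equilibrium
    # populations; the detected signal is the major-state component,
    # normalised by its initial amplitude (1 - pm).
    v0 = np.zeros(shape + (4,), dtype=complex)
    v0[..., 0] = 1.0 - np.broadcast_to(pm, shape)
    v0[..., 1] = np.broadcast_to(pm, shape)
    v = (half @ v0[..., None])[..., 0]
    # 1H pi at Trelax/2: DQ <-> ZQ swap plus complex conjugation of the vector
    v = np.conj(v[..., [2, 3, 0, 1]])
    v = (half @ v[..., None])[..., 0]
    # After the even number of 13C pulses plus the midpoint 1H swap the
    # surviving coherence sits in exactly one of the two major-state slots;
    # the observable is their (non-interfering) sum.
    amp = np.abs(v[..., 0] + v[..., 2]) / (1.0 - np.broadcast_to(pm, shape))
    if not np.all(np.isfinite(amp)):
        raise FloatingPointError("overflow in MQ propagator (model failure)")
    return amp


def mq_r2eff(
    params: ExchangeParams,
    site: str,
    schedule: CPMGSchedule,
    nu: float,
) -> float:
    """Effective MQ relaxation rate at one CPMG frequency (s^-1).

    ``nu`` is snapped to the nearest realisable even pulse count; use
    :func:`mq_r2eff_curve` to obtain whole dispersion profiles efficiently.
    """
    return float(mq_r2eff_curve(params, site, schedule, [nu])[0])


def mq_r2eff_curve(
    params: ExchangeParams,
    site: str,
    schedule: CPMGSchedule,
    nu: Sequence[float] | None = None,
) -> np.ndarray:
    """Dispersion profile R2,eff(nu) for one site at one field (s^-1)."""
    sp = params.sites[site]
    return _r2eff_raw(
        params.kex,
        params.pm,
        sp.dw_c_ppm,
        sp.dw_h_ppm,
        sp.r20_at(schedule.field_mhz),
        schedule,
        nu,
    )


def _r2eff_raw(kex, pm, dw_c_ppm, dw_h_ppm, r20, schedule, nu=None):
    """Vectorised R2,eff; scalar parameters may be arrays broadcast over nu."""
    if nu is None:
        nu = schedule.nu_cpmg
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    ncyc = np.array([snap_ncyc(v, schedule.trelax) for v in nu])
    if np.isclose(pm, 0.0) or (np.isclose(dw_c_ppm, 0.0) and np.isclose(dw_h_ppm, 0.0)):
        return np.full(nu.shape, float(r20))
    dw_c = _dw_rad(dw_c_ppm, schedule.field_mhz, "C")
    dw_h = _dw_rad(dw_h_ppm, schedule.field_mhz, "H")
    amp = _mq_amplitude(kex, pm, dw_c, dw_h, r20, schedule.trelax, ncyc)
    amp = np.maximum(amp, 1e-300)
    return -np.log(amp) / schedule.trelax


def rex_amplitude(
    params: ExchangeParams, site: str, schedule: CPMGSchedule
) -> float:
    """Exchange contribution Rex = R2,eff(nu_min) - R2,eff(nu_max) (s^-1)."""
    if len(schedule.nu_cpmg) < 2:
        raise ValueError("Rex needs a schedule with at least two frequencies")
    curve = mq_r2eff_curve(params, site, schedule)
    i_min = int(np.argmin(schedule.nu_cpmg))
    i_max = int(np.argmax(schedule.nu_cpmg))
    return float(curve[i_min] - curve[i_max])


def alpha_value(
    params: ExchangeParams,
    site: str,
    field_low: float,
    field_high: float,
    schedule: CPMGSchedule,
) -> float:
    """Exchange-regime exponent from the static-field dependence of Rex.

    alpha = ln(Rex_high / Rex_low) / ln(B_high / B_low); ~0 in slow exchange,
    ~2 in fast exchange.  Returns NaN (undefined) when either Rex <= 0.
    """
    if not field_high > field_low:
        raise ValueError("field_high must exceed field_low")
    rex = []
    for f in (field_low, field_high):
        sched = CPMGSchedule(schedule.trelax, schedule.nu_cpmg, f)
        # carry the site's R2,0 over to the requested field if missing there
        sp = params.sites[site]
        if f not in sp.r20:
            r20_any = next(iter(sp.r20.values()))
            sp = SiteParams(sp.dw_c_ppm, sp.dw_h_ppm, {f: r20_any})
            params = ExchangeParams(params.kex, params.pm, {site: sp})
        rex.append(rex_amplitude(params, site, sched))
    if rex[0] <= 0 or rex[1] <= 0:
        return float("nan")
    return float(np.log(rex[1] / rex[0]) / np.log(field_high / field_low))


def fast_exchange_shift(
    p: float,
    delta_free: tuple[float, float],
    delta_bound: tuple[float, float],
) -> tuple[float, float]:
    """Population-weighted average peak position in the fast-exchange limit.

    Returns the observed (dH, dC) position for bound-state fraction ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"population must lie in [0, 1], got {p}")
    return (
        (1.0 - p) * delta_free[0] + p * delta_bound[0],
        (1.0 - p) * delta_free[1] + p * delta_bound[1],
    )
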