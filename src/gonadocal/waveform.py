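"""Canonical calcium-transient waveform.

A single transient is modelled as a product of exponentials,

    w(t) = A * k * (1 - exp(-t / tau_r)) * exp(-t / tau_d),   t >= 0,

the minimal smooth shape with a fast rise and slow decay that can be pinned
to both of the quantities the analysis reports: peak amplitude ``A`` (dF/F)
and full width at half maximum (seconds).  ``tau_r`` is set to a fixed
fraction of the target half-width and ``tau_d`` is solved numerically so the
realized FWHM matches the target; ``k`` normalizes the peak to ``A``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "peak_time",
    "unit_waveform",
    "solve_decay_tau",
    "fwhm",
    "mass_quantile_time",
    "event_profile",
]

#: FWHM solver tolerance, seconds.
FWHM_TOL_S = 1e-4


def peak_time(tau_r: float, tau_d: float) -> float:
    """Time of the waveform maximum: ``tau_r * ln(1 + tau_d/tau_r)`` (closed form)."""
    return tau_r * np.log1p(tau_d / tau_r)


def _unnormalized(t, tau_r, tau_d):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = -np.expm1(-tp / tau_r) * np.exp(-tp / tau_d)
    return out


def unit_waveform(t, tau_r: float, tau_d: float):
    """Waveform with peak normalized to 1, evaluated at times ``t`` (s)."""
    tp = peak_time(tau_r, tau_d)
    k = 1.0 / _unnormalized(np.array([tp]), tau_r, tau_d)[0]
    return k * _unnormalized(t, tau_r, tau_d)


def fwhm(tau_r: float, tau_d: float) -> float:
    """Full width at half maximum of the unit waveform, by root bracketing."""
    tp = peak_time(tau_r, tau_d)

    def half_excess(t):
        return unit_waveform(np.array([t]), tau_r, tau_d)[0] - 0.5

    left = brentq(half_excess, 1e-12 * tau_r, tp, xtol=FWHM_TOL_S / 10)
    # decay tail: bracket by expanding until below half
    hi = tp * 2 + 3 * tau_d
    while half_excess(hi) > 0:
        hi *= 2
    right = brentq(half_excess, tp, hi, xtol=FWHM_TOL_S / 10)
    return right - left


@lru_cache(maxsize=16384)
def solve_decay_tau(target_fwhm_s: float, rise_fraction: float) -> tuple[float, float]:
    """Solve for ``(tau_r, tau_d)`` so the waveform FWHM equals ``target_fwhm_s``.

    ``tau_r = rise_fraction * target_fwhm_s``; ``tau_d`` found by bisection
    (brentq) to :data:`FWHM_TOL_S`.  FWHM is strictly increasing in ``tau_d``.
    """
    if target_fwhm_s <= 0:
        raise ValueError(f"target FWHM must be positive, got {target_fwhm_s}")
    if not 0 < rise_fraction < 1:
        raise ValueError(f"rise_fraction must lie in (0, 1), got {rise_fraction}")
    tau_r = rise_fraction * target_fwhm_s

    def width_err(tau_d):
        return fwhm(tau_r, tau_d) - target_fwhm_s

    lo, hi = 1e-3 * target_fwhm_s, 3.0 * target_fwhm_s
    while width_err(hi) < 0:
        hi *= 2
    while width_err(lo) > 0:
        lo /= 2
    tau_d = brentq(width_err, lo, hi, xtol=FWHM_TOL_S)
    return tau_r, tau_d


def mass_quantile_time(tau_r: float, tau_d: float, q: float = 0.99) -> float:
    """Time by which a fraction ``q`` of the waveform's integral has elapsed.

    Used to reject evoked events whose tail would be cut by the session end.
    The integral of the unnormalized waveform is available in closed form:
    ``int_0^t = tau_d(1-e^(-t/tau_d)) - tau_e(1-e^(-t/tau_e))`` with
    ``1/tau_e = 1/tau_r + 1/tau_d``.
    """
    tau_e = 1.0 / (1.0 / tau_r + 1.0 / tau_d)

    def cum(t):
        return tau_d * -np.expm1(-t / tau_d) - tau_e * -np.expm1(-t / tau_e)

    total = tau_d - tau_e
    hi = 10 * tau_d
    while cum(hi) < q * total:
        hi *= 2
    return brentq(lambda t: cum(t) - q * total, 0.0, hi, xtol=1e-6 * tau_d)


def event_profile(
    frame_times_s: np.ndarray,
    onset_s: float,
    amplitude: float,
    fwhm_s: float,
    rise_fraction: float,
) -> np.ndarray:
    """Sampled dF/F contribution of one transient starting at ``onset_s``."""
    tau_r, tau_d = solve_decay_tau(fwhm_s, rise_fraction)
    return amplitude * unit_waveform(frame_times_s - onset_s, tau_r, tau_d)
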