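"""Closed-form recovery-curve formulae for the asymptotic regimes.

All formulae assume an ideal experiment: an infinite domain, instantaneous
bleaching of a disk of radius ``r_n`` (Heaviside initial profile) and
radially averaged readout over the same disk.  Time arguments accept scalars
or arrays; every function returns the fluorescence fraction in [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

from .core import PhysicalParams, effective_diffusivity, equilibrium_fractions

__all__ = [
    "soumpasis",
    "soumpasis_series",
    "recovery_rapid_equilibration",
    "recovery_reaction_limited",
    "recovery_first_order",
    "recovery_effective_diffusion",
    "recovery_pure_diffusion",
]


def soumpasis(z):
    """Soumpasis recovery function F_S(z) = e^{-z} (I0(z) + I1(z)).

    The recovery curve of radially symmetric single-species diffusion with a
    Heaviside bleach profile, as a function of the dimensionless argument
    ``z = r_n²/(2 D t)``.  Evaluated with exponentially scaled modified
    Bessel functions, so it neither overflows nor loses the limits
    F_S(0⁺) = 1 and F_S(∞) = 0 for any positive ``z``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("soumpasis argument must be non-negative")
    out = i0e(z) + i1e(z)
    # exact limit at z = 0 (i0e(0) + i1e(0) = 1 already, kept for clarity
    # with +inf arguments, where i0e/i1e return 0)
    out = np.where(np.isinf(z), 0.0, out)
    return out if out.ndim else float(out)


def soumpasis_series(z, n_terms: int = 2):
    """Large-z asymptotic series √(2/(πz)) (1 − 1/(8z) + …) of F_S.

    Retained as an independent cross-check of the scaled-Bessel evaluation;
    the runtime path never needs it.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("series requires z > 0")
    # coefficients of the (I0 + I1)·e^{-z} expansion: sum of the standard
    # Abramowitz–Stegun expansions of I0 and I1
    acc = np.ones_like(z)
    if n_terms >= 2:
        acc = acc - 1.0 / (8.0 * z)
    if n_terms >= 3:
        acc = acc - 15.0 / (128.0 * z**2)
    return np.sqrt(2.0 / (np.pi * z)) * acc


def _fs_of_time(t, r_n: float, D: float):
    """F_S(r_n²/(2 D t)) with the t → 0⁺ and D → 0 limits made explicit."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if D < 0:
        raise ValueError("diffusivity must be non-negative")
    if D == 0.0:
        return np.zeros_like(t) if t.ndim else 0.0
    with np.errstate(divide="ignore"):
        z = np.where(t > 0, r_n**2 / (2.0 * D * t), np.inf)
    return soumpasis(z)


def recovery_pure_diffusion(D: float, r_n: float, t):
    """Single-species diffusive recovery F(t) = F_S(r_n²/(2 D t))."""
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got {D}")
    if r_n <= 0:
        raise ValueError(f"bleach radius must be positive, got {r_n}")
    return _fs_of_time(t, r_n, D)


def recovery_effective_diffusion(params: PhysicalParams, r_n: float, t):
    """Slow-equilibration (η ≪ 1) limit: diffusion at the effective rate.

    When binding equilibrates much faster than transport across the bleach
    region, the total fluorescence diffuses with
    D_eff = u_eq D_u + v_eq D_v and only that combination is identifiable.
    """
    D_eff = effective_diffusivity(params)
    if D_eff <= 0:
        raise ValueError("effective diffusivity is zero; no recovery")
    return recovery_pure_diffusion(D_eff, r_n, t)


def recovery_reaction_limited(params: PhysicalParams, t):
    """Reaction-limited recovery F(t) = 1 − v_eq e^{−k_off t}.

    Valid deep in the rapid-equilibration regime when the free-diffusion
    phase is unresolvably fast and the bound pool is immobile: the only
    visible kinetics is dissociation.
    """
    t = np.asarray(t, dtype=float)
    eq = equilibrium_fractions(params)
    out = 1.0 - eq.v_eq * np.exp(-params.k_off * t)
    return out if out.ndim else float(out)


def recovery_rapid_equilibration(params: PhysicalParams, r_n: float, t):
    """Rapid-equilibration (η ≫ 1) recovery.

    F(t) = u_eq F_S(r_n²/(2 D_u t)) + v_eq (1 − e^{−k_off t} [1 − F_S(r_n²/(2 D_v t))]).

    The free pool recovers diffusively on the fast timescale while the bound
    pool refills by exchange (rate k_off) and, if D_v > 0, by its own slow
    diffusion.  With D_v = 0 the bracket is 1 and the bound term degenerates
    to the reaction-limited exponential.
    """
    if r_n <= 0:
        raise ValueError(f"bleach radius must be positive, got {r_n}")
    t = np.asarray(t, dtype=float)
    eq = equilibrium_fractions(params)
    fs_u = _fs_of_time(t, r_n, params.D_u)
    fs_v = _fs_of_time(t, r_n, params.D_v)
    out = eq.u_eq * fs_u + eq.v_eq * (
        1.0 - np.exp(-params.k_off * t) * (1.0 - fs_v))
    return out if out.ndim else float(out)


def recovery_first_order(params: PhysicalParams, r_n: float, t):
    """First-order-in-1/η extension of the reaction-limited formula.

    F(t) = 1 − v_eq e^{−k_off t}
             − (k_on r_n/(3 D_u)) e^{−k_off t} (k_off + k_on k_off t)/(k_on + k_off).

    Implemented verbatim in the project's fixed unit system.  Note the
    correction prefactor k_on r_n/(3 D_u) carries residual units of 1/μm as
    written, so this formula does not obey the diffusive (D, r_n²) scaling
    invariance of the other curves; it is excluded from scaling property
    tests and offered as the literature states it.
    """
    if params.D_u <= 0:
        raise ValueError("D_u must be positive for the first-order correction")
    t = np.asarray(t, dtype=float)
    base = recovery_reaction_limited(params, t)
    total = params.k_on + params.k_off
    corr = (params.k_on * r_n / (3.0 * params.D_u)) * np.exp(
        -params.k_off * t) * (
        (params.k_off + params.k_on * params.k_off * t) / total)
    out = base - corr
    return out if out.ndim else float(out)
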