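"""Parameter containers, dimensionless groups and the effective diffusivity.

The model describes a fluorescently tagged protein that switches between a
freely diffusing state (concentration ``u``, diffusivity ``D_u``) and a bound
complex (``v``, ``D_v``) through pseudo-first-order binding kinetics with
association rate ``k_on`` (the true bimolecular rate times the constant
binding-site concentration) and dissociation rate ``k_off``.

Units are fixed project-wide: lengths in μm, times in s, diffusivities in
μm²/s, rates in 1/s.  There is no unit-conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np

__all__ = [
    "PhysicalParams",
    "DimensionlessParams",
    "EquilibriumFractions",
    "equilibrium_fractions",
    "dimensionless",
    "params_from_dimensionless",
    "effective_diffusivity",
    "kappa_from_deff",
]


@dataclass(frozen=True)
class PhysicalParams:
    """The four physical unknowns θ = (D_u, D_v, k_on, k_off).

    Attributes
    ----------
    D_u : float
        Diffusivity of the free species (μm²/s).
    D_v : float
        Diffusivity of the bound complex (μm²/s).
    k_on : float
        Pseudo-first-order association rate (1/s).
    k_off : float
        Dissociation rate (1/s).
    """

    D_u: float
    D_v: float
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        vals = (self.D_u, self.D_v, self.k_on, self.k_off)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"parameters must be finite, got {vals}")
        if any(v < 0 for v in vals):
            raise ValueError(f"parameters must be non-negative, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.D_u, self.D_v, self.k_on, self.k_off])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "PhysicalParams":
        D_u, D_v, k_on, k_off = (float(x) for x in np.asarray(theta))
        return cls(D_u, D_v, k_on, k_off)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PhysicalParams":
        known = {f.name for f in fields(cls)}
        extra = set(mapping) - known - {"r_n"}
        if extra:
            raise KeyError(f"unknown parameter keys: {sorted(extra)}")
        missing = known - set(mapping)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(mapping[k]) for k in known})


PARAM_NAMES = ("D_u", "D_v", "k_on", "k_off")


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless groups controlling the recovery dynamics.

    ``delta = D_v/D_u`` compares bound to free mobility, ``kappa =
    k_off/k_on`` is the equilibrium constant ratio, and ``eta = D_u/(k_on
    r_n²)`` compares the diffusion and binding timescales over the bleach
    region of interest.
    """

    delta: float
    kappa: float
    eta: float


@dataclass(frozen=True)
class EquilibriumFractions:
    """Pre-bleach fluorescent fractions; normalised so u_eq + v_eq = 1."""

    u_eq: float
    v_eq: float


def equilibrium_fractions(params: PhysicalParams) -> EquilibriumFractions:
    """Equilibrium free/bound fluorescent fractions.

    With total pre-bleach fluorescence normalised to 1, detailed balance of
    the binding reaction gives ``u_eq = k_off/(k_on+k_off)`` and
    ``v_eq = k_on/(k_on+k_off)``.
    """
    total = params.k_on + params.k_off
    if total <= 0:
        raise ValueError("k_on + k_off must be positive (k_on = k_off = 0 "
                         "leaves the equilibrium undefined)")
    u_eq = params.k_off / total
    # enforce exact complementarity rather than recomputing the ratio
    return EquilibriumFractions(u_eq=u_eq, v_eq=1.0 - u_eq)


def dimensionless(params: PhysicalParams, r_n: float) -> DimensionlessParams:
    """Map physical parameters and a bleach radius to (δ, κ, η)."""
    if r_n <= 0:
        raise ValueError(f"bleach radius must be positive, got {r_n}")
    if params.D_u <= 0 or params.k_on <= 0:
        raise ValueError("D_u and k_on must be positive for the "
                         "dimensionless ratios to be defined")
    return DimensionlessParams(
        delta=params.D_v / params.D_u,
        kappa=params.k_off / params.k_on,
        eta=params.D_u / (params.k_on * r_n**2),
    )


def params_from_dimensionless(D_u: float, delta: float, kappa: float,
                              eta: float, r_n: float) -> PhysicalParams:
    """Inverse of :func:`dimensionless`: rebuild θ from (D_u, δ, κ, η)."""
    if D_u <= 0 or eta <= 0 or r_n <= 0:
        raise ValueError("D_u, eta and r_n must be positive")
    k_on = D_u / (eta * r_n**2)
    return PhysicalParams(D_u=D_u, D_v=delta * D_u, k_on=k_on,
                          k_off=kappa * k_on)


def effective_diffusivity(params: PhysicalParams) -> float:
    """Effective diffusivity of the rapidly equilibrating mixture.

    ``D_eff = (k_on D_v + k_off D_u)/(k_on + k_off)`` is the equilibrium-
    weighted average ``u_eq D_u + v_eq D_v``; when binding and unbinding are
    fast compared with transport the total fluorescence obeys a single
    diffusion equation with this diffusivity.
    """
    total = params.k_on + params.k_off
    if total <= 0:
        raise ValueError("k_on + k_off must be positive")
    return (params.k_on * params.D_v + params.k_off * params.D_u) / total


def kappa_from_deff(D_u: float, D_v: float, D_eff: float,
                    as_printed: bool = False) -> float:
    """Invert the effective diffusivity for the rate ratio κ = k_off/k_on.

    The self-consistent inverse of the effective-diffusivity formula is
    ``κ = (D_eff − D_v)/(D_u − D_eff)``: substituting back reproduces
    ``D_eff`` exactly, and κ → ∞ as D_eff → D_u.  The literature also
    circulates the reciprocal form ``(D_u − D_eff)/(D_eff − D_v)``, which is
    not consistent with the weighted-average definition; it is available
    behind ``as_printed=True`` for audit only.
    """
    if not (D_v < D_eff < D_u):
        raise ValueError(
            f"no consistent kappa: D_eff={D_eff} must lie strictly inside "
            f"(D_v, D_u) = ({D_v}, {D_u})")
    if as_printed:
        return (D_u - D_eff) / (D_eff - D_v)
    return (D_eff - D_v) / (D_u - D_eff)
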