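"""Physical constants, Boltzmann inverse-temperature transforms, and the
metabolic-theory rate equations.

The metabolic theory of ecology (MTE) describes the temperature dependence of
a biological rate with the Boltzmann–Arrhenius factor ``exp(-E/kT)``, where
``E`` is an activation energy in electron-volts, ``k`` the Boltzmann constant
in eV/K, and ``T`` absolute temperature.  Ecosystem-scale rates add a
biomass term ``M_B`` and a size-structure ("mass correction") term
``<m^(alpha-1)> = sum(m^alpha)/sum(m)`` that accounts for the allometric
scaling of per-capita metabolism with body mass.

Everything in this module is pure computation on Kelvin temperatures; Celsius
conversion happens at the I/O boundary (:func:`celsius_to_kelvin`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_EV",
    "O2_UMOL_PER_MG",
    "PhysicalConstants",
    "MetabolicParams",
    "CommunityState",
    "CascadeTheoryParams",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "inv_kT",
    "arrhenius_factor",
    "percapita_rate",
    "ecosystem_rate",
    "biomass_from_rate",
    "mass_corrected_average",
    "cascade_theory_lnratio",
    "activation_energy_from_slope",
]

#: Boltzmann constant in eV/K (CODATA).
BOLTZMANN_EV = 8.617e-5

#: Dissolved-oxygen unit conversion: micromoles of O2 per milligram.
O2_UMOL_PER_MG = 31.25


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants shared across the pipeline.

    Parameters
    ----------
    k : float
        Boltzmann constant, eV/K.
    z : float
        Oxygen unit conversion, umol per mg.
    T_c : float
        Reference temperature in Kelvin.  Defaults to 295.65 K (22.5 C, the
        midpoint of the experimental gradient); in the assembled pipeline it
        is normally replaced by the grand mean of the observed temperatures.
    """

    k: float = BOLTZMANN_EV
    z: float = O2_UMOL_PER_MG
    T_c: float = 295.65

    def __post_init__(self) -> None:
        if self.k <= 0 or self.z <= 0 or self.T_c <= 0:
            raise ValueError("k, z and T_c must all be positive")


@dataclass(frozen=True)
class MetabolicParams:
    """Parameters of a Boltzmann–Arrhenius rate.

    ``b0`` is the normalization constant at the reference temperature
    (gO2 g^-alpha h^-1), ``E`` the activation energy in eV (negative for
    responses that decline with temperature), and ``alpha`` the allometric
    mass-scaling exponent.
    """

    b0: float
    E: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if not math.isfinite(self.E):
            raise ValueError("E must be finite")


@dataclass
class CommunityState:
    """Body-mass composition of one ecosystem.

    ``masses`` are individual body masses in grams, ``V`` the ecosystem
    volume in litres.  Derived quantities: total biomass density
    ``M_B = sum(m_i)/V`` and the mass correction ``<m^(alpha-1)>``.
    """

    masses: Sequence[float]
    V: float = 1.0
    alpha: float = 1.0
    M_B: float = field(init=False)
    J: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if m.size and (m <= 0).any():
            raise ValueError("all body masses must be positive")
        if self.V <= 0:
            raise ValueError("volume must be positive")
        self.J = int(m.size)
        self.M_B = float(m.sum() / self.V)

    @property
    def mass_corr(self) -> float:
        return mass_corrected_average(self.masses, self.alpha)


@dataclass(frozen=True)
class CascadeTheoryParams:
    """Treatment-specific terms of the theoretical trophic-cascade ratio.

    AG = algae + grazers; AGP = algae + grazers + predators.  ``E_b`` and
    ``E_m`` are the (possibly zero) temperature dependences of the
    normalization constants and of the mass-correction terms.  The
    "first-order" metabolic-scaling null sets all four E terms to zero, in
    which case the cascade strength is independent of temperature.
    """

    b0_ag: float = 1.0
    b0_agp: float = 1.0
    masscorr_ag: float = 1.0
    masscorr_agp: float = 1.0
    E_b_ag: float = 0.0
    E_b_agp: float = 0.0
    E_m_ag: float = 0.0
    E_m_agp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b0_ag", "b0_agp", "masscorr_ag", "masscorr_agp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def swapped(self) -> "CascadeTheoryParams":
        """Return the parameter set with AG and AGP roles exchanged."""
        return CascadeTheoryParams(
            b0_ag=self.b0_agp, b0_agp=self.b0_ag,
            masscorr_ag=self.masscorr_agp, masscorr_agp=self.masscorr_ag,
            E_b_ag=self.E_b_agp, E_b_agp=self.E_b_ag,
            E_m_ag=self.E_m_agp, E_m_agp=self.E_m_ag,
        )


def celsius_to_kelvin(t_c):
    """Convert Celsius to Kelvin (array-safe)."""
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


def inv_kT(T, constants: PhysicalConstants = PhysicalConstants()):
    """Inverse thermal energy 1/(kT) in eV^-1 for Kelvin temperature ``T``.

    Strictly decreasing in T; raises for non-positive temperatures.
    """
    T = np.asarray(T, dtype=float)
    if (T <= 0).any():
        raise ValueError("temperature must be positive (Kelvin)")
    out = 1.0 / (constants.k * T)
    return float(out) if out.ndim == 0 else out


def arrhenius_factor(T, T_c=None, E=0.0,
                     constants: PhysicalConstants = PhysicalConstants()):
    """Boltzmann–Arrhenius multiplier exp(-E * (1/kT - 1/kT_c)).

    Equals 1 at ``T == T_c`` or when ``E == 0``.  Positive E means the rate
    increases with temperature.
    """
    if T_c is None:
        T_c = constants.T_c
    out = np.exp(-E * (inv_kT(T, constants) - inv_kT(T_c, constants)))
    return float(out) if np.ndim(out) == 0 else out


def percapita_rate(m, T, p: MetabolicParams,
                   constants: PhysicalConstants = PhysicalConstants()):
    """Per-capita metabolic rate b0 * exp(-E/kT) * m^alpha (gO2/h)."""
    m = np.asarray(m, dtype=float)
    if (m <= 0).any():
        raise ValueError("body mass must be positive")
    out = p.b0 * np.exp(-p.E * inv_kT(T, constants)) * m ** p.alpha
    return float(out) if out.ndim == 0 else out


def mass_corrected_average(masses: Sequence[float], alpha: float) -> float:
    """Mass-corrected average metabolic biomass <m^(alpha-1)>.

    Defined as sum(m^alpha) / sum(m); equals 1 exactly when alpha == 1 and
    m^(alpha-1) for a single individual.
    """
    m = np.asarray(masses, dtype=float)
    if m.size == 0:
        raise ValueError("mass_corrected_average requires at least one mass")
    if (m <= 0).any():
        raise ValueError("all body masses must be positive")
    return float((m ** alpha).sum() / m.sum())


def ecosystem_rate(state: CommunityState, T, p: MetabolicParams,
                   constants: PhysicalConstants = PhysicalConstants()):
    """Ecosystem-scale metabolic rate per unit volume.

    B_R = b0(T_c) * exp(-E * (1/kT - 1/kT_c)) * M_B * <m^(alpha-1)>.
    An empty community returns 0 with a warning.
    """
    if state.J == 0:
        warnings.warn("empty community: ecosystem rate is 0", stacklevel=2)
        return 0.0
    mc = mass_corrected_average(state.masses, p.alpha)
    return arrhenius_factor(T, None, p.E, constants) * p.b0 * state.M_B * mc


def biomass_from_rate(B_R, T, p: MetabolicParams, mass_corr: float,
                      constants: PhysicalConstants = PhysicalConstants()):
    """Invert :func:`ecosystem_rate` for total biomass density M_B.

    M_B = B_R * exp(+E * (1/kT - 1/kT_c)) / (b0 * <m^(alpha-1)>).  Exact
    algebraic inverse: the round-trip M_B -> B_R -> M_B is an identity.
    """
    if mass_corr <= 0:
        raise ValueError("mass correction must be positive")
    denom = p.b0 * mass_corr
    if denom == 0:
        raise ZeroDivisionError("zero divisor in biomass inversion")
    return B_R / (arrhenius_factor(T, None, p.E, constants) * denom)


def cascade_theory_lnratio(theta: CascadeTheoryParams, T,
                           constants: PhysicalConstants = PhysicalConstants()):
    """Theoretical log trophic-cascade strength ln(M_B.AGP / M_B.AG).

    Difference of the two treatment rows:
    [ln b0_AG + ln <m>_AG - (E_b.ag + E_m.ag)/kT]
    - [ln b0_AGP + ln <m>_AGP - (E_b.agp + E_m.agp)/kT].
    Antisymmetric under exchanging the AG and AGP parameter sets, and
    independent of T under the first-order null (all E terms zero).
    """
    x = inv_kT(T, constants)
    row_ag = (math.log(theta.b0_ag) + math.log(theta.masscorr_ag)
              - (theta.E_b_ag + theta.E_m_ag) * x)
    row_agp = (math.log(theta.b0_agp) + math.log(theta.masscorr_agp)
               - (theta.E_b_agp + theta.E_m_agp) * x)
    out = row_ag - row_agp
    return float(out) if np.ndim(out) == 0 else out


def activation_energy_from_slope(slope: float) -> float:
    """Map a fitted slope on 1/kT to the reported temperature dependence E.

    A rate proportional to exp(-E/kT) is log-linear in 1/kT with slope -E,
    so the reported activation energy is minus the fitted slope.  This single
    helper owns the sign convention used everywhere in the package.
    """
    return -slope
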