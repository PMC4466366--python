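"""Heavy-ion ionisation cross-sections by velocity matching and charge
scaling.

A bare ion of charge Z moving with the same velocity as a proton has
Z² times the proton's ionisation cross-section; the velocity match maps the
ion kinetic energy to the proton energy tau = E_ion / (M/M_p).  At low
velocity the ion captures electrons and carries a reduced effective charge
Z* given by the Booth-Grant fit
    Z*/Z = 1 - exp(-1.316 x + 0.112 x² - 0.0650 x³),  x = 100 beta Z^(-2/3),
which becomes a noticeable (few-percent) correction around 0.2 MeV/u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants, CONSTANTS
from .errors import DomainError


@dataclass(frozen=True)
class IonSpec:
    """A projectile ion: bare charge Z and mass in proton-mass units."""

    name: str
    z: int
    mass_ratio: float  # M / M_p

    def __post_init__(self) -> None:
        if self.z < 1:
            raise DomainError(f"ion {self.name}: charge Z must be >= 1")
        if self.mass_ratio <= 0:
            raise DomainError(f"ion {self.name}: mass ratio must be positive")


#: Default projectile table (masses in proton-mass units, A*u/m_p rounded).
DEFAULT_IONS = (
    IonSpec("H", 1, 1.0),
    IonSpec("He", 2, 3.9726),
    IonSpec("Li", 3, 6.9565),
    IonSpec("Be", 4, 8.9425),
    IonSpec("B", 5, 10.7309),
    IonSpec("C", 6, 11.9067),
    IonSpec("N", 7, 13.8928),
    IonSpec("O", 8, 15.8735),
    IonSpec("Si", 14, 27.8442),
    IonSpec("Fe", 26, 55.4679),
)


def matched_ion_energy(ion: IonSpec, tau_proton_ev: float) -> float:
    """Kinetic energy of the ion that has the same velocity as a proton of
    kinetic energy tau:  E_ion = (M/M_p) tau  (valid relativistically)."""
    if tau_proton_ev <= 0:
        raise DomainError("proton energy must be positive")
    return ion.mass_ratio * tau_proton_ev


def matched_proton_energy(ion: IonSpec, e_ion_ev: float) -> float:
    """Inverse of :func:`matched_ion_energy`."""
    if e_ion_ev <= 0:
        raise DomainError("ion energy must be positive")
    return e_ion_ev / ion.mass_ratio


def ion_beta(ion: IonSpec, e_ion_ev: float,
             constants: PhysicalConstants = CONSTANTS) -> float:
    """Relativistic speed beta of the ion from its kinetic energy:
    beta² = 1 - (1 + E/(M c²))⁻²."""
    if e_ion_ev <= 0:
        raise DomainError("ion energy must be positive")
    mc2 = ion.mass_ratio * constants.proton_rest_energy_ev
    gamma = 1.0 + e_ion_ev / mc2
    return math.sqrt(1.0 - 1.0 / (gamma * gamma))


def effective_charge_ratio(z: int, beta: float) -> float:
    """Booth-Grant effective-charge fraction Z*/Z, clamped to [0, 1].

    Zero at beta = 0 (fully neutralised), monotone non-decreasing in beta,
    tends to 1 (bare ion) at high velocity.
    """
    if not 0.0 <= beta < 1.0:
        raise DomainError("require 0 <= beta < 1")
    if z < 1:
        raise DomainError("Z must be >= 1")
    x = 100.0 * beta * z ** (-2.0 / 3.0)
    val = 1.0 - math.exp(-1.316 * x + 0.112 * x * x - 0.0650 * x ** 3)
    return min(max(val, 0.0), 1.0)


def ion_ionisation_dcs(ion: IonSpec, e_ion_ev: float, w_ev, medium, chain,
                       use_effective_charge: bool | None = None,
                       effective_charge_below_mev_per_u: float = 0.2,
                       constants: PhysicalConstants = CONSTANTS):
    """Heavy-ion ionisation DCS (m²/eV): the velocity-matched proton DCS
    scaled by Z² (or Z*² when the effective-charge correction applies).

    ``use_effective_charge=None`` applies the correction automatically below
    ``effective_charge_below_mev_per_u`` (default 0.2 MeV/u); True/False
    force it on/off.  ``chain`` is a :class:`aquatrack.chains.ChainPhysics`.
    """
    if e_ion_ev <= 0:
        raise DomainError("ion energy must be positive")
    tau = matched_proton_energy(ion, e_ion_ev)
    base = chain.proton_ionisation_dcs_summed(tau, w_ev)
    if use_effective_charge is None:
        e_per_u_mev = e_ion_ev / ion.mass_ratio / 1e6
        use_effective_charge = e_per_u_mev < effective_charge_below_mev_per_u
    if use_effective_charge:
        zeff = ion.z * effective_charge_ratio(ion.z, ion_beta(ion, e_ion_ev, constants))
        scale = zeff * zeff
    else:
        scale = float(ion.z) ** 2
    return scale * base
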