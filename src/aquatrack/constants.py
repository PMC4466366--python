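"""Physical constants used throughout the cross-section models.

Internal unit system: energies in eV, lengths in m, cross-sections in m².
Momenta in the Born kinematics are expressed in energy-equivalent units
(masses entered as rest energies, eV), so only ratios of momenta are ever
dimensionful-sensitive; see :mod:`aquatrack.proton`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (defaults: CODATA, except r_e kept at the
    3-digit value conventional in the Seltzer-model literature)."""

    bohr_radius_m: float = 0.529177210903e-10
    rydberg_ev: float = 13.605693122994
    classical_electron_radius_m: float = 2.817e-15
    electron_rest_energy_ev: float = 510998.95
    electron_proton_mass_ratio: float = 1.0 / 1836.15267343
    vacuum_permittivity: float = 8.8541878128e-12  # F/m
    avogadro: float = 6.02214076e23

    @property
    def proton_rest_energy_ev(self) -> float:
        return self.electron_rest_energy_ev / self.electron_proton_mass_ratio

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name} must be strictly positive")


#: Shared default instance; models take a ``constants`` argument so tests can
#: substitute synthetic values, but nearly all callers want this one.
CONSTANTS = PhysicalConstants()
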