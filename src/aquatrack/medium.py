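"""Liquid-water medium description.

The inelastic models treat water as five ionisable molecular orbitals
(1b1, 3a1, 1b2, 2a1, 1a1) and five discrete electronic excitation levels.
Each orbital carries its electron count N_i, binding energy B_i (identified
with the ionisation energy I_i of the Rudd model), mean orbital kinetic
energy U_i and mean radius <r>_i; each excitation level carries a Gaussian
strength function f_i(W) and the linking energy W_0,i of the low-energy
excitation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .constants import PhysicalConstants, CONSTANTS

ORBITAL_LABELS = ("1b1", "3a1", "1b2", "2a1", "1a1")

#: Minimum energy transfer by electronic excitation (eV).
E_MIN_EXCITATION_EV = 7.34


class MediumValidationError(ValueError):
    """Raised when a medium configuration violates the model's contract."""


@dataclass(frozen=True)
class MolecularOrbital:
    """One ionisable shell of the water molecule."""

    index: int
    label: str
    n_electrons: float
    binding_ev: float          # B_i == I_i
    mean_kinetic_ev: float     # U_i
    r_mean_angstrom: float     # informational only; no implemented model uses it
    shell_class: str = "outer"  # "outer" or "inner"

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise MediumValidationError(
                f"orbital {self.label}: n_electrons must be positive")
        for name in ("binding_ev", "mean_kinetic_ev", "r_mean_angstrom"):
            if getattr(self, name) <= 0:
                raise MediumValidationError(
                    f"orbital {self.label}: {name} must be positive")
        if self.shell_class not in ("outer", "inner"):
            raise MediumValidationError(
                f"orbital {self.label}: shell_class must be 'outer' or 'inner'")


@dataclass(frozen=True)
class ExcitationLevel:
    """One discrete electronic excitation level with Gaussian strength f_i(W).

    ``alpha_ev`` is the slope parameter of the low-energy excitation model,
    alpha_i = 4 E_min / ln 2; it is derived from ``e_min_ev`` and validated
    against it on construction.
    """

    index: int
    label: str
    w0_ev: float               # linking energy W_0,i
    gaussian_amplitude: float  # eV (strength scale of f_i)
    gaussian_center_ev: float
    gaussian_width_ev: float
    e_min_ev: float = E_MIN_EXCITATION_EV
    alpha_ev: float = field(default=0.0)

    def __post_init__(self) -> None:
        expected = 4.0 * self.e_min_ev / math.log(2.0)
        if self.alpha_ev == 0.0:
            object.__setattr__(self, "alpha_ev", expected)
        elif abs(self.alpha_ev - expected) > 1e-12 * expected:
            raise MediumValidationError(
                f"level {self.label}: alpha_ev={self.alpha_ev} inconsistent "
                f"with 4*E_min/ln2={expected}")
        if self.gaussian_amplitude < 0 or self.gaussian_width_ev <= 0:
            raise MediumValidationError(
                f"level {self.label}: Gaussian strength must have amplitude >= 0 "
                "and width > 0")

    def strength(self, w_ev):
        """Gaussian strength function f_i(W) >= 0 (vectorised)."""
        w = np.asarray(w_ev, dtype=float)
        z = (w - self.gaussian_center_ev) / self.gaussian_width_ev
        out = self.gaussian_amplitude * np.exp(-0.5 * z * z)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MediumSpec:
    """Validated liquid-water medium: bulk properties plus shell tables."""

    mass_density_g_cm3: float
    molar_mass_g_mol: float
    orbitals: tuple[MolecularOrbital, ...]
    excitation_levels: tuple[ExcitationLevel, ...]

    def __post_init__(self) -> None:
        if self.mass_density_g_cm3 <= 0 or self.molar_mass_g_mol <= 0:
            raise MediumValidationError("density and molar mass must be positive")
        if len(self.orbitals) != 5:
            raise MediumValidationError(
                f"expected exactly 5 molecular orbitals, got {len(self.orbitals)}")
        if len(self.excitation_levels) != 5:
            raise MediumValidationError(
                f"expected exactly 5 excitation levels, got {len(self.excitation_levels)}")
        labels = [o.label for o in self.orbitals]
        if len(set(labels)) != len(labels):
            raise MediumValidationError(f"duplicate orbital labels: {labels}")

    @property
    def number_density_cm3(self) -> float:
        """Molecules per cm³ (density * N_A / molar mass)."""
        return self.mass_density_g_cm3 * CONSTANTS.avogadro / self.molar_mass_g_mol

    @property
    def number_density_m3(self) -> float:
        return self.number_density_cm3 * 1e6

    @property
    def min_binding_ev(self) -> float:
        return min(o.binding_ev for o in self.orbitals)

    def orbital(self, label: str) -> MolecularOrbital:
        for o in self.orbitals:
            if o.label == label:
                return o
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "mass_density_g_cm3": self.mass_density_g_cm3,
            "molar_mass_g_mol": self.molar_mass_g_mol,
            "orbitals": [asdict(o) for o in self.orbitals],
            "excitation_levels": [asdict(l) for l in self.excitation_levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MediumSpec":
        return cls(
            mass_density_g_cm3=d["mass_density_g_cm3"],
            molar_mass_g_mol=d["molar_mass_g_mol"],
            orbitals=tuple(MolecularOrbital(**o) for o in d["orbitals"]),
            excitation_levels=tuple(ExcitationLevel(**l) for l in d["excitation_levels"]),
        )


def orbital_prefactor(orbital: MolecularOrbital,
                      constants: PhysicalConstants = CONSTANTS) -> float:
    """Rudd-model shell prefactor S_i = 4 pi a0^2 N_i (Ry / I_i)^2 in m²."""
    a0 = constants.bohr_radius_m
    ratio = constants.rydberg_ev / orbital.binding_ev
    return 4.0 * math.pi * a0 * a0 * orbital.n_electrons * ratio * ratio
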