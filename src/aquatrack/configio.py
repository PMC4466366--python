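"""YAML configuration loading, validation and hashing.

The schema (see ``data/default.yaml`` for the shipped defaults) has
sections [constants], [medium], [orbitals], [excitation_levels],
[rudd_electron], [rudd_proton], [born_elf], [photo_xs], [ions] and
[transport].  Validation is strict: a missing orbital, a non-positive
energy or an unknown key produces an error naming the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .constants import PhysicalConstants, CONSTANTS
from .dielectric import DrudeELF
from .electron import RuddElectronParams, PowerLawPhotoXS
from .errors import ConfigError
from .ions import IonSpec
from .medium import (MediumSpec, MolecularOrbital, ExcitationLevel,
                     MediumValidationError)
from .proton import RuddProtonParams
from . import chains as _chains
from .transport import SimConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OrbitalCfg(_Strict):
    index: int
    label: str
    n_electrons: float = Field(gt=0)
    binding_ev: float = Field(gt=0)
    mean_kinetic_ev: float = Field(gt=0)
    r_mean_angstrom: float = Field(gt=0)
    shell_class: str = "outer"


class ExcitationCfg(_Strict):
    index: int
    label: str
    w0_ev: float = Field(gt=0)
    gaussian_amplitude: float = Field(ge=0)
    gaussian_center_ev: float = Field(gt=0)
    gaussian_width_ev: float = Field(gt=0)
    e_min_ev: float = 7.34


class MediumCfg(_Strict):
    mass_density_g_cm3: float = Field(gt=0)
    molar_mass_g_mol: float = Field(gt=0)


class RuddElectronSetCfg(_Strict):
    a1: float
    a2: float
    b1: float
    b2: float


class RuddElectronCfg(_Strict):
    liquid: RuddElectronSetCfg = Field(default_factory=lambda: RuddElectronSetCfg(
        a1=0.94, a2=1.13, b1=2.30, b2=22.0))
    inner: RuddElectronSetCfg = Field(default_factory=lambda: RuddElectronSetCfg(
        a1=1.31, a2=0.37, b1=0.00, b2=0.00))


class RuddProtonCfg(_Strict):
    a1: float = 0.97
    b1: float = 82.0
    c1: float = 0.40
    d1: float = -0.30
    e1: float = 0.38
    a2: float = 1.04
    b2: float = 17.3
    c2: float = 0.76
    d2: float = 0.04
    alpha: float = 0.64


class DrudeTermCfg(_Strict):
    e0_ev: float = Field(gt=0)
    gamma_ev: float = Field(gt=0)
    strength_ev2: float = Field(gt=0)


class BornElfCfg(_Strict):
    drude_terms: list[DrudeTermCfg] = Field(default_factory=lambda: [
        DrudeTermCfg(e0_ev=21.4, gamma_ev=13.0, strength_ev2=21.46 ** 2)])


class PhotoXSCfg(_Strict):
    exponent: float = 3.0
    sigma0_cm2: dict[str, float] = Field(default_factory=dict)


class IonCfg(_Strict):
    name: str
    z: int = Field(ge=1)
    mass_ratio: float = Field(gt=0)


class TransportCfg(_Strict):
    box_edge_um: float = Field(default=7.0, gt=0)
    electron_cutoff_ev: float = Field(default=10.0, ge=0)
    proton_cutoff_ev: float = Field(default=100.0, ge=0)
    effective_charge_below_mev_per_u: float = Field(default=0.2, ge=0)


class AquatrackConfig(_Strict):
    """Top-level validated configuration."""

    constants: dict[str, float] = Field(default_factory=dict)
    medium: MediumCfg
    orbitals: list[OrbitalCfg]
    excitation_levels: list[ExcitationCfg]
    rudd_electron: RuddElectronCfg = Field(default_factory=RuddElectronCfg)
    rudd_proton: RuddProtonCfg = Field(default_factory=RuddProtonCfg)
    born_elf: BornElfCfg = Field(default_factory=BornElfCfg)
    photo_xs: PhotoXSCfg = Field(default_factory=PhotoXSCfg)
    ions: list[IonCfg] = Field(default_factory=list)
    transport: TransportCfg = Field(default_factory=TransportCfg)

    # -- runtime objects -----------------------------------------------------
    def physical_constants(self) -> PhysicalConstants:
        return replace(CONSTANTS, **self.constants) if self.constants else CONSTANTS

    def medium_spec(self) -> MediumSpec:
        try:
            return MediumSpec(
                mass_density_g_cm3=self.medium.mass_density_g_cm3,
                molar_mass_g_mol=self.medium.molar_mass_g_mol,
                orbitals=tuple(MolecularOrbital(**o.model_dump())
                               for o in self.orbitals),
                excitation_levels=tuple(ExcitationLevel(**l.model_dump())
                                        for l in self.excitation_levels),
            )
        except MediumValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def rudd_electron_params(self) -> dict[str, RuddElectronParams]:
        return {
            "liquid": RuddElectronParams(**self.rudd_electron.liquid.model_dump()),
            "inner": RuddElectronParams(**self.rudd_electron.inner.model_dump()),
        }

    def rudd_proton_params(self) -> RuddProtonParams:
        return RuddProtonParams(**self.rudd_proton.model_dump())

    def elf(self) -> DrudeELF:
        return DrudeELF(terms=tuple(
            (t.e0_ev, t.gamma_ev, t.strength_ev2)
            for t in self.born_elf.drude_terms))

    def photo_xs_provider(self) -> PowerLawPhotoXS:
        return PowerLawPhotoXS(
            sigma0_m2={k: v * 1e-4 for k, v in self.photo_xs.sigma0_cm2.items()},
            exponent=self.photo_xs.exponent)

    def ion_table(self) -> tuple[IonSpec, ...]:
        return tuple(IonSpec(i.name, i.z, i.mass_ratio) for i in self.ions)

    def chain_physics(self, chain: str) -> "_chains.ChainPhysics":
        return _chains.ChainPhysics(
            medium=self.medium_spec(),
            chain=_chains.chain_by_name(chain),
            rudd_electron=self.rudd_electron_params(),
            rudd_proton=self.rudd_proton_params(),
            photo_xs=self.photo_xs_provider(),
            elf=self.elf(),
            constants=self.physical_constants(),
        )

    def sim_config(self, **overrides) -> SimConfig:
        kwargs = dict(
            box_edge_m=self.transport.box_edge_um * 1e-6,
            electron_cutoff_ev=self.transport.electron_cutoff_ev,
            proton_cutoff_ev=self.transport.proton_cutoff_ev,
        )
        kwargs.update(overrides)
        return SimConfig(**kwargs)

    def config_hash(self) -> str:
        """Stable hash of every physics-relevant field."""
        payload = self.model_dump(mode="json")
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config_text() -> str:
    return (resources.files("aquatrack") / "data/default.yaml").read_text()


def load_config(source: Optional[str | Path | dict] = None) -> AquatrackConfig:
    """Load and validate a configuration.

    ``source`` may be None (shipped defaults), a YAML file path, or an
    already-parsed mapping.
    """
    if source is None:
        raw = yaml.safe_load(default_config_text())
    elif isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text())
    try:
        return AquatrackConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_medium(source: Optional[str | Path | dict] = None) -> MediumSpec:
    """Validated MediumSpec from a config (default config when omitted)."""
    return load_config(source).medium_spec()
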