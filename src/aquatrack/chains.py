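"""Model chains: ordered bindings of physics models to processes over
energy ranges, mirroring the two production track-structure codes.

``ritracks_like``
    electron ionisation: Rudd below 50 keV, Seltzer above;
    electron excitation: Kaplan-Sukhonosov below 100 eV, Kutcher-Green above;
    proton ionisation: Rudd throughout (relativistic velocity substitution).

``geant4dna_like``
    electron ionisation and excitation: Born (dielectric-response) machinery;
    proton ionisation: Rudd below 500 keV, Born above.

Binding intervals are half-open [lo, hi): the lower model applies on
[lo, hi) with no blending at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import PhysicalConstants, CONSTANTS
from .errors import ConfigError
from .medium import MediumSpec, MolecularOrbital, ExcitationLevel
from . import electron as _el
from . import proton as _pr
from .dielectric import DrudeELF

ELECTRON_IONISATION = "electron_ionisation"
ELECTRON_EXCITATION = "electron_excitation"
PROTON_IONISATION = "proton_ionisation"


@dataclass(frozen=True)
class Binding:
    process: str
    model: str
    e_lo_ev: float
    e_hi_ev: float  # exclusive; math.inf for open-ended

    def covers(self, e_ev: float) -> bool:
        return self.e_lo_ev <= e_ev < self.e_hi_ev


@dataclass(frozen=True)
class ModelChain:
    """A named, validated set of (process, model, [E_lo, E_hi)) bindings."""

    name: str
    bindings: tuple[Binding, ...]

    def __post_init__(self) -> None:
        by_process: dict[str, list[Binding]] = {}
        for b in self.bindings:
            by_process.setdefault(b.process, []).append(b)
        for process, bs in by_process.items():
            bs = sorted(bs, key=lambda b: b.e_lo_ev)
            if bs[0].e_lo_ev != 0.0 or bs[-1].e_hi_ev != math.inf:
                raise ConfigError(
                    f"chain {self.name}: process {process} does not tile [0, inf)")
            for lo, hi in zip(bs[1:], bs[:-1]):
                if lo.e_lo_ev != hi.e_hi_ev:
                    raise ConfigError(
                        f"chain {self.name}: process {process} has a gap or "
                        f"overlap at {lo.e_lo_ev} eV")

    def model_for(self, process: str, e_ev: float) -> str:
        for b in self.bindings:
            if b.process == process and b.covers(e_ev):
                return b.model
        raise ConfigError(f"chain {self.name}: no {process} model at {e_ev} eV")


def ritracks_like() -> ModelChain:
    return ModelChain("ritracks_like", (
        Binding(ELECTRON_IONISATION, "rudd", 0.0, 50e3),
        Binding(ELECTRON_IONISATION, "seltzer", 50e3, math.inf),
        Binding(ELECTRON_EXCITATION, "kaplan", 0.0, 100.0),
        Binding(ELECTRON_EXCITATION, "kutcher_green", 100.0, math.inf),
        Binding(PROTON_IONISATION, "rudd", 0.0, math.inf),
    ))


def geant4dna_like() -> ModelChain:
    return ModelChain("geant4dna_like", (
        Binding(ELECTRON_IONISATION, "born", 0.0, math.inf),
        Binding(ELECTRON_EXCITATION, "born_excitation", 0.0, math.inf),
        Binding(PROTON_IONISATION, "rudd", 0.0, 500e3),
        Binding(PROTON_IONISATION, "born", 500e3, math.inf),
    ))


_CHAIN_FACTORIES = {"ritracks_like": ritracks_like, "geant4dna_like": geant4dna_like}


def chain_by_name(name: str) -> ModelChain:
    try:
        return _CHAIN_FACTORIES[name]()
    except KeyError:
        raise ConfigError(
            f"unknown model chain {name!r}; available: {sorted(_CHAIN_FACTORIES)}"
        ) from None


@dataclass
class ChainPhysics:
    """A model chain bound to a concrete medium and parameter sets.

    This is the object the samplers, transport loop and CLI consume: it
    answers "what is the DCS of channel c at (T, W), and which model
    produced it" for every process the chain covers.
    """

    medium: MediumSpec
    chain: ModelChain
    rudd_electron: dict = field(
        default_factory=lambda: dict(_el.RUDD_ELECTRON_DEFAULTS))
    rudd_proton: _pr.RuddProtonParams = field(default_factory=_pr.RuddProtonParams)
    photo_xs: object = _el.zero_photo_xs
    elf: object | None = field(default_factory=DrudeELF)
    velocity_mode: str = "relativistic"
    constants: PhysicalConstants = CONSTANTS

    # -- electron ionisation -------------------------------------------------
    def electron_ionisation_dcs(self, t_ev: float, w_ev,
                                orbital: MolecularOrbital):
        """(model_id, dsigma/dW) for one orbital channel."""
        model = self.chain.model_for(ELECTRON_IONISATION, t_ev)
        if model == "rudd":
            val = _el.rudd_electron_dcs(
                t_ev, w_ev, orbital, _el.rudd_params_for(orbital, self.rudd_electron),
                self.constants)
        elif model == "seltzer":
            val = _el.seltzer_dcs(t_ev, w_ev, orbital, self.photo_xs, self.constants)
        elif model == "born":
            if self.elf is None:
                raise ConfigError("Born electron ionisation requires an ELF")
            val = _pr.born_orbital_dcs(
                t_ev, w_ev, orbital, self.medium,
                self.constants.electron_rest_energy_ev, self.elf,
                self.constants, electron_projectile=True)
        else:
            raise ConfigError(f"unknown electron ionisation model {model!r}")
        return model, val

    def electron_ionisation_support(self, t_ev: float,
                                    orbital: MolecularOrbital):
        return _el.rudd_support(t_ev, orbital)

    # -- electron excitation -------------------------------------------------
    def electron_excitation_dcs(self, t_ev: float, w_ev,
                                level: ExcitationLevel):
        model = self.chain.model_for(ELECTRON_EXCITATION, t_ev)
        if model == "kaplan":
            val = _el.kaplan_dcs(t_ev, w_ev, level, self.constants)
        elif model == "kutcher_green":
            val = _el.kutcher_green_dcs(t_ev, w_ev, level, self.constants)
        elif model == "born_excitation":
            val = self._born_excitation_dcs(t_ev, w_ev, level)
        else:
            raise ConfigError(f"unknown electron excitation model {model!r}")
        return model, val

    def _born_excitation_dcs(self, t_ev: float, w_ev, level: ExcitationLevel):
        """Born-style excitation DCS: the Born kinematic kernel with the
        level's Gaussian strength standing in for the (unavailable)
        channel-resolved part of the ELF; f_i(W)/W plays the role of
        Im(-1/eps)."""
        w = np.atleast_1d(np.asarray(w_ev, dtype=float))
        scalar = np.ndim(w_ev) == 0
        out = np.zeros_like(w)
        mask = (w > 0) & (w < t_ev)
        if np.any(mask):
            wm = w[mask]
            st = math.sqrt(t_ev)
            sr = np.sqrt(t_ev - wm)
            lnratio = np.log((st + sr) / np.maximum(st - sr, 1e-300))
            a0 = self.constants.bohr_radius_m
            n_m3 = self.medium.number_density_m3
            out[mask] = (level.strength(wm) / wm * lnratio
                         / (math.pi * a0 * t_ev * n_m3))
        return float(out[0]) if scalar else out

    def excitation_support(self, t_ev: float, level: ExcitationLevel):
        lo = level.e_min_ev
        hi = min(t_ev, level.gaussian_center_ev + 8.0 * level.gaussian_width_ev)
        return (lo, max(hi, lo))

    # -- proton ionisation ---------------------------------------------------
    def proton_ionisation_dcs(self, e_p_ev: float, w_ev,
                              orbital: MolecularOrbital):
        model = self.chain.model_for(PROTON_IONISATION, e_p_ev)
        if model == "rudd":
            val = _pr.proton_rudd_dcs(e_p_ev, w_ev, orbital, self.rudd_proton,
                                      self.velocity_mode, self.constants)
        elif model == "born":
            if self.elf is None:
                raise ConfigError("Born proton ionisation requires an ELF")
            val = _pr.born_orbital_dcs(
                e_p_ev, w_ev, orbital, self.medium,
                self.constants.proton_rest_energy_ev, self.elf, self.constants)
        else:
            raise ConfigError(f"unknown proton ionisation model {model!r}")
        return model, val

    def proton_ionisation_dcs_summed(self, e_p_ev: float, w_ev):
        """Sum of the per-orbital proton ionisation DCS (m²/eV)."""
        total = None
        for orb in self.medium.orbitals:
            _, val = self.proton_ionisation_dcs(e_p_ev, w_ev, orb)
            total = val if total is None else total + val
        return total

    def proton_support(self, e_p_ev: float, orbital: MolecularOrbital):
        model = self.chain.model_for(PROTON_IONISATION, e_p_ev)
        if model == "rudd":
            hi = _pr.proton_w_max(e_p_ev, orbital, self.rudd_proton,
                                  self.velocity_mode, self.constants)
        else:
            t = e_p_ev * self.constants.electron_proton_mass_ratio
            hi = min(e_p_ev - orbital.binding_ev, 4.0 * t)
        return (0.0, max(hi, 0.0))

    # -- spec-level convenience ------------------------------------------------
    def electron_channel_dcs(self, t_ev: float, w_ev) -> dict:
        """All electron channels at (T, W): {(process, label): (model, value)}."""
        out = {}
        for orb in self.medium.orbitals:
            out[(ELECTRON_IONISATION, orb.label)] = \
                self.electron_ionisation_dcs(t_ev, w_ev, orb)
        for lvl in self.medium.excitation_levels:
            out[(ELECTRON_EXCITATION, lvl.label)] = \
                self.electron_excitation_dcs(t_ev, w_ev, lvl)
        return out


def electron_channel_dcs(t_ev: float, w_ev, medium: MediumSpec, chain,
                         **kwargs) -> dict:
    """Module-level wrapper: chain may be a name or a ModelChain."""
    if isinstance(chain, str):
        chain = chain_by_name(chain)
    return ChainPhysics(medium=medium, chain=chain, **kwargs).electron_channel_dcs(
        t_ev, w_ev)
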