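"""Precomputed per-chain cross-section and sampling tables for transport.

The event loop needs, at every step, the per-channel total cross-sections
at the particle's current energy and a draw from the secondary-energy
distribution of the selected channel.  Both are precomputed here on a
log-spaced primary-energy grid: totals by trapezoid integration of the
channel DCS on dense (512-point, log-spaced) support grids, and energy
losses by inverse-CDF interpolation on those same grids (the log spacing
resolves the steep ~W^-2 tails; the W error within one grid cell is a few
percent of the cell width).  Totals are interpolated linearly in ln E
between rows; spectra use the nearest row, with the sampled W clamped to
the kinematic support at the actual energy inside the transport loop.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .chains import ChainPhysics
from .errors import DomainError
from .sampling import build_sampler


@dataclass(frozen=True)
class Channel:
    kind: str          # "ionisation" | "excitation"
    label: str         # orbital or level label
    binding_ev: float  # B_i for ionisation channels, 0 for excitation


class ChannelTable:
    """Tabulated channels for one projectile species under one chain."""

    def __init__(self, species: str, energies: np.ndarray,
                 channels: list[Channel], sigma: np.ndarray,
                 w_grids, cdfs, models: list[list[str]]):
        self.species = species
        self.energies = energies
        self.ln_e = [math.log(e) for e in energies]
        self.channels = channels
        self.sigma = sigma                    # (n_e, n_ch)
        self.sigma_tot = sigma.sum(axis=1)
        self.w_grids = w_grids                # [row][ch] -> ndarray
        self.cdfs = cdfs                      # [row][ch] -> ndarray
        self.models = models                  # per row, per channel
        self._sig_tot = [float(s) for s in self.sigma_tot]
        self._cum = [list(np.cumsum(row)) for row in sigma]

    # -- lookups -------------------------------------------------------------
    def _row(self, e_ev: float) -> int:
        """Nearest-row index in ln E (clamped to the grid)."""
        ln = math.log(e_ev)
        i = bisect_right(self.ln_e, ln) - 1
        if i < 0:
            return 0
        if i >= len(self.ln_e) - 1:
            return len(self.ln_e) - 1
        return i if (ln - self.ln_e[i]) <= (self.ln_e[i + 1] - ln) else i + 1

    def total_sigma(self, e_ev: float) -> float:
        """Total cross-section (m²), linear in ln E between grid rows."""
        if e_ev <= 0:
            raise DomainError("energy must be positive")
        ln = math.log(e_ev)
        i = bisect_right(self.ln_e, ln) - 1
        if i < 0:
            return self._sig_tot[0] if e_ev >= self.energies[0] else 0.0
        if i >= len(self.ln_e) - 1:
            return self._sig_tot[-1]
        f = (ln - self.ln_e[i]) / (self.ln_e[i + 1] - self.ln_e[i])
        return self._sig_tot[i] + f * (self._sig_tot[i + 1] - self._sig_tot[i])

    def draw(self, e_ev: float, rng) -> tuple[Channel, str, float]:
        """Select a channel and draw an energy transfer at energy ``e_ev``.

        Returns (channel, model id, W).  Raises DomainError if every channel
        is closed at this energy.
        """
        i = self._row(e_ev)
        cum = self._cum[i]
        total = cum[-1]
        if total <= 0.0:
            raise DomainError(f"no open channel at {e_ev} eV")
        u = rng.random() * total
        ci = bisect_right(cum, u)
        if ci >= len(cum):
            ci = len(cum) - 1
        # never land on a closed (zero-sigma) channel at a cum-sum tie
        while ci < len(cum) - 1 and cum[ci] - (cum[ci - 1] if ci else 0.0) <= 0.0:
            ci += 1
        while ci > 0 and cum[ci] - (cum[ci - 1] if ci else 0.0) <= 0.0:
            ci -= 1
        w = float(np.interp(rng.random(), self.cdfs[i][ci], self.w_grids[i][ci]))
        return self.channels[ci], self.models[i][ci], w


def build_channel_table(physics: ChainPhysics, species: str,
                        e_min_ev: float, e_max_ev: float,
                        points_per_decade: int = 16,
                        grid_points: int = 512,
                        include_ionisation: bool = True,
                        include_excitation: bool = True) -> ChannelTable:
    """Tabulate all open channels of ``species`` on a log energy grid."""
    n_e = max(2, int(round(points_per_decade
                           * math.log10(e_max_ev / e_min_ev))) + 1)
    energies = np.geomspace(e_min_ev, e_max_ev, n_e)
    medium = physics.medium

    channels: list[Channel] = []
    makers = []  # (dcs(T, W) -> (model, value), support(T))
    if species == "electron":
        if include_ionisation:
            for orb in medium.orbitals:
                channels.append(Channel("ionisation", orb.label, orb.binding_ev))
                makers.append((
                    lambda t, w, o=orb: physics.electron_ionisation_dcs(t, w, o),
                    lambda t, o=orb: physics.electron_ionisation_support(t, o)))
        if include_excitation:
            for lvl in medium.excitation_levels:
                channels.append(Channel("excitation", lvl.label, 0.0))
                makers.append((
                    lambda t, w, l=lvl: physics.electron_excitation_dcs(t, w, l),
                    lambda t, l=lvl: physics.excitation_support(t, l)))
    elif species == "proton":
        if include_ionisation:
            for orb in medium.orbitals:
                channels.append(Channel("ionisation", orb.label, orb.binding_ev))
                makers.append((
                    lambda t, w, o=orb: physics.proton_ionisation_dcs(t, w, o),
                    lambda t, o=orb: physics.proton_support(t, o)))
    else:
        raise DomainError(f"unknown species {species!r}")

    n_ch = len(channels)
    sigma = np.zeros((n_e, n_ch))
    w_grids, cdfs, models = [], [], []
    empty_grid = np.array([0.0, 1.0])
    empty_cdf = np.array([0.0, 1.0])
    for ie, e in enumerate(energies):
        row_models, row_w, row_cdf = [], [], []
        for ic, (dcs_fn, sup_fn) in enumerate(makers):
            model_holder = {}

            def dcs(w, _fn=dcs_fn, _e=e, _mh=model_holder):
                m, v = _fn(_e, w)
                _mh["m"] = m
                return v

            sampler = build_sampler(dcs, e, sup_fn(e), grid_points,
                                    channel=channels[ic])
            row_models.append(model_holder.get("m", ""))
            if sampler.empty:
                row_w.append(empty_grid)
                row_cdf.append(empty_cdf)
            else:
                sigma[ie, ic] = sampler.sigma_total
                row_w.append(sampler.w_grid)
                row_cdf.append(sampler.cdf)
        models.append(row_models)
        w_grids.append(row_w)
        cdfs.append(row_cdf)
    return ChannelTable(species, energies, channels, sigma, w_grids, cdfs,
                        models)


class TransportTables:
    """Channel tables for every species the transport loop may encounter."""

    def __init__(self, physics: ChainPhysics,
                 electron_range_ev=(8.0, 1.0e6),
                 proton_range_ev=(100.0, 1.0e8),
                 points_per_decade: int = 16,
                 include_ionisation: bool = True,
                 include_excitation: bool = True):
        self.physics = physics
        self.medium = physics.medium
        self.chain_name = physics.chain.name
        self.tables = {
            "electron": build_channel_table(
                physics, "electron", *electron_range_ev,
                points_per_decade=points_per_decade,
                include_ionisation=include_ionisation,
                include_excitation=include_excitation),
            "proton": build_channel_table(
                physics, "proton", *proton_range_ev,
                points_per_decade=points_per_decade,
                include_ionisation=include_ionisation,
                include_excitation=include_excitation),
        }

    def for_species(self, species: str) -> ChannelTable:
        if species == "ion":
            return self.tables["proton"]
        return self.tables[species]
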