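"""Samplers that turn differential cross-sections into energy-loss draws,
free flight lengths and channel choices for the transport loop.

Energy-loss sampling is by tabulated inverse CDF: the DCS is evaluated on a
dense (log-spaced where possible) W grid, integrated cumulatively by the
trapezoid rule, normalised, and inverted by linear interpolation.  The DCS
shapes here are smooth and steeply falling (roughly W^-2 ... W^-3), for
which tabulated inversion is accurate and has deterministic cost.

Reproducibility: one RNG per history, seeded from (master seed, history
index) via ``history_rng``, so histories are independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError


@dataclass
class EnergyLossSampler:
    """Inverse-CDF sampler for one channel at one primary energy."""

    t_ev: float
    channel: object
    w_grid: np.ndarray        # ascending energy-transfer grid (eV)
    cdf: np.ndarray           # normalised CDF on w_grid (0 -> 1)
    sigma_total: float        # integral of the DCS over the support (m²)
    empty: bool = False

    def sample(self, rng: np.random.Generator, n: int | None = None):
        if self.empty:
            raise DomainError("cannot sample from an empty (zero-sigma) sampler")
        u = rng.random(n) if n is not None else rng.random()
        return np.interp(u, self.cdf, self.w_grid)

    def cdf_at(self, w):
        return np.interp(w, self.w_grid, self.cdf)

    def quantile(self, u):
        return np.interp(u, self.cdf, self.w_grid)


def _support_grid(w_lo: float, w_hi: float, n: int) -> np.ndarray:
    """Log-spaced grid on (w_lo, w_hi]; if the support reaches 0 the decades
    below w_hi * 1e-6 are collapsed onto a linear toe so the grid still
    starts exactly at w_lo."""
    if w_lo > 0:
        return np.geomspace(w_lo, w_hi, n)
    toe = w_hi * 1e-6
    head = np.linspace(0.0, toe, max(n // 16, 4), endpoint=False)
    tail = np.geomspace(toe, w_hi, n - head.size)
    return np.concatenate([head, tail])


def build_sampler(dcs: Callable, t_ev: float, support: Sequence[float],
                  grid_points: int = 512, channel: object = None) -> EnergyLossSampler:
    """Tabulate ``dcs`` over ``support`` into an :class:`EnergyLossSampler`.

    A zero total cross-section yields a flagged empty sampler.
    """
    w_lo, w_hi = float(support[0]), float(support[1])
    if not w_hi > w_lo:
        return EnergyLossSampler(t_ev, channel, np.array([0.0, 1.0]),
                                 np.array([0.0, 1.0]), 0.0, empty=True)
    grid = _support_grid(w_lo, w_hi, grid_points)
    vals = np.asarray(dcs(grid), dtype=float)
    if np.any(vals < 0):
        raise DomainError("DCS must be non-negative on its support")
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    sigma = float(cum[-1])
    if sigma <= 0.0 or not math.isfinite(sigma):
        return EnergyLossSampler(t_ev, channel, grid, np.zeros_like(grid),
                                 0.0, empty=True)
    cdf = cum / sigma
    # enforce strict monotonicity for stable inversion
    cdf = np.maximum.accumulate(cdf)
    return EnergyLossSampler(t_ev, channel, grid, cdf, sigma)


def sample_free_path(sigma_total_m2: float, number_density_m3: float,
                     rng: np.random.Generator) -> float:
    """Exponential free-flight length (m) with mean 1/(N sigma); infinite
    when sigma = 0 (the particle escapes without interacting)."""
    if sigma_total_m2 < 0:
        raise DomainError("total cross-section must be non-negative")
    if number_density_m3 <= 0:
        raise DomainError("number density must be positive")
    if sigma_total_m2 == 0.0:
        return math.inf
    lam = 1.0 / (number_density_m3 * sigma_total_m2)
    return -lam * math.log1p(-rng.random())


def select_channel(sigma_by_channel: Sequence[tuple], rng: np.random.Generator):
    """Choose a channel with probability sigma_i / sum(sigma); channels with
    zero cross-section are never selected."""
    channels = [c for c, _ in sigma_by_channel]
    sigmas = np.asarray([s for _, s in sigma_by_channel], dtype=float)
    if np.any(sigmas < 0):
        raise DomainError("channel cross-sections must be non-negative")
    total = sigmas.sum()
    if total <= 0:
        raise DomainError("cannot select a channel: all cross-sections are zero")
    u = rng.random() * total
    acc = 0.0
    for ch, s in zip(channels, sigmas):
        acc += s
        if u < acc and s > 0:
            return ch
    # numerical edge: return the last channel with positive sigma
    for ch, s in zip(reversed(channels), reversed(list(sigmas))):
        if s > 0:
            return ch
    raise DomainError("no channel with positive cross-section")


def history_rng(master_seed: int, history_index: int) -> np.random.Generator:
    """Independent, order-insensitive RNG stream for one history."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed,
                               spawn_key=(history_index,)))
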