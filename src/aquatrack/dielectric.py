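"""Energy-loss-function (ELF) providers for the Born inelastic model.

The Born inverse mean free path needs Im(-1/eps(E, q)), the energy loss
function of liquid water.  Providers are plain callables ``elf(e_ev, q) ->
float`` (vectorised over ``e_ev``); they must be non-negative and zero for
E <= 0.  ``q_independent`` advertises that the provider ignores q, which
lets the single-differential integral use the analytic ln(q+/q-) form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


_ELECTRON_REST_EV = 510998.95


@dataclass(frozen=True)
class DrudeELF:
    """Sum of Drude oscillators with Bethe-ridge momentum dispersion:

    Im(-1/eps)(E, q) = sum_k A_k gamma_k E / [(E0_k(q)² - E²)² + (gamma_k E)²],
    E0_k(q) = E0_k + q²/2m  (impulse-approximation dispersion; q in the
    energy-equivalent momentum units of :func:`aquatrack.proton.born_q_bounds`,
    so q²/2m = q² / (2 mc²)).

    The shipped default is a single oscillator at the 21.4 eV collective
    (plasmon-like) peak of the water ELF, with its strength A fixed by the
    f-sum rule  ∫ E·ELF dE = (pi/2)(hbar omega_pl)², hbar omega_pl = 21.46 eV
    for liquid water (10 electrons/molecule at unit density).  This is a
    deliberately coarse optical-data parameterisation; it is a config input,
    not a fit performed by this package.  ``dispersive=False`` freezes the
    oscillators at their optical positions (q-independent ELF).
    """

    terms: tuple = field(default_factory=lambda: (
        # (E0 [eV], gamma [eV], strength A [eV²])
        (21.4, 13.0, 21.46 ** 2),
    ))
    dispersive: bool = True

    @property
    def q_independent(self) -> bool:
        return not self.dispersive

    def __call__(self, e_ev, q=None):
        e = np.asarray(e_ev, dtype=float)
        if self.dispersive and q is not None:
            qq = np.asarray(q, dtype=float)
            shift = qq * qq / (2.0 * _ELECTRON_REST_EV)
        else:
            shift = np.asarray(0.0)
        e, shift = np.broadcast_arrays(e, shift)
        out = np.zeros_like(e, dtype=float)
        pos = e > 0
        if np.any(pos):
            ep = e[pos]
            sh = shift[pos]
            acc = np.zeros_like(ep)
            for e0, gamma, strength in self.terms:
                e0q = e0 + sh
                acc += strength * gamma * ep / ((e0q * e0q - ep * ep) ** 2
                                                + (gamma * ep) ** 2)
            out[pos] = acc
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConstantELF:
    """Toy ELF equal to ``value`` for E > 0 (analytic-oracle fixture)."""

    value: float = 1.0
    q_independent: bool = True

    def __call__(self, e_ev, q=None):
        e = np.asarray(e_ev, dtype=float)
        out = np.where(e > 0, self.value, 0.0)
        return out if out.ndim else float(out)


def elf_is_q_independent(elf) -> bool:
    return bool(getattr(elf, "q_independent", False))
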