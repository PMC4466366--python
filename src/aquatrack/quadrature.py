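"""Total cross-sections by adaptive quadrature of a W-differential DCS."""

from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

from .errors import NumericalError


def total_cross_section(dcs: Callable[[float], float], t_ev: float,
                        support: Sequence[float], tol: float = 1e-6) -> float:
    """Integrate ``dcs`` (m²/eV) over ``support = (W_lo, W_hi)`` -> m².

    Adaptive quadrature with relative tolerance ``tol``; wide strictly
    positive supports are integrated in ln W (the spectra fall off like
    steep power laws).  Returns 0 for an empty support.  Raises
    :class:`NumericalError` (carrying the achieved estimate) if the
    quadrature cannot reach the requested tolerance.
    """
    w_lo, w_hi = float(support[0]), float(support[1])
    if not w_hi > w_lo:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        if w_lo > 0 and w_hi / w_lo > 50.0:
            val, err = integrate.quad(
                lambda u: float(dcs(math.exp(u))) * math.exp(u),
                math.log(w_lo), math.log(w_hi),
                epsrel=tol, epsabs=0.0, limit=200)
        else:
            val, err = integrate.quad(lambda w: float(dcs(w)), w_lo, w_hi,
                                      epsrel=tol, epsabs=0.0, limit=200)
    if val != 0.0 and err > 50.0 * tol * abs(val):
        raise NumericalError(
            f"quadrature did not converge: estimate={val}, abserr={err}",
            estimate=val)
    return max(val, 0.0)
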