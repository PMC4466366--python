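"""Electron-impact inelastic cross-sections in liquid water.

Ionisation
    * Rudd semiempirical model (Mott-based; secondary electrons are
      indistinguishable from the primary, so the ejected-energy support is
      W in [0, (T - I_i)/2]).  Used by the RITRACKS-like chain below 50 keV.
    * Seltzer model (close + distant collision terms); the distant term is
      driven by a pluggable photoelectric cross-section provider.  Used by
      the RITRACKS-like chain above 50 keV.

Excitation
    * Kutcher-Green model (free-electron Rutherford kernel rho(W) with
      Gaussian level strengths), intended above 100 eV.
    * Kaplan-Sukhonosov / Cobut low-energy model with the velocity factor
      alpha(t) = 4 - 3 exp[-(W - W_0,i)/alpha_i], intended below 100 eV.

All differential cross-sections are per unit secondary/transferred energy
(m²/eV); they are non-negative on their support and exactly zero outside it.
Functions are vectorised over ``W``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .constants import PhysicalConstants, CONSTANTS
from .errors import DomainError, ProviderContractError
from .medium import MolecularOrbital, ExcitationLevel, orbital_prefactor


@dataclass(frozen=True)
class RuddElectronParams:
    """Fit constants (A1, A2, B1, B2) of the Rudd electron model for one
    shell class ('liquid' outer shells or 'inner' shells)."""

    a1: float
    a2: float
    b1: float
    b2: float


#: Default fitted constants for liquid water, by shell class.
RUDD_ELECTRON_DEFAULTS = {
    "liquid": RuddElectronParams(a1=0.94, a2=1.13, b1=2.30, b2=22.0),
    "inner": RuddElectronParams(a1=1.31, a2=0.37, b1=0.00, b2=0.00),
}


def rudd_params_for(orbital: MolecularOrbital,
                    params_by_class=None) -> RuddElectronParams:
    """Select the Rudd parameter set for an orbital ('inner' maps to the
    inner-shell set, everything else to the liquid set)."""
    table = params_by_class or RUDD_ELECTRON_DEFAULTS
    return table["inner"] if orbital.shell_class == "inner" else table["liquid"]


class PhotoXSProvider(Protocol):
    """Maps (orbital, photon energy E in eV) -> photoelectric cross-section
    sigma_PE^i(E) in m²; non-negative, zero below E = B_i."""

    def __call__(self, orbital: MolecularOrbital, e_ev) -> float: ...


@dataclass(frozen=True)
class PowerLawPhotoXS:
    """Simple synthetic photoionisation curve sigma0 * (B_i/E)^p above
    threshold.  Shipped default for the Seltzer distant term; the shape and
    amplitudes are package defaults (editable in config), not literature fits.
    """

    sigma0_m2: dict  # orbital label -> threshold cross-section (m²)
    exponent: float = 3.0

    def __call__(self, orbital: MolecularOrbital, e_ev):
        e = np.asarray(e_ev, dtype=float)
        s0 = self.sigma0_m2.get(orbital.label, 0.0)
        with np.errstate(divide="ignore"):
            out = np.where(e >= orbital.binding_ev,
                           s0 * (orbital.binding_ev / np.maximum(e, 1e-300)) ** self.exponent,
                           0.0)
        return out if out.ndim else float(out)


def zero_photo_xs(orbital: MolecularOrbital, e_ev):
    """Photo-XS provider that is identically zero (close-collision only)."""
    e = np.asarray(e_ev, dtype=float)
    out = np.zeros_like(e)
    return out if out.ndim else 0.0


def _check_tw(t_ev: float, w_ev) -> np.ndarray:
    if t_ev <= 0:
        raise DomainError(f"primary energy T={t_ev} eV must be positive")
    w = np.asarray(w_ev, dtype=float)
    if np.any(w < 0):
        raise DomainError("secondary energy W must be non-negative")
    return w


def rudd_electron_dcs(t_ev: float, w_ev, orbital: MolecularOrbital,
                      params: RuddElectronParams | None = None,
                      constants: PhysicalConstants = CONSTANTS):
    """Rudd differential ionisation cross-section dsigma/dW (m²/eV).

    Zero for T <= I_i and for W outside [0, (T - I_i)/2].
    """
    w_arr = _check_tw(t_ev, w_ev)
    scalar = w_arr.ndim == 0
    w_arr = np.atleast_1d(w_arr)
    i_ev = orbital.binding_ev
    t = t_ev / i_ev
    out = np.zeros_like(w_arr)
    if t > 1.0:
        p = params or rudd_params_for(orbital)
        omega = w_arr / i_ev
        mask = (w_arr <= 0.5 * (t_ev - i_ev)) & (t - omega > 0)
        if np.any(mask):
            om = omega[mask]
            # F1 carries the dipole ln t; F2 is the flat Mott-like term
            f1 = p.a1 * math.log(t) / (t + p.b1)
            f2 = p.a2 / (t + p.b2)
            u = 1.0 + om
            v = t - om
            g1 = 1.0 / u ** 3 + 1.0 / v ** 3 - 1.0 / (u ** 1.5 * v ** 1.5)
            g2 = 1.0 / u ** 2 + 1.0 / v ** 2 - 1.0 / (u * v)
            s_i = orbital_prefactor(orbital, constants)
            val = (s_i / i_ev) * (f1 * g1 + f2 * g2)
            out[mask] = np.maximum(val, 0.0)
    return float(out[0]) if scalar else out


def seltzer_dcs(t_ev: float, w_ev, orbital: MolecularOrbital,
                pe: PhotoXSProvider = zero_photo_xs,
                constants: PhysicalConstants = CONSTANTS):
    """Seltzer differential ionisation cross-section dsigma/dW (m²/eV),
    close-collision plus distant-collision (photoeffect-driven) terms.

    Valid for any T > B_i; the RITRACKS-like chain applies it above 50 keV.
    Support: W in [0, (T - B_i)/2].
    """
    w_arr = _check_tw(t_ev, w_ev)
    scalar = w_arr.ndim == 0
    w_arr = np.atleast_1d(w_arr)
    b = orbital.binding_ev
    u_i = orbital.mean_kinetic_ev
    out = np.zeros_like(w_arr)
    if t_ev > b:
        mask = w_arr <= 0.5 * (t_ev - b)
        if np.any(mask):
            w = w_arr[mask]
            mc2 = constants.electron_rest_energy_ev
            tau = t_ev / mc2
            beta2 = tau * (tau + 2.0) / (tau + 1.0) ** 2
            e = w + b
            tw = t_ev - w
            y = w / u_i
            sy = np.sqrt(y)
            g_i = (8.0 * u_i / (3.0 * math.pi)) * (1.0 / e ** 3 + 1.0 / tw ** 3) * (
                np.arctan(sy) + sy * (y - 1.0) / (y + 1.0) ** 2)
            bracket = (1.0 / e ** 2 + 1.0 / tw ** 2
                       + (tau / (tau + 1.0)) ** 2 / t_ev ** 2
                       - (2.0 * tau + 1.0) / (tau + 1.0) ** 2 / (e * tw)
                       + g_i)
            re = constants.classical_electron_radius_m
            pref = (2.0 * math.pi * re * re * mc2 * orbital.n_electrons
                    / (beta2 * (t_ev + b + u_i)))
            close = pref * np.maximum(bracket, 0.0)
            sig_pe = np.asarray(pe(orbital, e), dtype=float)
            if np.any(sig_pe < 0):
                raise ProviderContractError(
                    "photo-XS provider returned a negative cross-section")
            distant = orbital.n_electrons * sig_pe
            out[mask] = close + distant
    return float(out[0]) if scalar else out


def q_min(t_ev: float, w_ev):
    """Minimum energy transferred in a free-electron collision (eV):
    Q_min = 2T(1 - W/(2T) - sqrt(1 - W/T));  -> W²/(4T) for W << T."""
    w = np.asarray(w_ev, dtype=float)
    if t_ev <= 0:
        raise DomainError("T must be positive")
    if np.any(w < 0) or np.any(w > t_ev):
        raise DomainError("require 0 <= W <= T")
    x = w / t_ev
    out = 2.0 * t_ev * (1.0 - 0.5 * x - np.sqrt(1.0 - x))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def rho_free(t_ev: float, w_ev, constants: PhysicalConstants = CONSTANTS):
    """Free-electron Rutherford kernel rho(W) = 4 pi a0² Ry² / (T W²), m²/eV."""
    w = np.asarray(w_ev, dtype=float)
    if t_ev <= 0:
        raise DomainError("T must be positive")
    if np.any(w < 0):
        raise DomainError("W must be non-negative")
    a0 = constants.bohr_radius_m
    ry = constants.rydberg_ev
    with np.errstate(divide="ignore"):
        out = 4.0 * math.pi * a0 * a0 * ry * ry / (t_ev * w ** 2)
    return out if out.ndim else float(out)


def kutcher_green_dcs(t_ev: float, w_ev, level: ExcitationLevel,
                      constants: PhysicalConstants = CONSTANTS):
    """Kutcher-Green excitation DCS (m²/eV):
    (rho(W)/W) f_i(W) ln(4T/Q_min), clamped to 0 where the log argument <= 1.
    """
    w_arr = _check_tw(t_ev, w_ev)
    scalar = w_arr.ndim == 0
    w_arr = np.atleast_1d(w_arr)
    out = np.zeros_like(w_arr)
    mask = (w_arr > 0) & (w_arr <= t_ev)
    if np.any(mask):
        w = w_arr[mask]
        qm = q_min(t_ev, w)
        with np.errstate(divide="ignore"):
            arg = np.where(qm > 0, 4.0 * t_ev / np.maximum(qm, 1e-300), np.inf)
        ln = np.where(arg > 1.0, np.log(np.maximum(arg, 1.0)), 0.0)
        rho = rho_free(t_ev, w, constants)
        out[mask] = np.maximum(rho / w * level.strength(w) * ln, 0.0)
    return float(out[0]) if scalar else out


def kaplan_dcs(t_ev: float, w_ev, level: ExcitationLevel,
               constants: PhysicalConstants = CONSTANTS):
    """Kaplan-Sukhonosov / Cobut low-energy excitation DCS (m²/eV):
    (rho(W)/W) f_i(W) ln(alpha T / W), alpha = 4 - 3 exp[-(W - W_0,i)/alpha_i].

    Support W >= E_min (minimum excitation transfer, 7.34 eV by default);
    clamped to 0 wherever alpha <= 0 or the log argument <= 1.
    """
    w_arr = _check_tw(t_ev, w_ev)
    scalar = w_arr.ndim == 0
    w_arr = np.atleast_1d(w_arr)
    out = np.zeros_like(w_arr)
    mask = (w_arr >= level.e_min_ev) & (w_arr <= t_ev)
    if np.any(mask):
        w = w_arr[mask]
        alpha = excitation_alpha(w, level)
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = alpha * t_ev / w
        ln = np.where((alpha > 0) & (arg > 1.0), np.log(np.maximum(arg, 1.0)), 0.0)
        rho = rho_free(t_ev, w, constants)
        out[mask] = np.maximum(rho / w * level.strength(w) * ln, 0.0)
    return float(out[0]) if scalar else out


def excitation_alpha(w_ev, level: ExcitationLevel):
    """Velocity factor alpha(W) = 4 - 3 exp[-(W - W_0,i)/alpha_i] of the
    low-energy excitation model; equals 1 at W = W_0,i, tends to 4 as W grows."""
    w = np.asarray(w_ev, dtype=float)
    z = np.clip(-(w - level.w0_ev) / level.alpha_ev, -700.0, 700.0)
    out = 4.0 - 3.0 * np.exp(z)
    return out if out.ndim else float(out)


def rudd_support(t_ev: float, orbital: MolecularOrbital) -> tuple[float, float]:
    """Ejected-energy support [0, (T - I_i)/2] of the electron-impact models
    (empty when T <= I_i)."""
    hi = 0.5 * (t_ev - orbital.binding_ev)
    return (0.0, max(hi, 0.0))
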