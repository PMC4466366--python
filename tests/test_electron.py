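"""Electron ionisation and excitation cross-section models."""

import math

import numpy as np
import pytest

import aquatrack as aq
from aquatrack.electron import (rudd_electron_dcs, seltzer_dcs, q_min,
                                rho_free, kutcher_green_dcs, kaplan_dcs,
                                excitation_alpha, rudd_support,
                                RuddElectronParams, zero_photo_xs)
from aquatrack.errors import DomainError, ConfigError, ProviderContractError
from aquatrack.medium import MolecularOrbital, ExcitationLevel
from aquatrack.quadrature import total_cross_section
from aquatrack.report import generate_fixtures


A0 = aq.CONSTANTS.bohr_radius_m
RY = aq.CONSTANTS.rydberg_ev
MC2 = aq.CONSTANTS.electron_rest_energy_ev
RE = aq.CONSTANTS.classical_electron_radius_m


def rudd_oracle(T, W, I, N, A1, A2, B1, B2):
    """Independent single-expression transcription of the Rudd electron DCS."""
    t, w, S = T / I, W / I, 4 * math.pi * A0**2 * N * (RY / I) ** 2
    return (S / I) * (
        (A1 * math.log(t) / (t + B1))
        * (1 / (1 + w) ** 3 + 1 / (t - w) ** 3
           - 1 / ((1 + w) ** 1.5 * (t - w) ** 1.5))
        + (A2 / (t + B2))
        * (1 / (1 + w) ** 2 + 1 / (t - w) ** 2 - 1 / ((1 + w) * (t - w))))


def seltzer_close_oracle(T, W, B, U, N):
    """Independent transcription of the Seltzer close-collision term."""
    tau, E, y = T / MC2, W + B, W / U
    beta2 = 1 - 1 / (1 + tau) ** 2
    G = (8 * U / (3 * math.pi)) * (1 / E**3 + 1 / (T - W) ** 3) * (
        math.atan(math.sqrt(y)) + math.sqrt(y) * (y - 1) / (y + 1) ** 2)
    return (2 * math.pi * RE**2 * MC2 * N / (beta2 * (T + B + U))) * (
        1 / E**2 + 1 / (T - W) ** 2 + (tau / (tau + 1)) ** 2 / T**2
        - (2 * tau + 1) / (tau + 1) ** 2 / (E * (T - W)) + G)


class TestRuddElectron:
    def test_below_binding_threshold_is_zero(self, orbital_1b1):
        for w in [0.0, 1.0, 5.0]:
            assert rudd_electron_dcs(10.0, w, orbital_1b1) == 0.0

    def test_matches_independent_transcription(self, medium, rng):
        for _ in range(20):
            orb = medium.orbitals[rng.integers(0, 5)]
            el, _ = generate_fixtures("random_rudd_params",
                                      int(rng.integers(0, 2**31)))
            T = float(np.exp(rng.uniform(np.log(2 * orb.binding_ev),
                                         np.log(5e4))))
            W = float(rng.uniform(0, 0.5 * (T - orb.binding_ev)))
            got = rudd_electron_dcs(T, W, orb, el)
            want = rudd_oracle(T, W, orb.binding_ev, orb.n_electrons,
                               el.a1, el.a2, el.b1, el.b2)
            assert got == pytest.approx(want, rel=1e-12)

    def test_linearity_in_fit_constants(self, orbital_1b1):
        p1 = RuddElectronParams(0.5, 0.8, 0.0, 0.0)
        p2 = RuddElectronParams(1.0, 1.6, 0.0, 0.0)
        a = rudd_electron_dcs(100.0, 10.0, orbital_1b1, p1)
        b = rudd_electron_dcs(100.0, 10.0, orbital_1b1, p2)
        assert b == pytest.approx(2 * a, rel=1e-14)

    def test_zero_outside_support(self, orbital_1b1):
        T = 100.0
        hi = 0.5 * (T - orbital_1b1.binding_ev)
        assert rudd_electron_dcs(T, hi + 1e-6, orbital_1b1) == 0.0
        assert rudd_electron_dcs(T, hi - 1e-6, orbital_1b1) > 0.0

    def test_negative_arguments_raise(self, orbital_1b1):
        with pytest.raises(DomainError):
            rudd_electron_dcs(-5.0, 1.0, orbital_1b1)
        with pytest.raises(DomainError):
            rudd_electron_dcs(100.0, -1.0, orbital_1b1)

    def test_nonnegative_everywhere(self, medium, rng):
        for orb in medium.orbitals:
            T = float(np.exp(rng.uniform(np.log(12), np.log(1e5))))
            w = np.linspace(0, T, 300)
            assert np.all(rudd_electron_dcs(T, w, orb) >= 0)


class TestSeltzer:
    def test_zero_photoeffect_leaves_close_term(self, orbital_1b1):
        got = seltzer_dcs(1e5, 100.0, orbital_1b1, zero_photo_xs)
        want = seltzer_close_oracle(1e5, 100.0, orbital_1b1.binding_ev,
                                    orbital_1b1.mean_kinetic_ev,
                                    orbital_1b1.n_electrons)
        assert got == pytest.approx(want, rel=1e-10)

    def test_matches_independent_transcription(self, medium, rng):
        for _ in range(20):
            orb = medium.orbitals[rng.integers(0, 4)]
            T = float(np.exp(rng.uniform(np.log(6e4), np.log(1e6))))
            W = float(rng.uniform(1.0, 0.5 * (T - orb.binding_ev)))
            got = seltzer_dcs(T, W, orb, zero_photo_xs)
            want = seltzer_close_oracle(T, W, orb.binding_ev,
                                        orb.mean_kinetic_ev, orb.n_electrons)
            assert got == pytest.approx(want, rel=1e-10)

    def test_close_term_linear_in_electron_count(self, orbital_1b1):
        o2 = MolecularOrbital(1, "x", 2 * orbital_1b1.n_electrons,
                              orbital_1b1.binding_ev,
                              orbital_1b1.mean_kinetic_ev, 0.8)
        a = seltzer_dcs(1e5, 50.0, orbital_1b1, zero_photo_xs)
        b = seltzer_dcs(1e5, 50.0, o2, zero_photo_xs)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_distant_term_uses_photo_xs(self, orbital_1b1):
        def pe(orb, e):
            return np.full_like(np.asarray(e, dtype=float), 1e-24)

        with_pe = seltzer_dcs(1e5, 50.0, orbital_1b1, pe)
        without = seltzer_dcs(1e5, 50.0, orbital_1b1, zero_photo_xs)
        assert with_pe - without == pytest.approx(
            orbital_1b1.n_electrons * 1e-24, rel=1e-12)

    def test_negative_photo_xs_is_contract_error(self, orbital_1b1):
        def bad(orb, e):
            return np.full_like(np.asarray(e, dtype=float), -1.0)

        with pytest.raises(ProviderContractError):
            seltzer_dcs(1e5, 50.0, orbital_1b1, bad)


class TestFreeElectronKernel:
    def test_qmin_at_full_transfer_equals_t(self):
        assert q_min(250.0, 250.0) == pytest.approx(250.0, rel=1e-12)

    def test_qmin_zero_transfer(self):
        assert q_min(250.0, 0.0) == 0.0

    def test_qmin_small_transfer_series(self):
        T = 1000.0
        W = 1e-4 * T
        assert q_min(T, W) / (W * W / (4 * T)) == pytest.approx(1.0, abs=1e-3)

    def test_qmin_domain(self):
        with pytest.raises(DomainError):
            q_min(10.0, 11.0)

    def test_rho_rutherford_form(self):
        T, W = 321.0, 17.0
        want = 4 * math.pi * A0**2 * RY**2 / (T * W**2)
        assert rho_free(T, W) == pytest.approx(want, rel=1e-14)


class TestExcitationModels:
    def _level(self, amp=0.3, center=10.0, width=1.5, w0=10.0):
        return ExcitationLevel(1, "toy", w0, amp, center, width)

    def test_zero_amplitude_level_gives_zero(self):
        lvl = self._level(amp=0.0)
        w = np.linspace(0.5, 80.0, 200)
        assert np.all(kutcher_green_dcs(1000.0, w, lvl) == 0)
        assert np.all(kaplan_dcs(80.0, w, lvl) == 0)

    def test_linear_in_amplitude(self):
        a = kutcher_green_dcs(1000.0, 10.0, self._level(amp=0.3))
        b = kutcher_green_dcs(1000.0, 10.0, self._level(amp=0.6))
        assert b == pytest.approx(2 * a, rel=1e-14)

    def test_kutcher_green_matches_transcription(self, rng):
        lvl = self._level()
        for _ in range(20):
            T = float(np.exp(rng.uniform(np.log(150), np.log(1e4))))
            W = float(rng.uniform(8.0, 20.0))
            f = lvl.gaussian_amplitude * math.exp(
                -0.5 * ((W - lvl.gaussian_center_ev) / lvl.gaussian_width_ev) ** 2)
            qm = 2 * T * (1 - W / (2 * T) - math.sqrt(1 - W / T))
            want = (4 * math.pi * A0**2 * RY**2 / (T * W**2)) / W * f \
                * math.log(4 * T / qm)
            assert kutcher_green_dcs(T, W, lvl) == pytest.approx(want, rel=1e-12)

    def test_kaplan_matches_transcription(self, rng):
        lvl = self._level()
        for _ in range(20):
            T = float(rng.uniform(30.0, 99.0))
            W = float(rng.uniform(lvl.w0_ev, min(0.9 * T, 25.0)))
            alpha = 4 - 3 * math.exp(-(W - lvl.w0_ev) / lvl.alpha_ev)
            arg = alpha * T / W
            f = lvl.gaussian_amplitude * math.exp(
                -0.5 * ((W - lvl.gaussian_center_ev) / lvl.gaussian_width_ev) ** 2)
            want = (4 * math.pi * A0**2 * RY**2 / (T * W**2)) / W * f \
                * math.log(arg) if arg > 1 else 0.0
            assert kaplan_dcs(T, W, lvl) == pytest.approx(want, rel=1e-12)

    def test_alpha_factor_limits(self):
        lvl = self._level(w0=10.0)
        assert excitation_alpha(10.0, lvl) == pytest.approx(1.0, rel=1e-14)
        assert excitation_alpha(1e4, lvl) == pytest.approx(4.0, rel=1e-12)

    def test_clamped_to_zero_when_log_argument_small(self):
        lvl = self._level(w0=10.0, center=10.0)
        # at W = T = W_0: alpha = 1 and the log argument is exactly 1
        assert kaplan_dcs(10.0, 10.0, lvl) == 0.0

    def test_continuity_in_w_away_from_clamps(self):
        lvl = self._level()
        w = np.linspace(7.4, 40.0, 4000)
        vals = kutcher_green_dcs(500.0, w, lvl)
        body = vals[:-1] > 1e-6 * vals.max()   # exclude the steep deep tail
        rel_jump = np.abs(np.diff(vals)) / (np.abs(vals[:-1]) + 1e-300)
        assert np.nanmax(rel_jump[body]) < 0.05


class TestChainDispatch:
    def test_electron_ionisation_boundary_at_50_kev(self, rit_physics,
                                                    orbital_1b1):
        below, _ = rit_physics.electron_ionisation_dcs(49e3, 10.0, orbital_1b1)
        above, _ = rit_physics.electron_ionisation_dcs(51e3, 10.0, orbital_1b1)
        assert (below, above) == ("rudd", "seltzer")

    def test_excitation_boundary_at_100_ev(self, rit_physics, medium):
        lvl = medium.excitation_levels[0]
        low, _ = rit_physics.electron_excitation_dcs(99.0, 9.0, lvl)
        high, _ = rit_physics.electron_excitation_dcs(101.0, 9.0, lvl)
        assert (low, high) == ("kaplan", "kutcher_green")

    def test_geant4dna_routes_electron_ionisation_to_born(self, g4_physics,
                                                          orbital_1b1):
        model, val = g4_physics.electron_ionisation_dcs(1e3, 20.0, orbital_1b1)
        assert model == "born" and val > 0

    def test_unknown_chain_rejected(self):
        with pytest.raises(ConfigError, match="unknown model chain"):
            aq.chain_by_name("foo")

    def test_channel_map_covers_all_channels(self, rit_physics):
        out = rit_physics.electron_channel_dcs(200.0, 15.0)
        assert len(out) == 10
        assert all(v >= 0 for _, v in out.values())


class TestTotalCrossSection:
    def test_constant_integrand(self):
        assert total_cross_section(lambda w: np.full_like(
            np.asarray(w, float), 3.0), 100.0, (0.0, 10.0)) == pytest.approx(30.0)

    def test_empty_support_is_zero(self):
        assert total_cross_section(lambda w: 1.0, 5.0, (3.0, 3.0)) == 0.0

    def test_matches_brute_force_riemann(self, orbital_1b1):
        T = 500.0
        lo, hi = rudd_support(T, orbital_1b1)
        sig = total_cross_section(
            lambda w: rudd_electron_dcs(T, w, orbital_1b1), T, (lo, hi))
        mid = (np.arange(10**6) + 0.5) * (hi - lo) / 10**6 + lo
        brute = rudd_electron_dcs(T, mid, orbital_1b1).sum() * (hi - lo) / 10**6
        assert sig == pytest.approx(brute, rel=1e-3)

    def test_rudd_total_unimodal_in_t(self, medium):
        grid = np.geomspace(15.0, 5e4, 200)
        totals = []
        for T in grid:
            tot = 0.0
            for orb in medium.orbitals:
                lo, hi = rudd_support(T, orb)
                if hi > lo:
                    tot += total_cross_section(
                        lambda w, o=orb: rudd_electron_dcs(T, w, o), T,
                        (lo, hi), tol=1e-8)
            totals.append(tot)
        totals = np.asarray(totals)
        peak = int(np.argmax(totals))
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(totals[:peak + 1]) >= -1e-12 * totals[peak])
        assert np.all(np.diff(totals[peak:]) <= 1e-12 * totals[peak])

    def test_below_threshold_total_is_zero(self, medium):
        for T in [5.0, 11.0, 11.49]:
            for orb in medium.orbitals:
                lo, hi = rudd_support(T, orb)
                assert total_cross_section(
                    lambda w: rudd_electron_dcs(T, w, orb), T, (lo, hi)) == 0.0
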