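"""Proton Rudd model, relativistic velocity substitution and Born machinery."""

import math

import numpy as np
import pytest

import aquatrack as aq
from aquatrack.chains import ChainPhysics, geant4dna_like
from aquatrack.dielectric import ConstantELF, DrudeELF
from aquatrack.errors import DomainError, ConfigError, ProviderContractError
from aquatrack.proton import (scaled_velocity_sq, proton_rudd_dcs,
                              born_q_bounds, born_ddcs, born_sdcs_imfp,
                              born_orbital_dcs, proton_w_max,
                              RuddProtonParams)
from aquatrack.quadrature import total_cross_section
from aquatrack.report import generate_fixtures

A0 = aq.CONSTANTS.bohr_radius_m
MC2 = aq.CONSTANTS.electron_rest_energy_ev
M_RATIO = aq.CONSTANTS.electron_proton_mass_ratio
MP = aq.CONSTANTS.proton_rest_energy_ev


def rudd_proton_oracle(E_p, W, I, N, p, mode="relativistic"):
    """Independent single-expression transcription of the proton Rudd DCS."""
    T = E_p * M_RATIO
    v2 = T / I if mode == "classical" else \
        (MC2 / (2 * I)) * (1 - 1 / (1 + T / MC2) ** 2)
    v = math.sqrt(v2)
    S = 4 * math.pi * A0**2 * N * (aq.CONSTANTS.rydberg_ev / I) ** 2
    w = W / I
    F1 = (p.a1 * math.log(1 + v2) / (v2 + p.b1 / v2)
          + p.c1 * v**p.d1 / (1 + p.e1 * v ** (p.d1 + 4)))
    h2 = p.a2 / v2 + p.b2 / v**4
    l2 = p.c2 * v**p.d2
    F2 = l2 * h2 / (l2 + h2)
    wc = 4 * v2 - 2 * v - aq.CONSTANTS.rydberg_ev / (4 * I)
    return (S / I) * (F1 + w * F2) / ((1 + w) ** 3
                                      * (1 + math.exp(p.alpha * (w - wc) / v)))


class TestScaledVelocity:
    def test_classical_limit_below_500_kev(self, orbital_1b1):
        for e_p in [1e3, 1e4, 1e5, 5e5]:
            rel = scaled_velocity_sq(e_p, orbital_1b1.binding_ev, "relativistic")
            cla = scaled_velocity_sq(e_p, orbital_1b1.binding_ev, "classical")
            assert abs(rel / cla - 1) < 1e-3

    def test_deviation_scale_at_100_kev(self, orbital_1b1):
        rel = scaled_velocity_sq(1e5, orbital_1b1.binding_ev, "relativistic")
        cla = scaled_velocity_sq(1e5, orbital_1b1.binding_ev, "classical")
        # first-order deviation is ~1.5 T/mc² with T ≈ 54.5 eV
        assert abs(rel / cla - 1) == pytest.approx(1.5 * 54.46 / MC2, rel=0.05)

    def test_value_at_t_equal_mc2(self):
        i_ev = 11.5
        e_p = MC2 / M_RATIO  # T = mc²
        got = scaled_velocity_sq(e_p, i_ev, "relativistic")
        assert got == pytest.approx((3.0 / 8.0) * MC2 / i_ev, rel=1e-12)

    def test_monotone_and_bounded(self):
        i_ev = 11.5
        vals = [scaled_velocity_sq(e, i_ev, "relativistic")
                for e in np.geomspace(1e3, 1e12, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < MC2 / (2 * i_ev)

    def test_domain_and_mode_errors(self):
        with pytest.raises(DomainError):
            scaled_velocity_sq(-1.0, 11.5)
        with pytest.raises(ConfigError):
            scaled_velocity_sq(1e5, 11.5, mode="bogus")


class TestRuddProton:
    def test_matches_independent_transcription(self, medium, rng):
        for _ in range(20):
            orb = medium.orbitals[rng.integers(0, 5)]
            _, pr = generate_fixtures("random_rudd_params",
                                      int(rng.integers(0, 2**31)))
            e_p = float(np.exp(rng.uniform(np.log(1e4), np.log(1e7))))
            W = float(rng.uniform(0.0, 100.0))
            got = proton_rudd_dcs(e_p, W, orb, pr)
            want = rudd_proton_oracle(e_p, W, orb.binding_ev,
                                      orb.n_electrons, pr)
            assert got == pytest.approx(want, rel=1e-12)

    def test_default_params_at_500_kev(self, orbital_1b1):
        got = proton_rudd_dcs(5e5, 20.0, orbital_1b1)
        want = rudd_proton_oracle(5e5, 20.0, orbital_1b1.binding_ev, 2,
                                  RuddProtonParams())
        assert got == pytest.approx(want, rel=1e-12)

    def test_vanishing_fit_functions_give_zero(self, orbital_1b1):
        class ZeroF(RuddProtonParams):
            def f1(self, v):
                return 0.0

            def f2(self, v):
                return 0.0

        w = np.linspace(0, 500, 50)
        assert np.all(proton_rudd_dcs(1e6, w, orbital_1b1, ZeroF()) == 0)

    def test_decays_to_zero_at_large_w(self, orbital_1b1):
        big_w = proton_w_max(1e6, orbital_1b1) * 2
        small = proton_rudd_dcs(1e6, big_w, orbital_1b1)
        peak = proton_rudd_dcs(1e6, 10.0, orbital_1b1)
        assert small < 1e-12 * peak

    def test_total_unimodal_over_energy(self, rit_physics):
        grid = np.geomspace(1e4, 1e7, 200)
        totals = []
        for e_p in grid:
            tot = 0.0
            for orb in rit_physics.medium.orbitals:
                sup = rit_physics.proton_support(e_p, orb)
                tot += total_cross_section(
                    lambda w, o=orb: proton_rudd_dcs(e_p, w, o), e_p, sup,
                    tol=1e-7)
            totals.append(tot)
        totals = np.asarray(totals)
        peak = int(np.argmax(totals))
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(totals[:peak + 1]) >= -1e-9 * totals[peak])
        assert np.all(np.diff(totals[peak:]) <= 1e-9 * totals[peak])


class TestBornKinematics:
    def test_equal_bounds_at_full_transfer(self):
        lo, hi = born_q_bounds(1000.0, 1000.0, MP)
        assert lo == pytest.approx(hi, rel=1e-12)
        assert lo == pytest.approx(math.sqrt(2 * MP * 1000.0), rel=1e-12)

    def test_product_identity(self, rng):
        for _ in range(50):
            tau = float(np.exp(rng.uniform(np.log(10), np.log(1e8))))
            e = float(rng.uniform(0, tau))
            m = float(rng.choice([MC2, MP]))
            lo, hi = born_q_bounds(tau, e, m)
            assert lo * hi == pytest.approx(2 * m * e, rel=1e-9)

    def test_zero_transfer_lower_bound(self):
        lo, hi = born_q_bounds(500.0, 0.0, MC2)
        assert lo == 0.0

    def test_small_transfer_limit(self):
        tau, e = 1e6, 1.0
        lo, _ = born_q_bounds(tau, e, MP)
        assert lo == pytest.approx(e * math.sqrt(MP / (2 * tau)), rel=1e-5)

    def test_transfer_beyond_energy_raises(self):
        with pytest.raises(DomainError):
            born_q_bounds(10.0, 11.0, MP)


class TestBornDDCS:
    def test_zero_outside_theta_window(self):
        elf = ConstantELF(1.0)
        assert born_ddcs(100.0, 150.0, 10.0, MP, elf) == 0.0  # E > tau
        lo, hi = born_q_bounds(100.0, 50.0, MP)
        assert born_ddcs(100.0, 50.0, lo * 0.5, MP, elf) == 0.0
        assert born_ddcs(100.0, 50.0, hi * 1.5, MP, elf) == 0.0
        assert born_ddcs(100.0, 50.0, 0.5 * (lo + hi), MP, elf) > 0.0

    def test_window_interior_value(self):
        tau, e = 1e6, 40.0
        lo, hi = born_q_bounds(tau, e, MP)
        q = math.sqrt(lo * hi)
        t = tau * MC2 / MP
        want = 1.0 / (math.pi * A0 * t * q)
        assert born_ddcs(tau, e, q, MP, ConstantELF(1.0)) == pytest.approx(
            want, rel=1e-12)

    def test_negative_elf_is_contract_error(self):
        class Bad:
            q_independent = True

            def __call__(self, e, q=None):
                return -1.0

        lo, hi = born_q_bounds(100.0, 50.0, MP)
        with pytest.raises(ProviderContractError):
            born_ddcs(100.0, 50.0, 0.5 * (lo + hi), MP, Bad())

    def test_q_integral_matches_log_closed_form(self, rng):
        elf = ConstantELF(1.0)
        for _ in range(25):
            tau = float(np.exp(rng.uniform(np.log(1e3), np.log(1e7))))
            e = float(rng.uniform(1e-3 * tau, tau * 0.99))
            m = float(rng.choice([MC2, MP]))
            lo, hi = born_q_bounds(tau, e, m)
            t = tau * MC2 / m
            want = math.log(hi / lo) / (math.pi * A0 * t)
            got = born_sdcs_imfp(tau, e, m, elf, method="quad")
            assert got == pytest.approx(want, rel=1e-9)

    def test_dispersive_grid_integration_matches_quad(self, medium):
        elf = DrudeELF()
        orb = medium.orbitals[0]
        tau = 2e6
        w = np.array([5.0, 20.0, 100.0, 1000.0])
        grid_vals = born_orbital_dcs(tau, w, orb, medium, MP, elf)
        for wi, gv in zip(w, grid_vals):
            e = wi + orb.binding_ev
            quad_val = born_sdcs_imfp(tau, e, MP, elf, method="quad") \
                * orb.n_electrons / 10.0 / medium.number_density_m3
            assert gv == pytest.approx(quad_val, rel=1e-4)


class TestProtonDispatch:
    def test_boundary_at_500_kev(self, g4_physics, orbital_1b1):
        below, _ = g4_physics.proton_ionisation_dcs(499e3, 20.0, orbital_1b1)
        above, _ = g4_physics.proton_ionisation_dcs(501e3, 20.0, orbital_1b1)
        assert (below, above) == ("rudd", "born")

    def test_ritracks_uses_rudd_at_2_mev(self, rit_physics, orbital_1b1):
        model, _ = rit_physics.proton_ionisation_dcs(2e6, 20.0, orbital_1b1)
        assert model == "rudd"

    def test_born_without_elf_is_config_error(self, medium):
        physics = ChainPhysics(medium=medium, chain=geant4dna_like(), elf=None)
        with pytest.raises(ConfigError, match="ELF"):
            physics.proton_ionisation_dcs(1e6, 20.0, medium.orbitals[0])
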