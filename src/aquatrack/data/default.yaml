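# Default aquatrack configuration: liquid water medium and model parameters.
#
# Everything in this file is an editable model input.  Provenance notes:
#   * orbitals: the standard five-shell water table of the Seltzer/Rudd
#     semiempirical models (electron counts, binding energies B_i, mean
#     orbital kinetic energies U_i, mean radii <r>_i).
#   * rudd_electron: the liquid/inner-shell fit constants of the Rudd
#     electron-impact model.
#   * excitation_levels: NOT part of the semiempirical tables above; the
#     five-level decomposition (A1B1, B1A1, two Rydberg bands, diffuse
#     bands) with Gaussian strengths is a package default assembled from
#     the liquid-water excitation literature.  Edit freely.
#   * rudd_proton: functional forms follow the Rudd proton parameterisation;
#     the numbers are the standard water set.
#   * born_elf: single-Drude optical approximation of the water energy-loss
#     function (21.4 eV collective peak, f-sum-rule strength).  A coarse
#     package default, not a fitted dielectric model.
#   * photo_xs: synthetic threshold power-law photoionisation curves used
#     only by the Seltzer distant-collision term.  Package default.

constants: {}   # optional overrides by field name of PhysicalConstants

medium:
  mass_density_g_cm3: 1.0
  molar_mass_g_mol: 18.015

orbitals:
  - {index: 1, label: 1b1, n_electrons: 2, binding_ev: 11.50, mean_kinetic_ev: 30.0,  r_mean_angstrom: 0.833, shell_class: outer}
  - {index: 2, label: 3a1, n_electrons: 2, binding_ev: 11.75, mean_kinetic_ev: 40.0,  r_mean_angstrom: 0.867, shell_class: outer}
  - {index: 3, label: 1b2, n_electrons: 2, binding_ev: 13.51, mean_kinetic_ev: 50.0,  r_mean_angstrom: 0.901, shell_class: outer}
  - {index: 4, label: 2a1, n_electrons: 2, binding_ev: 16.0,  mean_kinetic_ev: 60.0,  r_mean_angstrom: 0.906, shell_class: outer}
  - {index: 5, label: 1a1, n_electrons: 2, binding_ev: 539.7, mean_kinetic_ev: 700.0, r_mean_angstrom: 0.129, shell_class: inner}

excitation_levels:
  # e_min_ev is the minimum energy transfer by excitation; alpha_ev
  # (= 4 e_min / ln 2) is derived automatically.
  # The Gaussian strengths play the role of Ry * df/dW (an oscillator-
  # strength density, units eV): each amplitude is chosen so the Gaussian
  # integrates to Ry * f_osc with the level oscillator strengths
  # (0.052, 0.068, 0.043, 0.062, 0.270) of the liquid-water excitation
  # literature, i.e. amplitude = Ry * f_osc / (width * sqrt(2 pi)).
  - {index: 1, label: A1B1,    w0_ev: 8.4,   gaussian_amplitude: 0.3529, gaussian_center_ev: 8.4,   gaussian_width_ev: 0.8, e_min_ev: 7.34}
  - {index: 2, label: B1A1,    w0_ev: 10.1,  gaussian_amplitude: 0.3691, gaussian_center_ev: 10.1,  gaussian_width_ev: 1.0, e_min_ev: 7.34}
  - {index: 3, label: RydAB,   w0_ev: 11.26, gaussian_amplitude: 0.2334, gaussian_center_ev: 11.26, gaussian_width_ev: 1.0, e_min_ev: 7.34}
  - {index: 4, label: RydCD,   w0_ev: 11.93, gaussian_amplitude: 0.2804, gaussian_center_ev: 11.93, gaussian_width_ev: 1.2, e_min_ev: 7.34}
  - {index: 5, label: diffuse, w0_ev: 14.1,  gaussian_amplitude: 0.7327, gaussian_center_ev: 14.1,  gaussian_width_ev: 2.0, e_min_ev: 7.34}

rudd_electron:
  liquid: {a1: 0.94, a2: 1.13, b1: 2.30, b2: 22.0}
  inner:  {a1: 1.31, a2: 0.37, b1: 0.00, b2: 0.00}

rudd_proton:
  a1: 0.97
  b1: 82.0
  c1: 0.40
  d1: -0.30
  e1: 0.38
  a2: 1.04
  b2: 17.3
  c2: 0.76
  d2: 0.04
  alpha: 0.64

born_elf:
  drude_terms:
    - {e0_ev: 21.4, gamma_ev: 13.0, strength_ev2: 460.5316}

photo_xs:
  exponent: 3.0
  sigma0_cm2:        # threshold photoionisation cross-section per orbital
    1b1: 8.0e-18
    3a1: 6.0e-18
    1b2: 5.0e-18
    2a1: 3.0e-18
    1a1: 5.0e-19

ions:
  - {name: H,  z: 1,  mass_ratio: 1.0}
  - {name: He, z: 2,  mass_ratio: 3.9726}
  - {name: Li, z: 3,  mass_ratio: 6.9565}
  - {name: Be, z: 4,  mass_ratio: 8.9425}
  - {name: B,  z: 5,  mass_ratio: 10.7309}
  - {name: C,  z: 6,  mass_ratio: 11.9067}
  - {name: N,  z: 7,  mass_ratio: 13.8928}
  - {name: O,  z: 8,  mass_ratio: 15.8735}
  - {name: Si, z: 14, mass_ratio: 27.8442}
  - {name: Fe, z: 26, mass_ratio: 55.4679}

transport:
  box_edge_um: 7.0
  electron_cutoff_ev: 10.0
  proton_cutoff_ev: 100.0
  effective_charge_below_mev_per_u: 0.2
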