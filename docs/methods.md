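# Methods

## Scope and units

`aquatrack` models the inelastic interactions (ionisation and electronic
excitation) of electrons, protons and heavy ions in liquid water, and
transports them event by event in a bounded cube.  Elastic scattering,
charge transfer, vibrational/rotational excitation of sub-ionisation
electrons, and the radiation-chemistry stage are out of scope.

Internally: energies in eV, lengths in m, cross-sections in m² (CSV export
convention for tables is cm² = 10⁴ m²).  Momenta in the Born kinematics are
energy-equivalent (masses entered as rest energies), so q has units of
√(eV·eV); only ratios and the combination q²/2mc² (an energy) ever enter
the physics, which makes the convention self-consistent.  Water is liquid
at 1.0 g/cm³, molar mass 18.015 g/mol, giving N = 3.343×10²² molecules/cm³.

## Medium

Five ionisable molecular orbitals (1b1, 3a1, 1b2, 2a1, 1a1) with electron
counts N_i = 2, binding energies B_i ≡ I_i = 11.50, 11.75, 13.51, 16.0,
539.7 eV, mean orbital kinetic energies U_i = 30…700 eV and mean radii
⟨r⟩_i (stored for completeness; no implemented equation uses ⟨r⟩_i).  Five
electronic excitation levels (A¹B₁, B¹A₁, two Rydberg bands, diffuse bands)
carry Gaussian strength functions f_i(W).  The excitation energies,
widths and strengths are **not** part of the semiempirical ionisation
tables; the shipped defaults place the levels at 8.4, 10.1, 11.26, 11.93
and 14.1 eV and normalise each Gaussian so its integral equals ℛ·f_osc
with oscillator strengths (0.052, 0.068, 0.043, 0.062, 0.270), i.e. f_i(W)
plays the role of ℛ·df/dW.  They are user-editable config inputs, and every
unit test that exercises them uses config or synthetic values, never
hard-coded numbers.

## Electron models

**Rudd ionisation** (used by `ritracks_like` below 50 keV).  The Mott-based
two-term form with F₁(t) = A₁ln(t)/(t+B₁) and F₂(t) = A₂/(t+B₂)
(liquid set A₁=0.94, A₂=1.13, B₁=2.30, B₂=22.0; inner-shell set 1.31,
0.37, 0, 0, applied to 1a1 only).  Because the two outgoing electrons are
indistinguishable, the ejected-energy support is W ∈ [0, (T−I_i)/2]; the
DCS is defined as 0 for T ≤ I_i and outside the support.  Consequently the
ionisation threshold of the implementation is min_i B_i = 11.50 eV.

**Seltzer ionisation** (above 50 keV): close-collision term with prefactor
2πr_e²mc²N_i/[β²(T+B_i+U_i)], the bracket 1/E² + 1/(T−W)² +
(1/T²)(τ/(τ+1))² − (2τ+1)/(τ+1)²·1/(E(T−W)) + G_i, E = W+B_i, and the
exchange correction G_i = (8U_i/3π)(1/E³+1/(T−W)³)(tan⁻¹√y + √y(y−1)/(y+1)²),
y = W/U_i.  The distant-collision term is N_i·σ_PE^i(E) with σ_PE a
pluggable photoionisation provider; the shipped default is a synthetic
threshold power law σ₀(B_i/E)³ with per-orbital σ₀ in config — it is a
placeholder curve for the (small) distant term, not a literature fit, and
tests exercise the provider contract with synthetic curves including ≡0.

**Excitation.**  Kutcher–Green, dσ/dW = (ρ(W)/W)f_i(W)ln(4T/Q_min) with
Q_min = 2T(1 − W/2T − √(1−W/T)), is used above 100 eV; the
Kaplan–Sukhonosov/Cobut form (ρ(W)/W)f_i(W)ln(α(W)T/W) with
α = 4 − 3e^{−(W−W_{0,i})/α_i}, α_i = 4E_min/ln2, E_min = 7.34 eV, below
100 eV.  Both are clamped to zero wherever the logarithm's argument ≤ 1
(and wherever α ≤ 0); the models' sources are silent about these regions,
and clamping keeps the DCS total and non-negative.  ρ(W) is implemented as
the free-electron Rutherford kernel 4πa₀²ℛ²/(TW²), the form to which
e⁴/(8πε₀²mv²W²) reduces exactly.

## Proton and ion models

**Rudd proton ionisation.**  dσ/dW = (S_i/I_i)[F₁(υ)+ωF₂(υ)] /
{(1+ω)³[1+exp(α(ω−ω_c)/υ)]} with υ = √(T/I_i), T = E_p(m/M_p).  The fitted
velocity functions use the standard Rudd branch forms
(H₁ = A₁ln(1+υ²)/(υ²+B₁/υ²), L₁ = C₁υ^{D₁}/(1+E₁υ^{D₁+4}), F₁ = L₁+H₁;
H₂ = A₂/υ²+B₂/υ⁴, L₂ = C₂υ^{D₂}, F₂ = L₂H₂/(L₂+H₂)) with the water
parameter set (0.97, 82, 0.40, −0.30, 0.38; 1.04, 17.3, 0.76, 0.04) and
α = 0.64, ω_c = 4υ²−2υ−ℛ/4I_i — all exposed in config, and all unit tests
run against synthetic sets so correctness never rests on these numbers.
Above a relativistic threshold (by default always) υ² uses the substitution
υ² = (mc²/2I_i)[1 − (1+T/mc²)⁻²].  The practical secondary-energy support
is the Fermi cutoff I_i·ω_c plus 40 e-folds of the exponential tail,
floored at the ~4T free-electron kinematic maximum.

**Born ionisation.**  The double-differential inverse mean free path
d²Σ/dEdq = Im(−1/ε(E,q))/(πa₀Tq)·θ(q−q₋)θ(q₊−q)θ(τ−E), q± = √(2M)(√τ±√(τ−E)),
T = (m/M)τ.  The default ELF is a single Drude oscillator at the 21.4 eV
collective peak of the water loss function (γ = 13 eV) with its strength
fixed by the f-sum rule (ħω_pl = 21.46 eV), **with Bethe-ridge dispersion**
E₀(q) = E₀ + q²/2m.  The dispersion matters: integrating a purely optical
ELF over the full heavy-particle q-window overestimates ionisation totals
by a factor ~2–4; with it the Born proton totals land within 10–20 % of the
Rudd model above 500 keV, mirroring the close agreement expected between
the two chains there.  The single-ELF inverse mean free path is partitioned
over the five orbitals with weights N_i/ΣN_j and secondary energy
W = E − B_i; electron projectiles additionally truncate at W = (τ−B_i)/2
for consistency with the indistinguishability convention.  The
`geant4dna_like` excitation channel reuses the Born kinematic kernel with
f_i(W)/W standing in for the (unavailable) channel-resolved part of the
ELF — a package construction, normalised consistently with the
Kutcher–Green kernel (the two agree within tens of percent at overlapping
(T, W)).

**Ions.**  Velocity matching E_ion = (M/M_p)τ, exact Z² scaling of the
matched proton DCS, and the Booth–Grant effective charge with
x = 100βZ^{−2/3}, where β is computed relativistically from the ion kinetic
energy, β² = 1−(1+E/Mc²)⁻².  The correction defaults to "on" below
0.2 MeV/u (where it becomes a few-percent effect for protons) with an
explicit override flag.  No ion excitation channel is provided.

## Model chains and dispatch

Chains bind models to processes over half-open energy intervals [lo, hi);
the lower model applies on [lo, hi) with no blending.  `ritracks_like`:
electron ionisation Rudd/Seltzer split at 50 keV, excitation
Kaplan/Kutcher–Green split at 100 eV, proton Rudd throughout.
`geant4dna_like`: electron ionisation and excitation through the Born
machinery, proton Rudd below 500 keV and Born above.  Chain validation
rejects gaps or overlaps.

## Sampling and transport

Channel totals come from adaptive quadrature (scipy, relative tolerance
10⁻⁶, log-substitution for wide supports).  Energy losses are drawn by
tabulated inverse CDFs: each channel DCS is evaluated on a 512-point
log-spaced support grid, integrated by trapezoid, and inverted by linear
interpolation — the log grid resolves the steep ~W⁻² tails (a uniform
quantile compression was tried and rejected: it linearises the δ-ray tail
and badly oversamples hard secondaries).  Transport tables hold these CDFs
on a log primary-energy grid (16 points/decade; electrons 8 eV–1 MeV,
protons 100 eV–100 MeV); totals interpolate linearly in ln E, spectra use
the nearest row with the sampled W clamped to the kinematic support at the
true energy.

The Monte Carlo fires the primary from the centre of one cube face along
+z, alternates exponential free flights (mean 1/NΣσ), boundary checks,
channel selection (∝σ_i) and energy-loss draws.  Ionisation deposits B_i
locally and hands W to a secondary electron (isotropic emission by default;
configurable to forward), which is transported identically; excitation
deposits W locally.  Particles terminate on leaving the cube (energy booked
as exited) or on falling below the tracking cutoff (10 eV electrons, 100 eV
protons; the residual is booked as a sub-cutoff deposit — no thermalisation
model).  No angular deflection is applied anywhere: the observable here,
ionisation counts in a micron-scale cube, is governed by inelastic mean
free paths, and elastic scattering is out of scope.  Energy bookkeeping is
exact by construction: E₀ = Σ binding deposits + Σ excitation deposits +
sub-cutoff + exited, verified to 10⁻⁹ relative per history.  Each history
has its own RNG stream derived from (master seed, history index), so runs
are reproducible and histories independent of execution order.

## Numerical and edge-case policy

Negative bracket values arising from floating cancellation are clamped to
zero; DCS functions return exactly 0 outside their kinematic support and
raise domain errors for negative energies; samplers with zero total are
flagged empty and refuse to sample; channel selection never returns a
zero-σ channel.  Exponentials in Fermi factors and α(W) are clipped at
±700 before `exp`.  The ion transport recomputes Z*(β) at every step.

## Problem sizes

The test suite uses 10⁶-panel Riemann sums as quadrature oracles, 10⁵–10⁶
draws for sampling statistics, 10³ mixed-energy histories for conservation
checks, 10⁴ toy histories against the analytic Poisson count, and the
single-proton counting protocol at 10 log-spaced energies over
10⁻²–10² MeV with 100 histories per energy per chain.
`scripts/acceptance.py` runs a 6-point, 30-history version of the same
protocol; these sizes are the package's chosen balance of statistical
resolution against desk-scale runtimes.

## Known limitations

* The large *low-energy* divergence in single-proton ionisation counts
  reported between the two production codes is not reproduced as an
  ordering: with both chains sharing the Rudd
  proton model below 500 keV and the soft low-energy secondary spectrum
  falling largely below the 10 eV tracking cutoff, the two chains agree
  *more* closely at 10–100 keV than at ≥1 MeV here (where the proton model
  switch and the different electron chains act).  The production codes'
  low-energy behaviour evidently involved implementation details beyond
  their published cross-sections.
* The single-Drude ELF is a coarse stand-in for a fitted dielectric
  response; Born absolute totals inherit its ~10–20 % level of realism.
* The Seltzer distant term depends on a synthetic photoionisation curve.
* No elastic deflection means spatial event patterns are straighter than
  physical tracks; counts and energy budgets are unaffected.
* Sub-8 eV electron physics (vibrational/rotational) is absent; electrons
  below the cutoff deposit on the spot.
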