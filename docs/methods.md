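# Methods

`isopimd` simulates liquid water isotopologues — H₂O, HDO (100% singly
deuterated), D₂O and T₂O — with path-integral molecular dynamics (PIMD)
over the q-TIP4P/F flexible water potential, and computes the
thermodynamic, dynamical and structural observables through which
nuclear quantum effects (NQE) express themselves.  Isotope substitution
changes *only* the nuclear masses; every difference between the
isotopologues is therefore a nuclear quantum effect by construction.

## Potential

q-TIP4P/F is a flexible 4-site model:

* OX stretch (X = H/D/T): quartic expansion of a Morse potential,
  `V = D_r [α² Δr² − α³ Δr³ + (7/12) α⁴ Δr⁴]` with
  `D_r = 485.72 kJ/mol`, `α = 22.87 nm⁻¹`, `r_eq = 0.09419 nm`.
* XOX bend: harmonic, `k_θ = 367.56 kJ mol⁻¹ rad⁻²`, `θ_eq = 107.4°`.
* Lennard-Jones on O only: `ε = 0.7749 kJ/mol`, `σ = 0.31589 nm`.
* Charges `q_H = 0.5564 e` on the covalent sites and
  `q_M = −1.1128 e` on a massless M site at
  `r_M = w r_O + (1−w)(r_X1 + r_X2)/2`, `w = 0.73612`.  Forces on M are
  redistributed to the massive sites by the transpose of these weights,
  which conserves molecular force and torque exactly.

The constants ship in `src/isopimd/data/qtip4pf.json` (versioned) in
the package unit system nm / ps / amu / kJ mol⁻¹ / e, in which
1 kJ/mol = 1 amu nm² ps⁻², so the equations of motion carry no unit
factors.

Electrostatics use the reaction-field approximation
(`ε_rf = 78.3`): each site pair within the cutoff interacts through
`f q_i q_j (1/r + k_rf r² − c_rf)` with
`k_rf = (ε_rf − 1)/((2ε_rf + 1) r_c³)`.  The kernel is shifted to zero
at `r_c` (flag `rf_shift`); with this shift the pair force is also
nearly zero at the cutoff, so a site-resolved cutoff produces no energy
drift.  The site-resolved cutoff (rather than a molecular, O–O-gated
one) was chosen after the group-gated variant showed steady heating at
desk-scale cutoffs: gating all nine charge-site terms on the O–O
distance makes several kJ/mol of energy appear and disappear whenever a
pair crosses `r_c`.  LJ is plainly truncated at `r_c` in the
reference profile; the desk profile additionally shifts it to zero
(`lj_shift`) for the same continuity reason.

## Path-integral propagation

Each atom is an `n_b`-bead cyclic chain with spring frequency
`ω_n = n_b/(βħ)`, sampled at temperature `n_b T`; bead slice *j* of one
molecule interacts only with slice *j* of others (standard
discretization).  One step of the integrator is the symmetric OBABO
splitting: half Ornstein–Uhlenbeck thermostat in normal-mode space,
half force kick, *exact* free-ring-polymer drift (per-mode rotation),
half kick, half thermostat.  The thermostat is the path-integral
Langevin equation (PILE): internal modes are critically damped
(`γ_k = 2ω_k`); the centroid mode uses `γ₀ = 0.1 ps⁻¹`, kept small so
the same thermostatted trajectories serve for transport and spectra
(RPMD practice).  With `n_b = 1` and the thermostat off the integrator
is bit-for-bit velocity Verlet.

Equilibration from the lattice start uses a strong centroid friction
(`γ_equil = 20 ps⁻¹`, an implementation choice — the lattice start
releases several kJ/mol per molecule that the production friction would
take ~100 ps to drain); production always runs at the study value
0.1 ps⁻¹.  Time step 0.25 fs (quantum), 0.5 fs (classical, `n_b = 1`).
A per-step displacement above 0.05 nm aborts the run with a diagnostic.

Estimators (per configuration): potential `U = ⟨V⟩_beads`; primitive
and centroid-virial kinetic energies; total quantum energy
`E = ⟨K_cv⟩ + ⟨U⟩`; virial pressure `PV = (2/3)K_cv + W/(3 n_b)` with
W the pair virial summed over slices; enthalpy `H = E + P V`.  For
`n_b = 1` every estimator reduces exactly to its classical counterpart.

Constant pressure uses a Monte-Carlo barostat: isotropic proposals in
ln V every 25 steps, molecular ring-polymer centers rescaled rigidly
(bead spread and internal geometry preserved), Metropolis weight
`exp(−β[ΔU + PΔV] + (N+1) Δln V)`.  Scaling whole-molecule centers
rather than individual beads keeps the intramolecular springs out of
the acceptance rule; a flag switches to bead scaling.  On an ideal gas
the sampled volume distribution reproduces the Gamma(N+1, k_BT/P) mean
and variance to within Monte-Carlo error (tested).

## Observables

* **Density / compressibility**: `ρ = N M/(N_A⟨V⟩)` with block-averaged
  errors (≥5 blocks enforced); `κ_T = ⟨δV²⟩/(k_B T ⟨V⟩)` from volume
  fluctuations (the fluctuation route was chosen over a numerical
  ∂V/∂P because it needs a single run; flagged in the output).
* **Heat capacities**: quartic least-squares fit of H(T) (→ C_P) or
  E(T) (→ C_V) followed by analytic differentiation; uncertainties by
  resampling the input error bars.  Finite-bead heat capacities are
  bead-convergence limited; every report carries that warning.
* **Density maximum**: local quadratic fit around the ρ(T) maximum (or
  the P(T) minimum at constant molar volume — the same anomaly seen
  from the other ensemble).
* **Diffusion**: multiple-time-origin MSD of the O ring-polymer
  centroids (FFT-based), `D = slope/6` in the linear window, with a
  log-log slope guard against non-diffusive input.  D(T) is described
  by an Arrhenius branch (`D₀ e^{−E_A/k_BT}`, fit above 300 K) and a
  mode-coupling branch (`D₁(T−T_MCT)^γ`, fit 220–300 K, `T_MCT`
  bounded below the window); the crossover temperature is reported as
  the intersection of the fitted branches.  Both fitters are exact
  inverses of their generators in the noiseless case (tested).
* **Spectra**: VDOS as the cosine transform of the mass-weighted
  centroid velocity autocorrelation (the RPMD stand-in for the
  Kubo-transformed one); IR as `ω tanh(βħω/2)` times the transform of
  the total-dipole autocorrelation (harmonic quantum-correction
  convention, recorded in the spectrum metadata).  Estimation uses a
  Hann window, ACF length ≤ 1/4 of the trajectory and 4× zero padding;
  band *positions* are the validated quantity, line shapes carry
  ring-polymer/thermostat broadening.  Sampling that cannot resolve the
  stretch band (Nyquist < 4500 cm⁻¹) is refused.
* **Structure**: bead-resolved RDFs (same-slice pairs, ideal-gas shell
  normalization); tetrahedral order
  `q = 1 − (3/8)Σ(cos ψ + 1/3)²` and the shell-separation metric
  `d_fs` on centroids (per-replica variants behind flags).  `d_fs` is
  implemented as the gap between the 5th and 4th nearest oxygen
  neighbours — a documented stand-in validated against its qualitative
  behaviour (≈0.1 nm for separated shells, → 0 with an interstitial).
* **Hydrogen bonds**: geometric criterion `d_OO < 3.5 Å` and
  `θ_HOO < 30°` (angle at the donor O between the covalent O→X bond
  and O→O), applied per replica, averaged per replica, then over
  replicas; for HDO the statistics split by donor species.  Bond
  energy `E_HB = (E_pot − E₀)/n_HB` with `E₀` from a single-molecule
  PIMD run at matched (T, n_b) — a thermal reference, so zero-point and
  intramolecular thermal energy cancel — and `n_HB = 2·bonds/N`
  (each donor–acceptor bond counted toward both partners; convention
  switchable).
* **Delocalization**: ring-polymer gyration radius per species and its
  components in a per-molecule frame built from centroid geometry
  (x̂ along O→X1, ẑ ⊥ molecular plane); the three components sum to
  R_g² exactly by construction.

## Oracles

Closed forms used as independent references throughout the tests:

* free ring polymer: `⟨R_g²⟩ = dim · ħ²β/(12m) · (1 − 1/n_b²)`,
  rederived in `ringpolymer.free_rg2_bruteforce` by summing
  `1/(β_n m ω_k²)` over modes with frequencies from direct
  diagonalization of the cyclic coupling matrix;
* harmonic oscillator: exact finite-bead energy from
  `−∂_β ln Z_n` with `ln Z_n = −Σ_k ln(β_n √(ω_k² + ω²))`, matching
  k_BT at `n_b = 1` and `(ħω/2)coth(βħω/2)` as `n_b → ∞`;
* ideal gas: NPT volume moments, κ_T = 1/P;
* monomer harmonic frequencies from a finite-difference Hessian of the
  analytic forces (isotope stretch ratio = √(μ_OD/μ_OH));
* O(N²) hydrogen-bond enumeration; hand-normalized RDF spikes.

## Problem sizes

The reference profile mirrors the study setup: N = 512 molecules,
n_b = 32, r_c = 1.0 nm, 0.25 fs steps, ns-scale runs (`configs/
cluster_*.yaml`).  The bundled analyses and tests use a desk profile —
N = 32, n_b = 8, ~1.5 ps equilibration + 1.5–2 ps production, cutoff
clipped to half the box edge — chosen so a full isotope scan runs in
minutes on one core.  At this scale the *qualitative* physics is
reproduced and asserted (delocalization orderings R_g(H)>R_g(D)>R_g(T),
anisotropy R_gz²>R_gy²>R_gx², VDOS band ordering and HDO bimodality,
E_HB ≈ −12 kJ/mol, d_OO ≈ 2.85 Å); quantitative study-scale numbers
(D(T) tables, C_P/C_V curves, T_MCT) require the cluster profile and
are *not* claimed by the desk runs.  The synthetic D(T)/H(T) curve
families emulate observable tables with prescribed noise; they carry no
liquid-state correlations, so fit-recovery results validate the
pipeline, not the simulations.

## Known limitations

* Desk-scale cutoffs (≈0.5 nm) truncate the attractive tail; the NPT
  density at 300 K comes out ≈0.95 g/cm³ and diffusion is somewhat
  fast.  These runs are analogues, not replicas.
* Heat capacities at n_b ≤ 32 are not bead-converged (warned).
* The IR prefactor convention is one of several in use; it is recorded
  in the spectrum metadata so spectra are comparable across runs.
* `n_b = 8` underestimates zero-point-dominated quantities (R_g, E at
  low T) relative to n_b = 32; orderings are unaffected.
* No Ewald/PME option; the reaction field is part of the model spec
  here.  No bosonic exchange, higher-order Trotter factorization, or
  path-integral Monte Carlo.
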