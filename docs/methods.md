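# Methods

This note documents the models, numerical choices and limitations behind
`neaspec`. Units are Å, amu, eV, fs and cm⁻¹ throughout; all conversions
live in `neaspec.constants` (CODATA 2018).

## Cross-section assembly

The cross-section on an energy grid E is

σ(E) = (K/E) · Σ_J (1/N_p) Σ_n ΔE_0J(R_n) · f_0J(R_n) · w_s[E − ΔE_0J(R_n); δ],

with K = πe²ħ/(2 m_e c ε₀) = 1.09761×10⁻¹⁶ eV·cm² evaluated from CODATA
constants, and the vacuum refractive index fixed at n = 1. The ΔE/E
weighting is unity at line center; for lineshapes much narrower than the
band it integrates to the sum rule ∫σ dE = K·⟨Σ_J f⟩. A switch
(`energy_weighting=False`) drops the ΔE/E factor for cross-checks; the two
forms agree at line centers and differ only at the δ/E level in the wings.

δ is interpreted as the **FWHM** of the unit-normalized lineshape
(Lorentzian default, 0.05 eV). Broadening is always performed on the
energy axis; the wavelength column of written spectra is derived afterward
as λ = hc/E. The default grid covers [min ΔE − 5δ, max ΔE + 5δ] at spacing
δ/10, which resolves the lineshape; halving the spacing changes band
integrals by < 0.1%. Integrated-strength recovery
(`integrated_strength`) adds back the analytically known lineshape mass
outside the grid window — for a Lorentzian, 1 − (2/π)·arctan(2L/δ) for a
half-window L, which is at the percent level even for windows of tens of
FWHM and cannot be ignored.

Conformer averaging multiplies each conformer's spectrum by its normalized
Boltzmann factor exp(−ΔE_i/k_BT) (energies zero-shifted to the minimum
before exponentiation). Composite spectra — fragment-sum estimates of a
multichromophoric parent — are plain unweighted sums and carry a
`composite` metadata flag. Grids must match exactly; there is no silent
regridding.

The reflection-principle reference (`reflection_reference`) is the
closed-form push-forward of a Gaussian coordinate density through a linear
gap map: a Gaussian band of std |κ|σ_x, convolved with the lineshape
(Gaussian ⊛ Gaussian in closed form; Gaussian ⊛ Lorentzian as an exact
Voigt profile). It is a validation oracle, not a production path.

## Harmonic analysis

Cartesian Hessians are symmetrized on construction, mass-weighted, and
Eckart-projected: the mass-weighted rigid translations and infinitesimal
rotations (rank-detected, so linear molecules lose five external modes)
are removed by an orthogonal projector before diagonalization. Wavenumbers
below a 10 cm⁻¹ floor are dropped as residual external motion; the
package's model molecules have no physical modes that low, and the floor
is configurable. Imaginary frequencies are reported as negative
wavenumbers and flagged; samplers refuse them unless the mode is
explicitly excluded, since a Gaussian Wigner density does not exist for an
inverted mode.

Finite-difference Hessians of the analytic potentials use central
differences of the gradient (default step 10⁻³ Å) with Richardson
extrapolation — combining the h and h/2 stencils to cancel the O(h²)
term. Without it, the quartic terms of soft curvilinear coordinates
(dihedrals) bias frequencies at the 10⁻⁴ relative level and break rigid-
rotation invariance; with it, frequencies are orientation-invariant to
~10⁻⁹.

## Wigner sampling

Each non-excluded normal coordinate is drawn from
N(0, (ħ/2ω)·coth(ħω/2k_BT)); momenta (optional, unused by the spectrum
pipeline) from N(0, (ħω/2)·coth(·)). The Cartesian back-transform
x = x_ref + M^(−1/2) Σ L_i Q_i is deliberately rectilinear — no
curvilinear correction — so the known torsion artifact is reproducible;
the supported mitigation is the excluded-mode set, which freezes
Q_i = P_i = 0 exactly. The default temperature is 0 K with finite
temperature optional; ensembles are bit-reproducible for a fixed seed.

## Quantum thermostat

Dynamics follow a symmetric splitting per step: exact GLE half-step on the
(mass-weighted momentum, auxiliary momenta) vector, velocity half-kick,
position drift, force refresh, half-kick, GLE half-step. The GLE substep
is the exact Ornstein–Uhlenbeck update (u,s) ← T(u,s) + Sξ with
T = exp(−A dt/2) and S Sᵀ = C − T C Tᵀ (symmetric square root; an
indefinite result beyond 10⁻¹⁰ rejects the A/C pair). The thermostat
therefore adds no step-size error; the only discretization error is the
Verlet (ωdt)² term, ≲1% in position variance at dt = 0.5 fs for
3600 cm⁻¹. The thermostat acts per Cartesian degree of freedom on
mass-weighted momenta, so one (A, C) pair serves all atoms. A blow-up
guard aborts if any single-step displacement exceeds 0.5 Å.

**Bundled matrices.** The Ns = 6 drift matrix is built from three
damped-oscillator channels — 2×2 blocks [[α, ω̃], [−ω̃, α]] with
antisymmetric momentum coupling, which gives positive friction and
unconditional stability — plus a weak white-noise term. The noise matrix
B is diagonal and C solves A C + C Aᵀ = B Bᵀ, so positivity of the
fluctuation-dissipation pair holds by construction. Parameters were
optimized so that the **exact stationary variances** of a thermostatted
harmonic oscillator (continuous Lyapunov equation, exposed as
`harmonic_stationary_variance`) match (ħω/2)·coth(ħω/2k_BT) at 296 K over
160–3700 cm⁻¹, with a penalty keeping the slowest relaxation rate of the
thermostatted oscillator above ~3×10⁻³ fs⁻¹ across the band (so ~100 ps
trajectories yield percent-level variance statistics). The fit is staged:
an accurate weak-coupling solution first, then the mixing floor is ramped
(homotopy) — a direct strongly-coupled fit reliably falls into poor local
optima. Residual bias of the bundled set is ≤ ~2% at 300/1000/3600 cm⁻¹
and ≤ ~4% across the fitted band; outside it (< 160 or > 3800 cm⁻¹) the
effective temperature degrades gracefully toward the classical value.
`scripts/fit_qt_matrices.py` regenerates the set.

Equilibration is detected from the per-step kinetic temperature: the
first index whose forward window mean agrees with the remaining-trajectory
mean within a relative tolerance (default 5%), with the window required
not to swallow the tail (which would make the test self-fulfilling).
Snapshots are then taken at uniform stride over the equilibrated segment.
Frames are never re-assigned between conformer basins; each trajectory
keeps its starting conformer label.

## Model systems

The generator's defaults are the study conditions and are not tuned per
run.

**Torsion–stretch toy** (the rectilinear-artifact system): four sites —
two heavy (16 amu) anchors defining a reference plane, a heavy bond
partner, and a 1.008 amu light atom at r0 = 0.96 Å. The potential
½k_r(r−r0)² + ½k_θφ² depends only on internals (bond length and dihedral),
so it is rotation-invariant. Force constants are derived from the target
wavenumbers (3600 cm⁻¹ stretch, 200 cm⁻¹ torsion — the hydroperoxide
regime) through the curvilinear reduced masses: the stretch uses
μ = m_H·m_anchor/(m_H+m_anchor), the torsion the Wilson G-matrix effective
inertia 1/Σ|∇φ|²/m evaluated by finite differences, which makes the
rectilinear normal-mode analysis land on the design wavenumbers to ~10⁻⁶.
The exact curvilinear sampler draws (r, φ) from the factorized quantum
(thermal) harmonic densities and embeds by rigid rotation about the
anchor axis; anchor recoil along the embedding is neglected (heavy
anchors). At 296 K the thermal factor on the 200 cm⁻¹ torsion
(coth ≈ 2.2) is what pushes the Wigner/exact std(r) ratio above 1.5; at
0 K the same geometry gives ≈1.26.

**Soft-intermolecular toy** (the microsolvation system): collinear
C(12)–O(16)···W(18 amu, a point-mass water) with
V = ½k_intra(q − cQ)² + D(1 − e^(−aQ))² + k_wall·max(0, Q − Q_wall)⁴,
where q is the stiff carbonyl-like bond (1700 cm⁻¹) and Q the soft
contact (150 cm⁻¹ harmonic wavenumber, Morse depth D = 0.25 eV — a typical
hydrogen-bond well). The bilinear coupling (c = 0.05) shifts the
chromophore equilibrium as the contact breathes. The quartic wall
(5 eV/Å⁴ beyond 0.8 Å) represents the surrounding environment: without
it, the Kramers escape probability over the 0.25 eV barrier is a few
percent per 50 ps trajectory, and an escaped (dissociated) contact makes
the sampled width meaningless. The wall is ~8 thermal standard deviations
out and does not perturb the well-region density. The quantum thermal
width of this Morse contact is ~25% larger than its harmonic
approximation (checked against a sinc-DVR reference during design), which
sets the expected QT-over-Wigner broadening.

**Toy chromophores** map one internal coordinate to (ΔE, f) per state:
linear gap ΔE = E0 + κ(q−q0), or exponential decay ΔE = E0·e^(−α(q−q0))
mimicking a dissociative nσ* state whose energy collapses as the bond
stretches; strengths constant or linear (clipped at 0). Non-positive gaps
raise, listing the offending members — they indicate map misuse, not data.

`stratified_normal` provides jittered-stratified normal sampling
(marginally exact, seeded, unbiased): each draw comes from one of n
equal-probability strata. Oracle-validation fixtures use it because
pointwise density comparison at N_p = 5000 under i.i.d. sampling carries
~10% noise at narrow lineshapes, which would swamp the systematic
deviation being measured; stratification reduces it to ~0.3% without
changing the marginal law.

## Photolysis rates

j = ∫σφF dλ by trapezoid on the union of the three wavelength grids with
linear interpolation — the convention of piecewise-linear atmospheric
tables, and exact for rectangle/triangle fixtures. Outside any table's
support the contribution is zero (no extrapolation). Quantum yields above
1 warn (multi-fragment conventions) rather than fail.

## Problem sizes

Default ensembles are 500 geometries per conformer. Validation runs use:
20 000 Wigner samples for variance exactness (3 standard errors at
√(2/n) ≈ 1%), 2×10⁵-step (100 ps) thermostatted trajectories for harmonic
exactness (statistical error 3–5% given the fitted relaxation rates),
4000-member ensembles for the artifact ratios, and 5000 stratified samples
for the reflection comparison. These sizes put statistical error
comfortably below each check's tolerance while keeping the full suite
under a minute.

## Limitations

* Vibronic structure is absent by construction — the NEA averages
  broadened vertical lines and cannot produce Franck–Condon progressions.
* Rectilinear Wigner sampling is kept deliberately; mode exclusion is a
  mitigation, not a cure (the excluded mode's true width is simply absent).
* The QT matrices are fitted for 296 K and 160–3700 cm⁻¹; other
  temperatures or very soft/stiff systems need refitted matrices
  (`scripts/fit_qt_matrices.py`).
* Model potentials emulate the *mechanisms* (soft torsion, anharmonic
  contact) at realistic frequencies and masses, not any specific
  molecule's surface; passing tests demonstrates the sampling physics and
  the pipeline's correctness, not chemical accuracy for a real VOC, which
  additionally depends on the external electronic-structure engine feeding
  the transition-table contract.
* Conformer interconversion during QT runs is not re-weighted; trajectories
  keep their starting labels and cross-basin statistics are left to the
  user's judgment.
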