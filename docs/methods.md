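# Methods

## Model and assumptions

**Dipolar cross-relaxation.**  Rates are the isotropic-tumbling Solomon
expression σ = K r⁻⁶ τ_c [6/(1+4ω₀²τ_c²) − 1] with
K = (1/10)(μ₀/4π)² ħ² γ⁴ (γ for ¹H, ω₀ defaulting to 2π·500.17 MHz).  The
sign changes at ω₀τ_c = √5/2; the peak-fitting layer reports magnitudes,
since build-up amplitudes are phased positive in practice, while the
relaxation engine keeps the signed rate.  Chemical exchange contributions,
scalar relaxation, cross-correlated relaxation, and anisotropic tumbling
are all out of scope.

**Relaxation matrix.**  NOESY blocks are M(τ_m) = exp(−R τ_m) with
off-diagonals −σ_ij and diagonals the like-spin auto-relaxation
ρ_i = Σ_j K r_ij⁻⁶ τ_c [1 + 3/(1+ω₀²τ_c²) + 6/(1+4ω₀²τ_c²)] plus an
optional external leakage rate.  Symmetric matrices are evolved by
eigendecomposition (deterministic); non-symmetric fall back to a Padé
matrix exponential.  Groups of n equivalent protons can scale the transfer
into them by n, switchable off for strict per-proton simulation.

**Distance averaging.**  Three models by motion regime: slow (>100 ps,
aromatic CH and hydrogen-bond-locked CH₂): ⟨r⁻⁶⟩⁻¹ᐟ⁶ over the n_I·n_S
member pairs; medium (50–100 ps): ⟨r⁻³⟩⁻¹ᐟ³; fast (<50 ps, methyls): the
second-order spherical-harmonic average
r = [C Σ_k w_k |⟨Y_2k(θ,φ)/r³⟩|²]⁻¹ᐟ⁶.  The normalization C = 4π/Σw_k is
fixed by the static-limit identity (a single vector must return its own
length; the addition theorem then gives C = 4π/5 for uniform weights).  The
semi-empirical harmonic weights published for methyl groups are not openly
tabulated, so the default is uniform — which also makes the model exactly
rotation-invariant — and user-overridable.  Note that orientational
averaging of equal-length vectors can only lengthen the effective distance
(the averaged harmonics partially cancel, and the inverse-sixth root flips
the inequality).

**Group averaging across conformers.**  The effective distance of a
conformer family is (mean r⁻⁶)⁻¹ᐟ⁶ of the per-conformer values — the
averaging a fast two-state exchange performs physically, and the only
choice that reproduces all tabulated open/closed group cells of both the
computed-conformer and crystallographic bicalutamide tables to 0.01 Å (the
arithmetic mean fails already on the open family, 3.41 vs 3.35 Å).

**Classification.**  Three interchangeable rules: explicit lists; a marker
distance threshold (default 3.85 Å, the midpoint of the two group means);
and the peripheral-fluorine rule (<6 Å closed, >9 Å open) whose 6–9 Å dead
zone deliberately raises rather than guesses.  Distance-based grouping is
authoritative here: no single torsion angle separates the families.

**PANIC / IRA.**  Normalized amplitude a(τ) = cross / diagonal; the
default divisor is the geometric mean of both diagonal peaks (symmetric,
halves single-diagonal distortion), with single-diagonal modes available.
The rate is the origin-constrained least-squares slope over points with
a ≤ 0.1 (configurable); for a two-spin system a(τ) = tanh(στ), so the
window bound caps the relative linearization bias near (στ)²/3 ≈ 0.3%, and
the tests verify the bias shrinks monotonically as the window tightens
(0.3 → 0.1 → 0.03).  The standard error is the ordinary no-intercept OLS
error; zero-diagonal points are excluded per-point with a QC flag, and
whole pairs can be excluded by named QC rules (e.g. T1 noise,
diagonal-peak overlap) without touching the rest of the table.

**ISPA and the two-state inversion.**  r_exp = r₀(σ₀/σ_exp)¹ᐟ⁶ with
first-order error (r_exp/6)·√((δσ₀/σ₀)² + (δσ_exp/σ_exp)²).  The inversion
P_open = r_open⁶(r_close⁶−r_exp⁶)/(r_exp⁶(r_close⁶−r_open⁶)) and the
forward mixture r_exp⁻⁶ = P_open r_open⁻⁶ + P_close r_close⁻⁶ are exact
algebraic inverses (tested to 1e-12).  Infeasibility (P outside [0,1]) is
a reported status carrying the raw value, because a distance outside the
attainable range is a scientific finding about the candidate structures.
N-state inversion from a single distance is under-determined and not
offered; only the forward N-state average is.

**Uncertainty.**  The published population intervals come with no stated
method, so the package's primary route is seeded Monte Carlo: rates (and
optionally group averages) drawn from independent normals truncated to
positive, infeasible draws counted and excluded, the spread of P_open
reported.  A first-order delta-method propagation is provided for
comparison; on the chloroform inputs the two routes agree to within ~35%.

**Superposition RMSD.**  Kabsch least-squares rotation (via scipy's
align_vectors) restricted to proper rotations — enantiomers are not
superposed, a deliberate caveat for a racemic compound.  Heavy atoms only
by default (crystallographic hydrogens are usually riding-model
artifacts); all-atom optional.  The residual is recomputed explicitly from
the aligned coordinates because the solver's reported residual loses
precision near zero.

**Boltzmann weighting.**  w_i ∝ exp(−ΔG_i/RT) with T defaulting to
298.15 K and energies re-referenced to the column minimum (weights are
shift-invariant; the re-referencing is purely numerical).  Energies are
accepted in kJ/mol only, with an explicit hartree converter — no silent
unit detection anywhere in the package.

## Fixtures

The packaged tables carry the published model-averaged distances for the
ten computed bicalutamide conformers and the seven deposited structures,
the gas-phase relative conformer energies, and the four measured rates.
The DMSO-d₆ marker rate is stored as 3.12×10⁻³ s⁻¹: the source report
prints 3.12×10⁻² s⁻¹, but that value is inconsistent with the
accompanying experimental distance (3.55 Å) and both reported population
fractions, all of which the corrected exponent reproduces; the fixture's
note column records the substitution.

Against the crystallographic families, the chloroform inversion yields
fractions {83.5%, 16.5%} with the *open* family in the majority, while the
narrative order of the published assignment is 16.4% open / 83.6% closed;
the package reports both fractions and the comparison targets the minority
value, flagging the label pairing rather than silently relabeling.

## Synthetic data: what it emulates and what it does not

The generator builds minimal four-proton scaffolds — a fixed reference
pair (1.78 Å), a marker proton whose distance is drawn per conformer from
N(mean, jitter²) with family means 3.35/4.21 Å, and a spectator — because
the inference chain depends only on distances, and tiny fully-controlled
geometries keep every stage checkable.  Experiments default to τ_c = 50 ps
(a small rigid molecule in a light solvent; the published analysis states
no value, so this is an explicit package choice honoring the <100 ps
motion bands), the 500.17 MHz field, an 8-point geometric mixing-time grid
over 0.05–0.8 s, and 5% multiplicative Gaussian noise on all intensities
(spectral noise scales with integration volume; an additive option
exists).  Populations split evenly within each family, and each pair is
evolved as an isolated two-spin system at its population-averaged
effective distance — exact for σ ∝ r⁻⁶, but it deliberately omits
spin diffusion through third protons, strong-coupling artifacts, peak
overlap, and baseline/phase errors.  Passing recovery tests therefore
demonstrate the correctness of the inference arithmetic under the stated
noise model, not robustness to every pathology of real spectra.

Recovery at these defaults: noiseless and jitterless chains return the
truth within 0.02 (residual initial-rate bias); at 5% noise over 100
replicates the mean estimate sits within two Monte-Carlo standard
deviations of the truth, and the estimate is monotone in the true
fraction.

## Numerical choices and degenerate inputs

- Distances in Å everywhere; conversion to metres only inside the rate
  constant.  Table output rounds to 0.01 Å; full precision is kept
  internally.
- Torsions follow the signed IUPAC convention via the atan2 form; collinear
  central atoms raise a degenerate-geometry error, as do coincident
  H-bond atoms.  Mirror reflection flips the torsion sign (tested).
- XYZ parsing accepts an optional 5th column as the atom label (chemical
  numbering must be able to travel with coordinates); otherwise labels are
  element+ordinal.  The minimal PDB reader takes the first alternate
  location and ignores occupancies.
- The reference-free screen fits the amplitude in closed form
  (A = Σσr⁻⁶/Σr⁻¹²); R² may be negative by construction and ties rank
  lexicographically.  A free-exponent variant exists behind a flag but is
  not the default screen.
- Monte-Carlo draws below zero are resampled (truncation), keeping rate
  and distance draws physical; the draw count floor is 10³.
- Replicate sub-seeds are drawn from a generator seeded by the experiment
  seed, keeping every replicate reproducible and independent.

## Known limitations

- Distance tables, not raw spectra, are the entry point: peak picking,
  Fourier processing, and resonance assignment live upstream.
- The two-state model assumes fast exchange and exactly two families;
  intermediate-exchange lineshape effects are not modeled.
- The spherical-harmonic fast-motion weights default to uniform; published
  semi-empirical weights, where available to a user, should be supplied in
  the configuration.
- Solvated free energies are inputs; the package computes no quantum
  chemistry and no continuum-solvent models.
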