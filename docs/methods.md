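# Methods

## The model

### Standard (MFP) rotational strengths

For a closed-shell molecule the VCD rotational strength of fundamental *i*
is

    R_i = Im[ E_i^tot · M_i^tot ]

with the electric and magnetic transition moments obtained by contracting
the atomic polar tensor (APT, `P = E + N`) and atomic axial tensor (AAT,
`A = I + J`) with the Cartesian-to-normal-mode transformation `S`:

    E_{i,β}^tot = (ħ/2ω_i)^{1/2}   Σ_{λα} P^λ_{αβ} S_{λα,i}
    M_{i,β}^tot = −(2ħ³ω_i)^{1/2}  Σ_{λα} A^λ_{αβ} S_{λα,i}

The nuclear parts are closed-form: `N^λ_{αβ} = e Z_λ δ_{αβ}` and
`J^λ_{αβ} = (Z_λ/4c) Σ_γ ε_{αβγ} R⁰_{λγ}` (so `J` is exactly antisymmetric
and vanishes for an atom at the gauge origin). The dipole strength is the
standard `D_i = |E_i^tot|²`.

For real ground-state wavefunctions, AAT blocks and magnetic transition
moments are purely imaginary. The package stores their imaginary parts as
real numbers, so every `Im[...]` above reduces to a real dot product. The
global sign convention is pinned operationally: mirroring a bundle (negating
all AATs and MDTMs) must flip every rotational strength and preserve every
dipole strength, and this invariant is asserted in the test suite rather
than argued from convention.

### Sum-over-states enhancement from low-lying excited states

Open-shell transition-metal complexes have electronic states a few tenths of
an eV above the ground state. In the sum-over-states vibronic treatment
these states add frequency-dependent corrections to the APT and AAT; the
correction to the rotational strength is the pair of cross terms

    R_i^enh = Im[ E_i^tot · M_i^enh + E_i^enh · M_i^tot ]

    E_{i,β}^enh = 2 (ħ/2ω_i)^{1/2}  Σ_e f_ie ⟨g|μ_β|e⟩ ⟨e|∂g/∂Q_i⟩
    M_{i,β}^enh = −(2ħ³ω_i)^{1/2}   Σ_e f_ie (⟨e|m_β|g⟩ / ω_eg) ⟨e|∂g/∂Q_i⟩

with the resonance factor

    f_ie = ω_i² / (ω_eg² − ω_i²)

and `⟨e|∂g/∂Q_i⟩` the Cartesian non-adiabatic coupling (NAC) projected onto
normal mode *i*: `NAC_i = Σ_{λα} S_{λα,i} ⟨e|∂g/∂R_{λα}⟩`. The factor 2
appears only in the electric summand and the magnetic summand carries an
extra `1/ω_eg`; the second-order product `E^enh · M^enh` is *not* included.
Note `f_ie` is large only when the excitation energy nearly coincides with a
vibrational frequency, and is *negative* for a state below the mode — a
sub-band state contributes with inverted sign.

Assumptions and known biases:

* **Vertical approximation.** Excited surfaces are treated as undisplaced
  copies of the ground-state surface; no Franck–Condon weights are applied.
  When an excited state relaxes appreciably this biases the enhancement,
  which is the motivation for treating excitation energies as tunable
  parameters rather than trusting computed values.
* **Pole guard.** `f_ie` diverges at exact resonance. Energies within δ =
  50 cm⁻¹ (configurable) of any mode are refused (`ResonanceError`); the
  optimizer substitutes a large negative objective value there instead of
  raising. A per-state diagnostic lists modes within 3δ.
* **States are independent sum terms.** No multiplicity weighting is
  applied; degenerate components enter as separate states.

### Spectra and similarity

Stick strengths are broadened with unit-area Lorentzians (default HWHM γ =
6 cm⁻¹, typical of solution-phase mid-IR work) and the conventional
frequency-weighted prefactors; with `D` in 10⁻⁴⁰ esu²cm² and `R` in 10⁻⁴⁴
esu²cm²:

    ε(ν)  = ν Σ_i D_i L_i(ν) × (10⁻⁴⁰/9.184·10⁻³⁹)
    Δε(ν) = ν Σ_i R_i L_i(ν) × (10⁻⁴⁴/2.296·10⁻³⁹)

A single multiplicative frequency scaling factor (fixed from IR, never
fitted against VCD) is the only frequency calibration.

Similarity between two spectra is the max-normalised overlap

    S(f, g) = ∫ f g dν / max(∫ f² dν, ∫ g² dν)  ∈ [−1, 1]

on a common 1 cm⁻¹ grid (linear resampling, trapezoidal integration),
default window 1000–1600 cm⁻¹. This normalisation penalises magnitude
mismatch (`S(f, 2f) = 1/2`) — informative here, because enhancement changes
band *areas*, not just shapes — and is antisymmetric under negating one
argument, which the configuration assignment exploits. No frequency-scale
optimisation happens inside the score. The exact window/normalisation used
to produce any particular published similarity number is generally not
recoverable; scores computed here are method-consistent rather than
value-matched against external reports.

## Excitation-energy fitting

Transition moments and NACs are kept fixed; the lowest excitation energies
are bounded parameters (defaults 0.05–1.0 eV) maximising simVCD against a
reference spectrum. The lower bound keeps the resonance factor finite below
the fingerprint band; the upper bound is where non-contributing states park.

The search is deliberately simple and fully deterministic given a seed:

1. Latin-hypercube sample of `n_starts` (default 16) starting points;
2. bounded Nelder–Mead from each (the objective is cheap, ≤3-dimensional,
   and non-smooth at the pole guard, so derivative-free local search fits);
3. a coordinate-wise sweep on a 0.005 eV grid of valid energies per tuned
   state, with Nelder–Mead re-polish on improvement, repeated up to twice.
   This step matters because the pole guard fragments the energy axis into
   disconnected pockets (narrow gaps between vibrational bands) that a
   simplex cannot cross;
4. an identifiability sweep: if moving a state's energy to the upper bound
   changes the objective by < 10⁻⁹ the state is pinned there and its
   `bound_hit` flag set — this is how a zero-coupling state is reported,
   since a flat objective direction would otherwise leave it wherever the
   best start happened to put it.

Diagnostics include per-state solo scores (similarity of each state's
enhancement-only spectrum against the reference, without the MFP part) and
near-resonance mode lists.

## Absolute-configuration assignment

The reference is fitted twice: as given, and sign-inverted (the spectrum the
opposite enantiomer would produce). The verdict is `assigned-as-given` /
`assigned-as-mirror` only when

* the winning score reaches the reliability threshold (default 0.4),
* no *contributing* state of the winning fit sits below the plausibility
  floor (default 0.10 eV), and
* the winner leads by the decision margin (default 0.15) **or** the losing
  fit itself is red-flagged.

The last clause reflects how wrong-enantiomer fits fail in practice: the
optimizer can push a state *below* the vibrational band, where the negative
resonance factor flips its contribution, and thereby reach a deceptively
high score — but only at an implausibly low energy. Such a loser is
evidence for the winner, not against it. Anything else is `inconclusive`,
which is a valid outcome, not an error.

## Synthetic data generator

`synth.make_bundle` emulates the data regime of an open-shell metal complex
with a chiral ligand cage; it is the package's test bed, not a force field:

* a compact cluster (metal at the gauge origin, a 2.0–2.4 Å ligand shell,
  filler atoms at 2.5–4.5 Å);
* normal modes `S = M^{−1/2} U` with `U` a seeded random orthonormal frame —
  exactly mass-weighted-orthonormal by construction; frequencies uniform in
  950–1650 cm⁻¹ (fingerprint region);
* electronic APT `−Z·1 + N(0, 0.3 e)` per block (screened effective
  charges); nuclear APT/AAT *computed* from the closed forms above, never
  drawn;
* electronic AAT `N(0, 0.05)` in the 1/c-absorbed atomic units, comparable
  to the nuclear AAT of second-row ligand atoms a few bohr from the origin;
* MDTM components `N(0, 8·10⁻³)` (vector norms of a few Bohr magnetons,
  typical of spin-allowed d–d transitions) and EDTMs zero by default
  (Laporte-forbidden d–d states; a scale knob enables them);
* NAC components `N(0, 0.5)` bohr⁻¹ on a masked atom subset only (default:
  metal + four neighbours), emulating the locality of the coupling to atoms
  bonded to the metal.

With these scales the enhancement at the default state energies is of the
same order as the MFP signal — the regime where enhanced VCD is actually
observed. The shipped demo fixture (`demo_spec`) is a 30-atom cluster with
three zero-EDTM states at (0.23, 0.23, 0.42) eV and a 5-atom coupling mask:
magnetic channel dominant, two near-degenerate contributing states, one
inert higher state.

What the generator does **not** emulate: real vibrational force fields and
mode mixing, anharmonicity, solvent effects, baseline drift or correlated
experimental noise (reference noise is additive white Gaussian, with
standard deviation quoted relative to the maximum signal inside the scored
fingerprint window), conformational flexibility. Passing tests demonstrate
the correctness and internal consistency of the formalism and the
robustness of the fitting protocol under known ground truth — not the
accuracy of any particular quantum-chemistry input.

The enantiomer transform is algebraic (negate all AATs and MDTMs) rather
than geometric (reflect coordinates): axial tensors and magnetic moments
are pseudoquantities and change sign under improper operations while polar
quantities do not, so the transform yields the exact `R → −R` property
without re-deriving wavefunction parities, and it is an involution.

## Numerical choices

* Atomic units internally (ħ = e = mₑ = 1, c = 1/α); Å/amu/eV/cm⁻¹ accepted
  at the I/O boundary; CODATA 2018 constants in `constants.py`, including
  the output conversions (e·a₀)² = 6.46·10⁴ × 10⁻⁴⁰ esu²cm².
* Bundle files are saved in atomic units so a save/load round trip is exact
  to the last bit; the loader converts from Å/eV/cm⁻¹ when declared.
* Mass-weighted orthonormality of imported S matrices is validated (default
  tolerance 10⁻⁶) with a warning, never silently fixed — upstream
  conventions vary.
* Similarity of two spectra that are both identically zero on the window is
  defined as 1 (they are equal).
* Lorentzian band positions use the already-scaled mode frequencies;
  `apply_scale` records the factor for provenance.
* Strength components (`mfp` + `enhancement`, per-state, per-channel) are
  bookkept so that channel sums are exact and per-state sums re-associate
  to the total within 10⁻¹⁰ relative.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: micro-systems of ≤3 atoms/≤2 modes for brute-force equivalence,
8-atom/10-mode bundles for the fitting batteries (20 fixtures each for
recovery and assignment), and the 30-atom demo fixture for pipeline-level
checks. Planted energies for the recovery battery are drawn uniformly in
0.15–0.45 eV, resampled if within 100 cm⁻¹ of a mode — a truth inside the
pole-guard exclusion zone is unrecoverable by construction.

## Known limitations

* No Franck–Condon/vibrational-overlap corrections (vertical approximation
  only); the energy fit partially absorbs, but cannot remove, this bias.
* Gauge-origin dependence of AATs and MDTMs is the caller's responsibility:
  bundles carry an `origin_note` and the package never re-origins data.
* The similarity score has no uncertainty model; no Bayesian posterior on
  fitted energies.
* Single rigid structure only — no conformational averaging.
* JCAMP-DX and program-specific quantum-chemistry outputs are not parsed;
  the JSON bundle is the single ingestion path.
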