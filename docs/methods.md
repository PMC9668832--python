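# Methods

This note records the models implemented in `amidyn`, the conventions
and defaults chosen where several were defensible, and what the
synthetic-data validation does and does not demonstrate.

## Relaxation rates

R1 and R2 are extracted per residue by unweighted nonlinear least
squares of the two-parameter model `I(t) = I0·exp(−R·t)`; no baseline
offset is fitted. Standard errors come from the variance–covariance
matrix at the optimum. Initialisation uses `I0 = max|I|` and the
log-ratio of the first and last points, with five seeded multi-start
perturbations on non-convergence; a fit that still fails is returned
flagged, never as a silent NaN. Delays are read in milliseconds and
converted to seconds; rates are always s⁻¹. Replicate delay points are
fitted jointly, not averaged. Intensity uncertainties are not used as
weights: with a single spectral noise level per spectrum, weighting is
uniform anyway, and stated noise levels are often less reliable than
the scatter itself.

The bundled delay schedules are sixteen R1 delays from 0 to 3.52 s and
nineteen R2 delays from 0 to 250.16 ms, evenly spaced. NOE errors are
`|NOE|·√(SNR_sat⁻² + SNR_ref⁻²)`.

## Interaction constants

One `NMRConstants` object feeds both the spectral density mapping and
the model-free forward model, so the two are consistent by
construction:

| parameter | default | unit |
|---|---|---|
| γ_H | 2.6752218744×10⁸ | rad s⁻¹ T⁻¹ |
| γ_N | −2.7126×10⁷ | rad s⁻¹ T⁻¹ |
| r_NH | 1.02 | Å |
| Δσ (¹⁵N CSA) | −160 | ppm |

The dipolar constant is d = μ0·ħ·γ_H·γ_N/(4π·r_NH³) and the relaxation
expressions carry the conventional d²/4 and c² = (ω_N·Δσ)²/3 factors.
Any self-consistent convention leaves the consistency ratio invariant;
these defaults give R2 ≈ 14 s⁻¹ at 700 MHz for a rigid residue at
τ_c = 9 ns.

## Reduced spectral density mapping and the consistency ratio

The single high-frequency reduction is used: σ_NH = R1·(NOE−1)·γ_N/γ_H,
J(0.87ω_H) = σ_NH/(5·d²/4), J(ω_N) = (R1 − 7·(d²/4)·J(0.87ω_H))/(3·d²/4
+ c²), and the apparent J(0) from R2 as written in `amidyn.jmap`. The
mapping is exact only in the limit where J varies slowly around ω_H;
for τ_c in 4–20 ns and S² ≥ 0.5 the J(0) bias stays below 5%, and it
largely cancels in the two-field ratio (RC deviations < 2·10⁻⁴ on
noiseless data).

RC is defined as the higher-field over the lower-field apparent J(0)
(950/700 by default), one number per residue; this choice (rather than
each-field-over-consensus) is recorded in the output metadata. Errors
are propagated by 1000 Gaussian Monte-Carlo draws of the observables
(seeded). A residue is flagged as exchanging when RC − 1 > 3·RC_err.

Detection power follows from the mapping algebra: an exchange term Rex
at 700 MHz raises J(0)_app by Rex/(2·d²/4 + ⅔c²) at 700 and by ~1.47×
that at 950, so RC − 1 ≈ 0.47·ΔJ0/(J0 + ΔJ0). With 2% intensity noise
(R2 errors of 2–3% from the fit covariance) the resulting RC_err of
~4% means a 3σ flag requires Rex ≳ 6 s⁻¹ at τ_c ≈ 11 ns; Rex = 3 s⁻¹
is only 3σ-detectable for τ_c ≲ 5 ns. This is an information limit of
the two-field experiment at that noise level, not a property of the
implementation; weaker exchange still shifts RC upward (RC is strictly
monotone in Rex) and is recovered by the model-free R_ex term instead.

## Anisotropic model-free analysis

The spectral density is the Woessner asymmetric-rotor form with five
correlation times and amplitudes determined by (D1, D2, D3) and the
direction cosines of the N–H vector in the tensor frame, extended with
Lipari–Szabo internal motion: each term carries S²·τ_k plus
(1−S²)·τ'_k, 1/τ'_k = 1/τ_k + 1/τ_int. The isotropic limit (Δ → 0) is
handled by zeroing the asymmetry weights, and the isotropic, axial and
asymmetric branches agree to 1×10⁻¹⁰ in their shared limits.

C2 symmetry is exploited exactly as the four-parameter construction:
the input structure frame must carry the symmetry axis on z
(`structmap.align_c2` produces this), leaving one Euler angle γ about
z. Since (D1, D2, γ) and (D2, D1, γ+90°) generate identical spectral
densities (as do γ and γ+180°), tensors are canonicalised to D1 ≤ D2,
γ ∈ [0°, 180°). Symmetry-equivalent residues in the two chains share
one observable set — a symmetric apo dimer shows one peak per residue —
and chain-qualified ids are used when symmetry is broken.

R_ex is reported at the reference field (700 MHz default) and scales as
(B/B_ref)², the fast-exchange limit; this convention is recorded in the
output header.

**Tensor fit.** The rigid subset excludes residues with NOE(700) ≤
0.65 (fast internal motion) or |RC − 1| > 2·RC_err (exchange), both of
which would bias the tensor; at least 10 rigid residues are required or
the fit refuses. The search profiles (S², τ_int) per residue on a
vectorised grid inside a multi-start (8 starts over anisotropy × γ)
Nelder–Mead over (log D1, log D2, log D3, γ), seeded from an isotropic
τ_c scan.

**Local fits.** Four nested models M0{S²}, M1{S², τ_int}, M2{S²,
R_ex}, M3{S², τ_int, R_ex} are fitted by bounded weighted least squares
against the six observables (τ_int is carried in ns inside the
optimiser so all parameters are O(1)); selection minimises
AICc = χ² + 2k + 2k(k+1)/(n−k−1) with n = 6, ties resolved toward
fewer parameters. A config switch (`force_model="M3"`) disables
selection. Zero stated errors (exact synthetic data) receive a 0.1%
weighting floor so the weighted problem stays defined.

**Orchestration.** Global fit and local fits alternate (block
coordinate descent) until the relative χ² change drops below 10⁻⁶
(max 20 rounds); with a fixed seed the output tables are bit-identical
across reruns. Monte-Carlo errors then resample every observable from
N(observed, stated error) and refit each residue's selected model with
the tensor held fixed, 200 iterations by default; residues with > 20%
failed refits are flagged `mc_unreliable`.

## Ligand analytics

CSP combines proton and nitrogen shift changes with the 0.1 nitrogen
weight. The 7PA statistic uses proton shifts only, converted to Hz via
the spectrometer frequency, summed over exactly seven reporter
residues supplied by the user (the reporter set is an input, not
inferred); hit thresholds default to 100/300 Hz. The screen hit rate
is (hit mixtures × assumed hits per mixture)/library size, as a
percentage rounded to the nearest integer.

K_d fitting uses the closed-form 1:1 isotherm (the physically relevant
root of the binding quadratic), parameterised directly in (K_d, δ_b)
so standard errors come straight from the covariance matrix; the
closed form equals the brute-force equilibrium solution to 10⁻¹⁰.
δ_i is the combined CSP in ppm by default (proton-only fitting is a
switch). [P_t] is taken exactly as supplied — no monomer/dimer
conversion is guessed. Amides with endpoint CSP below 0.05 ppm are not
fitted (they carry no K_d information); the reported K_d is the mean ±
sample SD over fitted amides, with a single-amide result annotated and
given its fit standard error instead.

A practical identifiability note: one four-point titration determines
K_d only to ~20–40% at 5% noise; the aggregate over ~6 amides at the
appropriate ligand range (125–1000 µM for K_d near 70 µM, 250–2000 µM
for weak, several-hundred-µM binders) brings the median recovery error
under 15%, which is the regime the reported mean ± SD convention
reflects.

## Structure handling

N–H vectors use the explicit amide proton when present; otherwise H is
placed in the peptide plane opposite the bisector of the C(i−1)→N and
CA→N directions at 1.02 Å. Prolines, chain starts and residues with
missing backbone atoms are skipped and reported, never fabricated.
Altlocs resolve to the highest-occupancy conformer. Residue ids are
chain-qualified with the source file's numbering; any NMR↔PDB
numbering offset must be supplied explicitly.

`align_c2` superposes chain A onto chain B over shared backbone atoms
(Kabsch), takes the rotation axis of that transform as the symmetry
axis, and rotates the assembly about a least-squares point on the axis
so the axis becomes +z (canonical +z hemisphere). It refuses when the
superposition angle deviates from 180° by more than 15° (overridable)
and reports the backbone RMSD and angle. The transform is a rigid
isometry (pairwise distances preserved to 10⁻⁹ Å).

Value maps write per-residue scalars into the PDB B-factor column,
min–max scaled to [0, 99.99] (two-decimal fixed columns); the exact
mapping and the raw values go to a sidecar TSV so nothing is lost.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) and always emit a
truth manifest. The default conditions mirror the target experiments:
two fields at 700/950 MHz; a 60-residue C2 dimer with planted tensor
(1.2, 1.4, 1.9)×10⁷ s⁻¹, γ = 35° (τ_c ≈ 10.9 ns, anisotropy ≈ 1.6);
S² drawn as a folded-protein mixture (75% core in [0.85, 0.98], 25%
loop-like in [0.5, 0.85]) with τ_int in [20, 200] ps and a third of
residues carrying R_ex in [2, 6] s⁻¹; 2% Gaussian noise on decay
intensities, with rate errors arising from the fit covariance exactly
as for measured data and NOE errors from synthetic SNR; four-point
titrations at 250 µM protein; screens of 600 compounds in mixtures of
10 at 500 µM each.

The generator reproduces the observables' statistics, not spectra: no
peak overlap, no differential line broadening from exchange, no
baseline or phase artefacts, no assignment errors, and N–H vectors for
the dynamics fixtures are random unit vectors rather than a real
fold's geometry (which conditions the tensor fit more favourably than
a helix-dominated topology would). Passing round-trip tests therefore
demonstrates correctness and calibration of the estimators under the
stated noise model, not robustness to spectral pathology.

## Numerical choices and degenerate inputs

- Decay fits refuse < 3 points or flat series; K_d fits refuse < 3
  nonzero-ligand points; singular K_d covariance flags the fit
  `poorly_determined`.
- NOE > 1.05 is flagged as artefactual; negative derived J beyond its
  error is flagged with the value retained; RC with non-positive
  low-field J(0) is undefined and flagged.
- The tensor optimiser works in log-rates, making positivity implicit;
  γ is wrapped after the fit.
- All Monte-Carlo procedures take explicit seeds; the package-level
  default seed is 20221116.

## Problem sizes used in validation

The acceptance computations use the 60-residue dimer (noiseless and 2%
noise with 200 MC refits), 150 exchange-free synthetic residues across
τ_c = 4–20 ns plus 24 exchange-carrying residues at the dimer τ_c for
the consistency test, 50 replicate titrations of 6 amides per K_d, and
1000 random tensor/vector pairs for the spectral-density identities.
These sizes give stable statistics (e.g., the MC coverage estimate has
a binomial SE of ~6 points at n = 60) while keeping a full validation
run to minutes on one CPU.
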