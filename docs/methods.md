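# Methods

`idpchar` implements the standard desk-side toolchain for deciding, from
orthogonal solution measurements, whether a protein region behaves as an
intrinsically disordered protein (IDP): what its sequence predicts, how
it migrates on a calibrated size-exclusion column, how it sediments, what
its far-UV CD spectrum contains, and what its small-angle X-ray
scattering (SAXS) curve and an ensemble fit of that curve say about its
conformational distribution. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not establish.

## Sequence diagnostics (`seqdis`)

**Charge–hydropathy classifier.** A sequence is placed at
(⟨H⟩, ⟨R⟩), where ⟨H⟩ is the mean over residues of window-averaged
Kyte–Doolittle hydropathy normalized to [0, 1] via (KD + 4.5)/9 (window
5, the convention of the original plot construction), and
⟨R⟩ = |#(K,R) − #(D,E)|/N at pH 7 (His neutral; pKa models are out of
scope). Points above the line ⟨R⟩ = 2.785⟨H⟩ − 1.151 are predicted
disordered; a configurable band ε = 0.005 around the line returns
"boundary". Because both coordinates depend only on composition, the
verdict is invariant under sequence shuffling — a property test checks
this.

**Foldability index.** Per-window FI = 2.785⟨H⟩_w − |⟨R⟩_w| − 1.151;
negative windows are predicted locally unfolded. Default window 51 in
the CLI (a common profile window); the function takes any window ≥ 1.

**Composition enrichment.** e_x = (f_sample − f_ref)/f_ref per residue,
with percentile confidence intervals from a multinomial bootstrap of
sequences of the sample's length (default n_boot = 1000; the seed is a
mandatory argument). When the sample lacks a residue the enrichment is
exactly −1; when the reference lacks one that the sample has, +inf is
returned with a warning rather than raising, since real reference tables
can have gaps. Reference compositions are editable config data; the
package ships a uniform reference and a documented disorder-biased
profile so no database download is needed.

**Residue classes.** Disorder-promoting {A,R,G,Q,S,E,K,P},
order-promoting {W,C,F,I,Y,V,L,N}, neutral {H,M,T,D}; config-overridable.

## Hydrodynamics (`hydro`)

**SEC calibration.** Kav = (Ve − V0)/(Vt − V0); standards' Stokes radii
come from the globular power law log₁₀(Rs[Å]) = −0.204 + 0.357·log₁₀(MM)
with **MM in daltons** — the law reproduces the five reference-protein
radii (64.8, 48.8, 44.0, 32.9, 24.5 Å) to the printed decimal only with
dalton input, which is why the unit is stated loudly. Calibration fits
log₁₀(Rs) against Kav by least squares (≥ 3 standards), reports R² and
residual RMS, and warns on extrapolation beyond the calibrated Kav range.

**Conformational-state laws.** Each compaction state has a log-linear
Rs(MM) track (coefficients in config): native, molten globule (MG),
pre-molten globule (PMG) and GdmCl-unfolded tracks from the published
globular-protein compilations, plus PMG-like and coil-like IDP tracks.
For the IDP tracks the published scaling exponents (0.403, 0.493) are
kept and the intercepts anchored so that a 23.396 kDa chain predicts
33.6 Å (PMG-like) and 38.7 Å (coil-like) — the validated reference
predictions for a chain of that mass; the anchored intercepts fall
inside the published uncertainties of the original regressions.
Classification takes the nearest state in log-radius. A self-consistency
test confirms that a radius generated by any track classifies back to
that track over 5–500 kDa, and that the globular tracks are strictly
ordered N < MG < PMG < U throughout.

**Shape classifiers.** Rg/Rs bands: 0.778 ± 0.01 sphere, 0.875–0.987
oblate, 1.36–2.24 prolate, otherwise indeterminate (all config data).
The frictional-ratio classifier interpolates published anchor values
log-linearly in MM (globular 1.19→1.25, PMG-like IDP 1.75→2.05,
coil-like IDP 2.1→3.0 between 20 and 200 kDa) and separately exposes the
operational "elongated if f/f₀ > 1.8" flag.

**Svedberg relations.** `auc_derive` computes
f = MM(1 − v̄ρ)/(N_A·s), f₀ = 6πη(3MMv̄/4πN_A)^{1/3}, Rs = f/(6πη) in CGS
with explicit unit conversions (kDa→g/mol, Svedberg→s, cP→poise,
cm→Å). Buffer density, viscosity and partial specific volume are inputs:
computing them from buffer composition is a solved problem elsewhere and
out of scope here. An algebraic round-trip test recovers a chosen Rs to
1e-9, and with near-water buffer constants the published sedimentation
row (s = 1.39 S at 19 kDa apparent mass) lands at Rs ≈ 33 Å, f/f₀ ≈ 1.85
— an anchor, not an equality, because the study's buffer constants are
not printed.

## Circular dichroism (`cdspec`)

**MRE conversion.** MRE(λ) = θ_mdeg/(10·c·l·n_res) with molar protein
concentration, pathlength in cm and the residue count — equivalently the
mean-residue molar concentration. The formula is documented against the
common ×10 error from quoting pathlength in mm. The conversion is linear
and exactly invertible (tested to 1e-12).

**HT filtering.** Wavelengths whose detector high-tension voltage is at
or above the cutoff (default 750 V, strict "under") are dropped — at
high HT the sample absorbs nearly all light and the ellipticity is
noise. The filter never reorders or interpolates; an all-filtered
spectrum is an error.

**Double-wavelength classification.** Coil-like and PMG-like IDPs
occupy distinct regions of the ([θ]₂₀₀, [θ]₂₂₂) plane. The default
regions are rectangles approximating the published clusters (coil:
θ₂₀₀ ∈ [−21600, −16600], θ₂₂₂ ∈ [−2400, −1000]; PMG: θ₂₀₀ ∈
[−13200, −8800], θ₂₂₂ ∈ [−5900, −3300] deg·cm²·dmol⁻¹); the exact
published boundaries are not available in machine-readable form, so
these are data to be refined by the user, not constants. Points in
neither region but inside the hull of both are "between" with the
nearer group reported.

**Deconvolution.** Secondary-structure fractions are estimated as the
simplex-constrained least-squares mixture (weights ≥ 0, summing to 1) of
labelled reference spectra, aggregated by label. The solver is an exact
active-set method on the KKT system: solve the equality-constrained
problem on the current support, drop the most negative weight while any
is negative, then re-admit zeroed basis members whose reduced gradient
is negative. It is deterministic, recovers noiseless mixtures to
machine precision, and recovers 40/60 mixtures within 0.01 at 2% noise
(the test bound is 0.05). A synthetic Gaussian-band basis
(helix/strand/turns/coil shapes) ships for testing the machinery; it is
not a measured reference set, so absolute fraction estimates on real
spectra require a real basis supplied by the user.

## SAXS (`saxs`)

**Units.** s = 4π sin θ/λ in Å⁻¹ internally; nm⁻¹ input is converted
only when the unit flag says so — magnitudes are never guessed.

**Guinier analysis.** The window starts at the lowest s and is iterated
to the fixed point at which every included point satisfies s·Rg ≤ 1.3
(default cutoff; the window selection re-estimates Rg each step). Within
the window, ln I is fitted as a quadratic in s² and Rg = √(−3·slope)
taken from the linear coefficient — the slope at s → 0. The quadratic
term is identically zero for an ideal Guinier curve (the fit is then
exact) and absorbs the systematic curvature of chain-like scattering: a
straight-line fit over the same window underestimates a Debye curve's Rg
by ≈ 6%, the curvature-corrected fit by ≈ 0.2%. If the quadratic gives a
non-decaying limit slope the fit falls back to the straight line.

**Kratky flag.** On y = I·s²: a clear interior maximum followed by decay
⇒ globular; no interior maximum with a statistically flat top-third
slope ⇒ disordered (chain-like plateau); an interior maximum over an
elevated flat tail ⇒ partially structured; signal indistinguishable from
noise (⪆ 20% negative intensities, or a maximum within 3 tail standard
deviations) ⇒ indeterminate. The plateau test compares the fitted slope
of the top third of the s range to zero at 95% confidence.

**Indirect Fourier transform.** p(r) is represented on an n_r-point
histogram over [0, Dmax] with p(0) = p(Dmax) = 0 and non-negativity,
solving I(s) ≈ 4π∫p(r)·sin(sr)/(sr)·dr by NNLS on the σ-weighted system
augmented with a √α-scaled second-difference penalty. When α is not
given it is chosen as the strongest smoothing whose weighted misfit
stays within 10% of the best achievable over a log-spaced α grid — a
discrepancy-style rule. An L-curve corner search was tried and rejected:
under the non-negativity constraint the roughness seminorm is nearly
constant in α, the L-curve has no corner, and curvature-hunting returns
arbitrary values. Rg and I(0) come from the moments of p(r); inputs
whose fit explains less than half the weighted signal variance are
rejected as noise-dominated. The sphere oracle (closed-form
p(r) ∝ r²(1 − 3r/4R + r³/16R³)) is matched within 2% of peak and
Rg = √(3/5)·R within 1% on noiseless data.

**Dmax scan.** Because the maximal dimension is operator-chosen in
interactive tools, `dmax_scan` makes it reproducible: it runs the IFT
over a candidate grid and recommends the smallest Dmax whose fit quality
is within 10% of the best and whose p(r) tail does not rebound above 20%
of the peak.

**Flory scaling.** Rg = 2.54·N^0.522 Å predicts the coil dimension of a
disordered chain of N residues; at N = 218 this is 42.22 Å (at N = 217,
42.12 Å — both chain-length conventions are kept as fixtures because the
residue count of a tagged construct is ambiguous by one tag remnant).

## Ensemble optimization (`ensemble`)

**Chain model.** Conformers are Cα-only chains with fixed 3.8 Å virtual
bonds, pseudo-bond-angles uniform on [75°, 150°], pseudo-dihedrals
uniform on (−180°, 180°], and self-avoidance enforced by rejection at a
4.0 Å clash radius for residue pairs ≥ 3 apart (per-step retries with
whole-chain restarts; an unsatisfiable geometry raises with
diagnostics). This is a deliberately simple excluded-volume coil — not
a native-like dihedral library — and it is the swappable default. Its
measured Rg scaling exponent over N ∈ {50…400} is ≈ 0.57, inside the
ideal-chain-to-good-solvent bracket [0.5, 0.65], and a 218-residue pool
has mean Rg ≈ 36 Å.

**Scattering.** Per-conformer intensities use the Debye formula with
unit point scatterers, I(s) = Σᵢⱼ sinc(s·rᵢⱼ), so I(0) = N². No
residue form factors or hydration shell: adequate for s ⪅ 0.3 Å⁻¹
desk-scale validation, and a documented limitation for absolute-scale or
wide-angle work. The vectorized engine is verified against a naive
double-loop sum to 1e-10 relative.

**Genetic algorithm.** An individual is a multiset of `ensemble_size`
pool indices (repeats act as weights). Fitness is reduced
χ² = 1/(K−1)·Σ[(c·Ī_ens − I_exp)/σ]² with the analytic least-squares
scale c per evaluation; a missing σ column falls back to a √I surrogate
with a warning. Evolution: tournament selection (k = 2), uniform
crossover, per-slot mutation (rate 0.05), a random-immigrant fraction of
population/10 per generation for exploration, and elitism of 1 — so the
best χ² is non-increasing (asserted in tests). Defaults: population 100,
generations 200, ensemble size 20, pool 10000 (reducible; tests and the
worked examples use desk-scale pools of 300–500 conformers of 60
residues on 40-point grids, which keep the whole suite in tens of
seconds on one CPU). Everything is reproducible from explicit seeds.

**Reporting.** `rg_report` compares pool and selection Rg distributions
(Gaussian KDE on a shared grid), counts selection modes (interior maxima
with ≥ 5% prominence), reports the mean-Rg shift and each conformer's
percentage contribution.

## Synthetic data (`synthetic`)

Generators return (data, truth) pairs; recovery tests consume the truth
only in assertions. SAXS curves: Debye Gaussian-chain, homogeneous
sphere, or an ensemble average over a generated pool, on 200 log-spaced
points over 0.0025–0.441 Å⁻¹ (the package's reference measurement
range), with noise σ(s) = max(rel_floor·I, counting_scale·√I) — shaped
like beamline error bars, declared rather than fitted. CD: convex
mixtures of the synthetic basis with optional noise and an HT ramp below
a configurable wavelength to exercise the filter. SEC: elution volumes
from a log-linear Kav truth line (intercept 1.95, slope −0.75 — placing
the five reference standards at plausible mid-column volumes) with
optional Gaussian Ve noise. Sequences: i.i.d. draws from a stated
composition; the default disorder-biased profile is Q/S/P-rich and
W/F/Y/I/N-poor. A 217-residue "MetC-like" stand-in sequence is generated
this way and is labelled synthetic: it reproduces only the composition
character of the real construct, not its residues, so sequence-level
results on it demonstrate the machinery, not the biology.

**What the synthetic tests do not show.** Real scattering has buffer
subtraction residuals, interparticle effects and correlated errors; real
CD bases are measured, not Gaussian bands; real columns drift. Passing
recovery tests establishes correctness of the estimators under the
stated noise models, not instrument-grade accuracy.

## Pipeline (`pipeline`)

Stages run independently; a failed stage marks its modality unavailable
and the rest proceed. Aggregation is a declarative rule table (field,
value, conditions over findings): the defaults encode the standard
reasoning chain — chain-like Kratky plateau, charge-hydropathy verdict,
elevated f/f₀ or an IDP-track radius each support "disorder: yes"; the
nearest compaction state maps to the compaction class; Rg/Rs bands or
the elongation flag set the shape; and the mass-consistency check
encodes the two classic caveats (SEC mass overestimates for extended
chains are shape-confounded, not oligomer proof; AUC apparent-mass
underestimates are IDP-typical boundary spreading). Every verdict cites
the findings that triggered it; no verdict is emitted from missing
inputs; report JSON is byte-stable for identical inputs. Where several
modalities disagree the first matching rule wins in table order — users
who prefer a different precedence (e.g. CD over hydrodynamics for the
PMG-vs-coil call) reorder the table.

## Known limitations

- The coil generator's angle distribution is a declared simplification;
  EOM-class tools use residue-specific dihedral libraries.
- Unit point scatterers cap the useful s range of ensemble fits.
- The CD basis shipped is synthetic; quantitative fractions on real
  spectra need a measured reference set.
- The double-wavelength regions and state-law coefficients are config
  data with documented provenance, to be refined against the original
  compilations when those tables are at hand.
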