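# Methods

## The measurement and its model

A fluorescence titration follows the intrinsic (tryptophan-dominated)
emission of a protein as increasing amounts of a quenching ligand are added.
The package analyses one scalar intensity per titration point, taken at a
fixed analysis wavelength — conventionally the emission maximum of the
zero-quencher scan (`intensity_at_analysis_wavelength` does the
extraction). The wavelength is held fixed across the titration because the
emission maximum itself shifts on binding; letting the window move would
conflate the shift with quenching. Whether an instrument exports peak or
fixed-wavelength intensities varies by lab; this is a convention, and it is
configurable.

Intensities are relative, so every downstream quantity is built from ratios
(F_0/F, (F_0−F)/F) and all fits are invariant to rescaling the intensity
axis. Concentrations are mol/L and temperatures kelvin throughout the
computation layer; only the report layer rescales (K_sv ×10⁴, K_q ×10¹²,
ΔH and ΔG in kJ/mol).

## Inner-filter correction

An absorbing titrant attenuates both the excitation beam and the emitted
light. The standard first-order correction multiplies the observed
intensity by `10^((A_ex·d_ex + A_em·d_em)/2)`, the inverse of the mean
Beer–Lambert attenuation over the cuvette (path lengths default to 1 cm).
The exponent is positive by construction: a correction can only increase an
attenuated signal, and the round trip with the inverse attenuation is exact
to machine precision (tested at ≤1e−12 relative). When only the ligand's
molar absorptivities are known, per-point absorbances are computed as
A = ε·[Q]·d — the same expression the simulator uses to apply the effect,
which is what makes the correction exactly invertible in tests. Off-centre
beam geometries and scattering are out of scope.

## Stern–Volmer analysis

`fit_stern_volmer` regresses F_0/F on [Q] over the positive-quencher
points (at least three required). The default fit leaves the intercept
free as a diagnostic — an intercept far from 1 flags curvature or a bad
F_0 — with a flag to constrain it to the theoretical value 1. K_q = K_sv/τ_0
uses τ_0 = 10 ns (typical unquenched tryptophan-band lifetime for these
proteins), overridable.

Mechanism classification applies the diffusion-limit rule first: dynamic
(collisional) quenching cannot exceed ~2.0×10¹⁰ L mol⁻¹ s⁻¹, so apparent
K_q above the limit at every temperature ⇒ static, below at every
temperature ⇒ dynamic. Because the published rule is qualitative ("much
higher"), values within ±1% of the limit are indeterminate by the primary
rule; temperature trends then arbitrate (K_A falling with T supports
static — complexes destabilise on heating; K_sv rising with T supports
dynamic — faster diffusion). The primary verdict and the corroborating
trends are reported separately so a reader can see which rule decided.

## Binding constants with ligand depletion

For static quenching the quenched fraction reports complex formation:
`log₁₀((F_0−F)/F) = n·log₁₀K_A + n·log₁₀[Q]_free`, fit by OLS; the slope is
the site number n and K_A = 10^(intercept/n). The free-ligand concentration
subtracts what the protein has bound, `[Q]_free = [Q] − [P](F_0−F)/F_0`,
using the quenched fraction as the bound-fraction estimate. Logarithms are
decadic everywhere (the 2.303 factors in the van't Hoff form imply log₁₀).

Numerical choices: the zero-quencher point never enters (the left side is
undefined there); points with F ≥ F_0 or [Q]_free ≤ 0 are dropped with a
warning rather than aborting, since early points are often noise-dominated;
at least three usable points are required. K_A bands follow the usual
protein-drug convention: 10⁵–10⁷ L/mol strong, 10²–10⁴ weak-to-moderate,
the gap labelled intermediate; out-of-range values map to the nearest band
with a warning.

## Van't Hoff thermodynamics

`fit_vant_hoff` regresses log₁₀K_A on 1/T: ΔH = −c·R·slope,
ΔS = c·R·intercept with R = 8.314 J mol⁻¹ K⁻¹ and c = ln 10 by default. A
`paper_faithful` mode uses the rounded constant 2.303 common in the applied
literature; the difference (~1 part in 10⁴) is far below fit uncertainty.
ΔG = ΔH − T·ΔS at each input temperature, and the identity
−c·R·T·log₁₀K_A_pred(T) ≡ ΔH − T·ΔS holds algebraically for the fit's own
parameters (tested). Two temperatures give an exact line (r² = 1 by
construction); fewer raise an error.

The force rule table follows the conventional sign framework: ΔH<0, ΔS>0
electrostatic; ΔH>0, ΔS>0 hydrophobic; ΔH<0, ΔS<0 hydrogen bond/van der
Waals; ΔH>0, ΔS<0 has no favourable canonical assignment and is returned
as unclassified. Exact zeros are classified with the adjacent negative-ΔH
rule and flagged as boundary cases. Spontaneity and exothermicity use
strict inequalities (ΔG<0, ΔH<0).

A note on scales: for the lactoferrin–chlorogenic acid reference values
bundled in the tests, the binding constants reproduce the published ΔG
column only on the 10⁴ L/mol scale (−RT·ln(5.29×10⁴) = −26.22 kJ/mol,
matching −26.23), although the source table's column header reads ×10³.
The package treats the exponent as data-dependent; the tests and the
acceptance script use the internally consistent 10⁴ scale. Similarly the
source text's "ΔS = −85.79 kJ mol⁻¹" is inconsistent with its own ΔG
values; the tabulated +85.79 J mol⁻¹ K⁻¹ is used.

## Assay calculators

All eight calculators are ratio formulas (grafting efficiency 100·C/C₀,
DPPH, solubility, FE/FS, EAI/ESI, bioaccessibility) plus the linear
Folin–Ciocalteu calibration. Two conventions worth noting:

- The DPPH expression ships in two variants because the source formula's
  typesetting is ambiguous. The default is the blank-corrected Blois form
  `100·(A₀ − (A₂ − A₁))/A₀` (A₁ being the sample-without-radical blank);
  the `literal` variant `100·(A₀ − A₂ − A₁)/A₀` is selectable and the
  choice is recorded in the output.
- EAI takes its inputs in the units the formula is printed in (path length
  in metres, protein concentration in g/mL); no hidden conversion. ESI with
  no turbidity decay returns an infinite-stability sentinel rather than
  raising.

Percentages are not clamped to [0, 100] — negative scavenging or >100% foam
expansion are real signals — except the calibration inversion, which clamps
negative concentrations to zero with a warning.

## Synthetic data generator

`simulate_titration` emulates the reference study design: 10 μM protein,
ligand molar ratios (0, 1, 2, 3, 4, 5, 6, 8, 10) mapped as
[Q]_total = ratio × [P], temperatures 290/300/310 K. The forward model is
exactly the model family the analysis fits (the quenched fraction
θ = x^n/(1+x^n) with x = K_A·[Q]_free, so (F_0−F)/F = x^n), which makes a
zero-noise simulation an inverse crime by design: the pipeline must recover
the truth to numerical precision, and that is the intended oracle. The
free-ligand concentration is solved by a damped fixed-point iteration
(damping 0.5, tolerance 1e−12 relative, 200 iterations), validated in tests
against a 10⁶-point grid search.

Ground-truth K_A(T) comes from van't Hoff parameters; the defaults
ΔH = −1368 J/mol, ΔS = 85.72 J mol⁻¹ K⁻¹, n = 1.19 put K_A(290 K) at
5.29×10⁴ L/mol with the weakly decreasing K_A(T) of the static-quenching
regime. The inner-filter effect is applied from ligand molar absorptivities
(default 0 = off) with the same Beer–Lambert expression the correction
inverts. Noise is multiplicative Gaussian per reading (fluorescence noise
scales with signal), applied last; each reported point is the mean of
`replicates` readings, default 3, matching the triplicate measurement
protocol standard in these studies. Randomness is a single root seed
fanned out into one child stream per temperature, so outputs are
byte-reproducible and adding a temperature does not perturb the others.
An optional dilution-tracking mode books the volume of 500 μM ligand stock
added to a 4 mL cuvette (off by default, since published analyses rarely
correct for it).

What the generator does *not* emulate: spectral lineshapes (a single
Gaussian band exists only to exercise wavelength extraction), combined
static+dynamic quenching, instrument drift, or correlated noise between
points. Passing recovery tests therefore demonstrates the estimators are
correct for the assumed model, not that the model fits any particular
instrument's artefacts.

### Recovery performance and a known limitation

At the default study conditions with 1% reading noise, 100 seeded studies
give median K_A error ≈ 0.9% and median n error ≈ 0.7% (tested bounds: 5%
and 3%), and estimator error grows monotonically with the noise level. The
*sign* of ΔH is a much harder target at these conditions: the reference
system's enthalpy (≈ −1.37 kJ/mol) moves K_A by only ~3.6% from 290 to
310 K, comparable to the K_A estimation noise, so the fitted ΔH sign is
recovered in only ~93% of replicate studies (measured over 1000 seeds).
This is a property of the experimental design, not of the estimator: a
near-athermal binding equilibrium cannot yield a reliably signed enthalpy
from three temperatures spanning 20 K at percent-level intensity noise.
The corresponding recovery test asserts a 95% success criterion and is
expected to fail at these conditions; it is kept as an honest record of
that sensitivity limit.

## Problem sizes

All fits are closed-form least squares on ≤ 27 points; the recovery studies
use 100–400 simulated titrations. The entire test suite and the acceptance
script each run in a few seconds on one CPU.
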