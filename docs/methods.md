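# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic world does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Radionuclide model

¹⁸⁶Re: half-life 89.28 h (3.72 d), beta emission with endpoint 1.07 MeV,
137 keV gamma line with 9 % abundance.  The default beta spectrum is a
single-branch allowed-transition Fermi shape, p(E) ∝ p·W·(E₀−E)², without
Coulomb (Fermi-function) correction; its mean is 0.427 MeV.  The physical
nuclide has several branches and a lower mean beta energy (≈0.35 MeV), so
users wanting branch-accurate energetics should supply a tabulated
spectrum (`BetaSpectrum.from_csv`, two columns: energy_MeV, probability
density; or discrete lines).  All internal conservation checks are
against the configured spectrum, so this choice affects absolute dose
scale but not self-consistency.

## Voxel S-value kernel

Per decay the Monte-Carlo samples a beta energy (inverse CDF), an
isotropic direction and a uniform position in the source voxel, then
deposits energy continuously along a *straight* track of length equal to
the CSDA range of the start energy, splitting the track into 32 equal
path segments whose energy losses follow the range–energy relation.
Multiple scattering and bremsstrahlung are omitted; photons are treated
as escaping (their 9 %·137 keV is small and mostly non-local at voxel
scale).  This cannot reproduce a condensed-history code bit for bit —
correctness is defined by:

- energy conservation: ΣK × voxel mass = spectrum mean energy (observed
  agreement ≈3×10⁻⁵ at 10⁶ histories);
- full local absorption of short-range electrons (10 keV: ≥99.9 % in the
  source voxel, self-dose matching the closed form);
- centrosymmetry within MC noise.  The symmetry check is restricted to
  offsets receiving ≥1 % of the self-dose: outer voxels hold pure MC
  noise, where a relative comparison fails at any history count.

The bundled range–energy table is an approximate CSDA curve for liquid
water, 10 keV–1.2 MeV, log-log interpolated and power-law extrapolated
below 10 keV; ranges scale with 1/ρ and the default medium density is
1.04 g/ml ("soft tissue").  Default grid: half-width = ⌈R(E₀)/voxel⌉+1
(7³ voxels at 4.67 mm — the 1.07 MeV CSDA range is only ≈4.6 mm).
Kernels are saved as NIfTI + JSON metadata (seed, histories, density,
escaped-energy fraction) for provenance.

## Synthetic world

The generator's defaults are the stated acquisition conditions: 4.67-mm
isotropic grid, scans at 1/4/24/48/72 h, energy windows 20 % at 137 keV
and 7 % at 119 keV, 11 cylinders (1×1 … 5×10 cm, 0.8–196 ml) at
2.20 MBq/ml, probe retention with Poisson CV ≤ 6 % and a first reading at
t = 0, and ~70 % urinary excretion by 24 h (biological whole-body
retention 0.30 at 24 h, enforced to 10⁻⁶ by solving the fast fraction of
a 3 h/250 h bi-exponential).

Values the protocol does not state were fixed once, before any testing,
at field-plausible levels: PSF FWHM 12 mm and sensitivity 10 cps/MBq for
a low-energy high-resolution collimator at 137 keV; scatter fraction 0.3;
acquisition 64 × 20 s.  The forward model works in reconstructed-image
space: primary = Gaussian-blurred (activity·S·t·decay), scatter = 0.3 ×
a 1.5×FWHM blur of the same counts added to the peak window and placed,
scaled by the window-width ratio, in the sub window — so the DEW
estimator removes in expectation exactly what was added.  Optional
uniform elliptical attenuation multiplies voxels by the same
angle-averaged transmission the Chang correction divides by, making the
pair exactly inverse by construction (a modelling convenience, not a
physics claim).  Poisson noise is per voxel; every stochastic call takes
an explicit seed and identical seeds give bitwise-identical output.

Cylinders are rasterised separably — exact axial overlap × 16² in-plane
sub-pixel sampling — giving <0.7 % volume error even for the 0.8 ml
object; cruder cubic sub-sampling produced up to 24 % error there, which
would have dominated every downstream volume check.

**Cohort generator.** Disease volume is log-normal (median 227 ml,
σ_ln = 0.7); baseline ALP is log-normal and correlated with ln(volume)
at r = 0.65; PSA log-normal and independent.  Doses are produced by the
analytic forward dose model, not drawn directly: 24-h retention rises
with ln(volume) (slope 0.09 — calibrated so the emergent dose–volume
correlations land near the reported clinical strength, r ≈ 0.6–0.7),
the whole-body dose follows from the residence time and patient mass,
and the lesion-dose scale follows from the skeletally bound fraction
spread over an 1800-ml active skeletal pool (chosen once so the mean
patient mean absorbed dose is ≈19 Gy at 5 GBq).  Survival is exponential
with log-hazard linear in ln(volume) (default 0.9 per ln-ml, baseline
ln 2/18.5 months⁻¹), plus optional censoring: random "subsequent therapy"
censoring and administrative censoring at 60 months.  The closed form for
the above/below-median-volume hazard ratio implied by this model,
Φ(βσ)/Φ(−βσ), is exposed as `CohortModel.implied_median_split_hr()` and
is the oracle for generator-calibration tests.

What the synthetic world does **not** emulate: projection-domain physics
and FBP streaks, depth-dependent or anisotropic resolution, collimator
septal penetration, non-uniform attenuation/scatter media, patient
motion/registration error, marrow or bone-matrix dosimetry, and
non-proportional hazards.  A green end-to-end test therefore establishes
the *chain's* correctness under the stated forward model, not clinical
accuracy on real scanners.

## Quantification decisions

- DEW multiplier k = 1.0 with width scaling w_peak/w_sub =
  (0.20·137)/(0.07·119) ≈ 3.289; only the windows are stated in the
  protocol, so k is configurable.
- Chang correction: first-order, image-domain, per-slice elliptical
  outline, 64 angles by default; out-of-outline voxels are zeroed.
- Recovery curve: for each phantom the relative volume error |V(T)−V|/V
  is scanned over T ∈ {0.01…0.99}; the curve values are chosen by a
  dynamic program minimising the summed relative error under the
  constraint that thresholds are non-increasing with volume (ties toward
  larger T to resist background bleed).  This replaces per-object argmin
  + isotonic smoothing, which is strictly worse when object shape makes
  raw optima non-monotone.  With the default world the DP lands on
  ≈0.99/0.62/0.56 for the sub-10-ml objects and a flat 0.40 above 20 ml —
  the same structure the physical phantom experiment reports (71/58/40 %).
- Shape limitation (important): at ≈12 mm isotropic FWHM the compact
  3×3 cm cylinder (21 ml) only tolerates thresholds ≈0.34–0.39 while the
  elongated 2×10 cm cylinder (31 ml) needs ≈0.47–0.50.  A volume-only
  monotone curve cannot serve both; the best achievable round-trip error
  is ≈15 % for the 3×3 cm object (others ≤7 %).  This is a genuine
  property of threshold segmentation under isotropic blur, not an
  implementation artifact.
- Segmentation: 26-connected components above a seed threshold
  (10 % of image max), refined by fixed-point iteration of
  threshold(volume)×component-max within the seed component.  The raw
  iteration is unstable for small objects (volume shrinks → threshold
  rises → volume shrinks …), so the volume fed to the threshold lookup is
  damped geometrically; lesions below 0.5 ml are discarded as noise.
- Lesion outlining operates on the dose map by default (activity maps are
  equally supported) and volumes are voxel counts × voxel volume.

## Kinetics decisions

- Falling TAC segments use the exactly determined two-point exponential
  (A_i−A_{i+1})Δt/ln(A_i/A_{i+1}); segments rising, equal, or touching
  zero use the trapezoid (the exponential's limit or degenerate case).
- The tail after the last scan decays with the *physical* half-life only,
  deliberately ignoring voxel-level biological redistribution.
- Retention fits use raw (not decay-corrected) count rates normalised to
  t = 0, so λ_eff includes physical decay; τ = 1/λ_eff.  For strongly
  bi-phasic retention a mono-exponential overestimates τ (by ≈45 % in the
  default synthetic world, visible as WBD ≈0.75 Gy where the analytic
  residence time gives ≈0.42 Gy); the fit report records the conventions
  and r².  Whole-body dose absorbs electrons fully and ignores photons by
  default (configurable photon absorbed fraction).
- Sequential scans are assumed rigidly co-registered.

## Statistics decisions

- Efron handling of tied event times (lifelines' default; less biased
  than Breslow).
- Median dichotomisation sends values equal to the cut to "below" —
  deterministic tie handling.
- 95 % confidence intervals and two-sided p-values throughout; Fisher-z
  interval for correlations; Wald intervals for hazard ratios.
- Normality dispatch for baseline comparisons uses Shapiro–Wilk at
  α = 0.05 per group (overridable), falling back to Mann–Whitney.
- Months = days/30.4375 where synthetic day counts need converting.

## Known limitations

- Straight-track CSDA transport slightly over-concentrates dose along the
  initial direction compared to scattered transport; at 4.67-mm voxels
  (range ≈ 1 voxel) the effect on kernels is small but unquantified here.
- The recovery curve is volume-only; shape-dependent recovery is out of
  reach by construction (see above).
- The mono-exponential whole-body fit biases τ upward for bi-phasic
  retention; a bi-exponential fit would remove this but is not the
  documented convention of this pipeline.
- The cohort generator's dose model is analytic and patient-level; it
  shares no code path with the image-based per-patient chain, so
  cohort-level statistics exercise the statistics stage, not imaging.
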