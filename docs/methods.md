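# Methods

## Scope and assumptions

The package analyses *pre-registered* static, reference-scaled uptake
images: every volume (cohort images and the label atlas) must live on one
common grid. Registration, reconstruction and PET physics (attenuation,
scatter, partial volume, decay) are out of scope; the phantom generates
images that are already co-registered by construction.

## Phantom data-generating model

The phantom emulates a cross-sectional transgenic (TG) vs wild-type (WT)
amyloid-mouse design with equal groups at four ages (defaults 5, 8, 13,
16 months, n = 8, two tracers).

**Grid and atlas.** Default grid 36 × 50 × 30 voxels at 0.4 mm isotropic —
finer than a typical small-animal PET reconstruction (~0.8 mm) so that
voxel-wise statistics have non-trivial spatial support. The atlas is
parametric: axis-aligned region boxes (frontal, parietal and
piriform/entorhinal cortex, hippocampus, thalamus, cerebellum, brainstem,
two white-matter reference blocks) inside a superellipsoid brain envelope
(12 × 18 × 10 mm, ~27.8 k brain voxels), the remainder labelled
`other_brain`. Box sizes are chosen so that the realized VOI volumes are
28.7 / 66.9 / 156.0 mm³ for the TSPO reference, amyloid reference and
forebrain target (within ~1% of the 29 / 67 / 156 mm³ configured targets);
`build_atlas` raises a sizing error naming the offending region on grids
too small or too coarse.

**Amyloid burden.** Per region `r`, truncated logistic growth from a
region-specific onset:
`B_A(r, a) = amp_r · max(0, tanh(g_A (a − onset_r)))`,
exactly zero at or before onset, zero in WT, zero in the reference VOIs and
in cerebellum/brainstem. Defaults: onsets 6 (frontal), 6.5 (thalamus),
9.5 (parietal), 11 (hippocampus), 12 (piriform/entorhinal), 12.5
(other brain) months; amplitudes 1.0 / 0.85 / 0.9 / 0.8 / 0.7 / 0.15;
rate `g_A = 0.25 / month`. Frontal cortex and thalamus lead, consistent
with a focal-onset, late-spreading amyloidosis.

**Inflammation burden.** Sum of three parts, zeroed in the reference VOIs:
a linear aging drift `0.013 · a` shared by both genotypes; in TG, a diffuse
component `s_I(a) · D(v)` where `D` is a Gaussian-blurred (2 mm FWHM,
max-normalized) indicator of the cortical/hippocampal/thalamic/cerebellar
regions and `s_I(a) = max(0, tanh(0.15 (a − 2)))` rises from 2 months; and a
plaque-associated component `0.25 · B_A(v, a)` proportional to the
subject's own local amyloid burden. With these defaults the
threshold-crossing age for inflammation precedes that for amyloid in every
cortical region — inflammation is widespread early, amyloid focal and
delayed, converging late, which is the progression the analysis is designed
to detect.

**Images.** `uptake = 1 + k · burden + ε` with `k = 0.25` (TSPO) / `0.35`
(amyloid) and white Gaussian voxel noise `σ = 0.04`. Reference regions are
pathology-free, so the expected reference mean is exactly 1 and SUVR equals
`1 + k · burden(target)` in expectation. The spatial correlation length of
real μPET noise is unknown; the default is white noise, and
`smooth_volume` (optional pre-statistics Gaussian smoothing, off by
default) is the knob for exploring correlated-noise behaviour.

**Between-animal variability.** Each subject carries two independent
lognormal severity factors (mean 1): CV 0.08 for inflammation and CV 0.25
for amyloid — amyloid load varies much more between animals than the
inflammatory response, which is what makes the amyloid-PET
standardized-difference curve sit below the TSPO curve despite a larger
mean effect. Severity factors multiply the TG pathology burden only.

**Biomarkers.** For biomarker `m` with driver burden `B` (the subject's
noiseless forebrain-mean inflammation burden for sTREM2 and cytokines,
amyloid burden for total Aβ):
`log Y_m = log(base_m) + slope_m · B + σ_m ε − σ_m²/2`,
`σ_m = sqrt(log(1 + CV_m²))`. Defaults: sTREM2 base 800, slope 1.3,
CV 0.05; total Aβ base 40, slope 1.3, CV 0.15; cytokines (IL-1β, IL-6,
KC/GRO) slopes 0.6–0.7, CV 0.25. The log-linear form keeps concentrations
positive, makes the noise-free map strictly monotone in burden, and gives
an analytically known burden–log-biomarker correlation
`ρ = slope·s_B / sqrt(slope²s_B² + σ²)` (exposed as
`implied_log_correlation`), which is the recovery target of the
parameter-recovery tests.

**Randomness.** Every subject owns an independent `SeedSequence` substream
keyed on (master seed, genotype, age, replicate index), so cohorts are
bit-reproducible and insensitive to iteration order; image noise, severity
factors and biomarker noise draw from separate child streams.

## Statistical procedures

* **Voxel-wise contrast**: pooled-variance two-sample Student *t*
  (TG − WT), equal group sizes enforced, `df = n₁ + n₂ − 2`, one-sided p
  for elevation (the binarized maps encode "significantly *elevated*");
  a two-sided Welch variant is deliberately not offered, matching the
  mapping convention the design targets. Voxels with zero pooled variance
  get `t = 0, p = 1` and are counted in `n_degenerate`.
* **FDR**: Benjamini–Hochberg step-up over brain-mask voxels only, with
  standard tie handling (everything at or below the critical p is
  rejected). The rejection set is converted to the smallest rejected
  T-score, which becomes the binarization threshold (+∞ when empty). No
  cluster-extent or random-field correction.
* **Dice on non-binarized T-maps**: fuzzy (min-based) Dice on the positive
  parts of the two T-fields,
  `2 Σ min(a⁺, b⁺) / (Σ a⁺ + Σ b⁺)`. Chosen because it reduces exactly to
  binary Dice on 0/1 fields and weights agreement by regional magnitude;
  the definition is isolated in one function so a level-set alternative
  can be swapped in. Both Dice variants return 0 (logged) when both inputs
  are empty.
* **%-occupancy** uses the atlas brain-mask voxel count as the whole-brain
  denominator. Transition flows are per tracer (persisting / new /
  disappeared as % of brain volume, conserving occupancy exactly); the
  full 4 × 4 category transition matrix is also emitted.
* **Normality**: Lilliefors-style KS (parameters estimated from the
  sample), since no reference distribution is available. This may be more
  conservative than a textbook KS against fixed parameters.
* **Regression**: OLS on z-scored (n − 1 SD) outcome and predictors, so β
  is dimensionless and β² = R² for a single predictor. The two tracers
  enter separate age-adjusted models by default (each tracer + age on
  sTREM2), with simultaneous entry available through the library call.
* **Standardized differences**: `d(a) = (mean_TG(a) − WT_line(a)) / SD_TG(a)`
  where `WT_line` is the straight line through two WT (age, mean) anchors,
  linearly *extrapolated* when a TG age falls outside them (the plain
  reading of linear WT aging). The pipeline uses the youngest and oldest WT
  groups as anchors. For the total-Aβ assay the two youngest TG groups
  share a pooled SD (`pooled_sd`, n − 1 weighting): a pre-onset group's
  degenerately small SD would otherwise explode its standardized
  difference.
* **Group-size planning**: smallest per-group n whose two-sided two-sample
  t-test power (exact noncentral-t) reaches the request; the negligible
  lower-tail term is dropped when the noncentrality is so large that the
  CDF underflows.

## Calibration and what the tests show

Default calibration targets the qualitative progression pattern only —
TSPO-elevated occupancy ≈ 11% of the brain at 5 months with no
FDR-surviving amyloid voxels, strictly increasing both-elevated occupancy
and continuous Dice across the four ages, and TSPO/sTREM2
standardized-difference curves at or above the amyloid-PET curve in mean
level (curve-level rather than pointwise comparison: single-group SD
estimates at n = 8 are too noisy for pointwise dominance to be a stable
property of the data-generating process). No attempt is made to force any
particular printed percentage.

The phantom omits many properties of real μPET data: spatially correlated
and intensity-dependent noise, partial-volume effects at region borders,
registration error, attenuation/scatter residuals, anatomical variability
(one fixed atlas for all subjects), and biomarker–pathology couplings that
are more complex than log-linear. Passing tests therefore demonstrate the
correctness and calibration behaviour of the *analysis*, not scanner-level
realism of the simulation.

Problem sizes used by the test suite and acceptance script: full default
cohorts (128 images of 54 k voxels, ~27.8 k brain voxels) for the
end-to-end checks; 200 null cohorts (single age, one tracer) for FDR
control; 200 biomarker-only replicates at n = 25 for coupling recovery;
500 OLS replicates at n = 25 for β recovery; brute-force oracles on
10³–10⁴-voxel instances.

## Known limitations

* The atlas is geometric (boxes in a superellipsoid); there are no
  ventricles, no bilateral symmetry, and region volumes quantize with the
  grid, so very coarse grids fail atlas construction by design.
* The one-sided elevation contrast cannot detect signal *decreases*;
  use the library's two-sided option for that.
* `fdr_binarize` controls FDR over whatever mask it is given; feeding it
  maps restricted post hoc to a subregion changes the error rate being
  controlled.
* WT linear-aging interpolation is exactly linear by construction in the
  phantom; on real data the extrapolation below the youngest WT anchor is
  an assumption, not a fact.
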