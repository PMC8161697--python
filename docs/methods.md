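# Methods

This note documents the models, conventions, defaults and numerical choices
behind `enfaceoct`, and what the synthetic-data tests do and do not
establish.

## Depth convention

All depths are µm below the ILM on a 3.87 µm axial grid. Slab *k* spans
[3.87k, 3.87(k+1)) and its **reported depth is the anterior edge 3.87k**.
This single convention is used by the generator, the extractor and all
statistics. Consequences worth knowing: with a uniform bundle extent of
100 µm, the deepest slab still inside the bundles is slab 25 (96.75 µm) and
the first slab fully beyond them is slab 26 (100.62 µm); a sector with no
bundles at all reports a first gap of 0 µm.

## Attenuation coefficients

Per A-scan, μ_i = I_i / (2 Δ Σ_{j>i} I_j) with Δ in mm. The estimate is
invariant to overall signal scaling (it is a ratio) and needs no calibrated
intensities. Samples whose below-tail sum is ≤ `tail_epsilon` (default
1e-12) — always the deepest sample, and every sample of an all-zero
A-scan — are set to 0 and flagged in a validity mask rather than raising.
The estimate is biased upward where the recorded tail is short (the
truncated geometric tail under-estimates the true integral), which matters
only within ~2/μ of the bottom of the volume.

## Normalization

Background *b* is the mean of a caller-chosen bundle-free raphe ROI in the
slab containing 35 µm (slab 9 = ⌊35/3.87⌋). After subtracting *b* and
clipping at zero, the stack is divided by the mean over the 50 slabs of each
slab's 99th percentile, computed **after** subtraction, and values above 1
are clipped. Percentiles are linear-interpolation (type-7) quantiles —
stated because percentile dialects differ. The normalizer is computed on
the stack the function is given (post-montage if montaging was used).
A zero normalizer (constant stack) raises.

## Sector geometry

Sectors (TMP 90°, TS 40°, NS 40°, NAS 110°, NI 40°, TI 40°) tile the circle
with half-open intervals `[start, end)` to break boundary ties
deterministically; TMP is centered on the fovea–disc axis. Grid angles
increase clockwise on screen for right eyes and anticlockwise for left eyes,
which makes the sector order temporal → superior → nasal → inferior for both
lateralities; in the anatomically standard display of a right eye (fovea to
the image left of the disc) this puts superior at the top of the image.
The circle radius is fixed at 1750 µm; physical-to-pixel conversion comes
from the stack's transverse scale, and ONH-center and fovea coordinates are
caller-supplied (no automatic detection). Circle sampling is bilinear
(`scipy.ndimage.map_coordinates`, order 1), 720 angles by default.

## Objective grading

The reflectance threshold is `median + k·MAD` of the pooled five deepest
slabs (174–193.5 µm), which lie beyond the nerve fiber layer everywhere and
so form a bundle-free reference; vessels contaminate only a small angular
fraction of that pool. `threshold_k` defaults to 4.0: the threshold must sit
several noise-sigmas above background yet below the partial-volume blur zone
at striation edges. The default was chosen by measuring truth recovery on
randomized synthetic eyes across k before freezing (k = 4 keeps noiseless
recovery exact and ≥90% of sectors within ±2 slabs at noise SD 0.1; smaller
and larger k both fail that design requirement). The MAD is floored at 1e-6
so a noiseless profile does not place the threshold exactly at the
background level, where interpolation round-off would flip bits.

Angles bright in ≥90% of slabs are flagged as vessels (only vessels stay
hyperreflective at every depth); an explicit vessel mask can be supplied
instead. Vessel angles carry no bundle evidence: they are **removed** before
run analysis, so a gap continues across a vessel, and run lengths are
remaining-sample count × angular step (the vessel's width is not counted).
Bundle runs shorter than `min_run_deg` (default 1°) are erased by a
wrap-aware angular opening.

First gap scans slabs from the ILM downward for a bundle-free run
≥ `gap_min_deg` (default 3°, chosen to exceed the ~1° striation gaps of
healthy bundle texture); total absence of bundles qualifies, so 0 µm is a
legal value. A gap is *not* required to be bounded by bundles on both sides
at the same depth — the 0 µm case makes the bounded reading untenable. If no
slab down to 193.5 µm qualifies, the result is censored at 193.5 µm and
flagged, never silently numeric. Last visible scans upward for a bundle run
≥ `bundle_min_deg` (default 1° ≈ one striation). The reported angle is the
qualifying run's midpoint. Weighted averages are Σ value·width / 360 and
propagate invalidity: a censored sector invalidates the average.

## Synthetic eyes

The generator emulates the *phenomenology* of peripapillary enface OCT, not
its physics: bundles are angular striations (period 2°, duty 0.5) at
reflectance 0.85 over a 0.10 background, visible in slab *k* wherever the
depth-extent profile satisfies T(θ) > 3.87k; vessels (default four, 3°
wide, near the superior/inferior arcades) are bright at every depth;
additive Gaussian noise is clipped to [0, 1]. T(θ) interpolates per-sector
anchors with a shape-preserving periodic PCHIP — monotone between anchors,
because real bundle extent has no ringing notches between sectors; focal
loss is modelled explicitly by raised-cosine wedge defects (taper avoids
knife-edge artifacts). Anchor defaults are **illustrative**: no published
per-sector norms exist, so they are loosely calibrated to one worked healthy
temporal sector (first gap 58 µm, last visible 108 µm) with ISNT-like
superior/inferior dominance. Default canvas: 512×512 px at 10 µm/px, ONH
center mid-image — arbitrary but fixed, overridable.

True indices are derived from T, the striation mask and the vessel mask by
dense angular enumeration (0.05° steps) of exactly the run rules above, so
truth and extractor share conventions but not code paths. What a green
truth-recovery test establishes: the image pipeline (render → bilinear
circle sampling → threshold → runs) reproduces the analytic rules within one
slab. What it does not establish: robustness to real OCT speckle, shadowing,
segmentation error, or reflectance loss without extent loss.

## Synthetic cohorts

Index-level tables follow the variance-components model
`y = mean[sector] − offset·[glaucoma] + u_eye + v_sector + ε` with
u ~ N(0, 10²), v ~ N(0, 5²) (drawn once per cohort — crossed, matching the
mixed model's ONH-sector random effect), ε ~ N(0, 8²), clipped to
[0, 193.5] µm. Default offsets are the reported group differences (39.1 µm
first gap, 48.1 µm last visible). Thickness is intercept + slope·depth +
noise (defaults 30 µm + 0.5·depth); when a per-group target correlation is
set (defaults 0.92 healthy / 0.80 glaucoma) the noise SD is derived from
r = βσ_x / √(β²σ_x² + σ_ε²), where σ_x² is the within-eye depth variance —
the per-sector mean spread **plus** the sector and residual components,
since within-subject demeaning shrinks signal and noise by the same factor.
Mean deviation is group-Gaussian (+0.6 ± 1.1 / −4.5 ± 3.1 dB) solely to
exercise the MD ≥ −4 dB early-glaucoma filter.

## Statistics

* **Mixed model**: `y ~ disease` with crossed random intercepts for eye and
  sector via statsmodels MixedLM variance components; both the full and the
  no-disease model are fitted by ML (they differ in fixed effects), the LRT
  has df 1, and the fixed effect carries a Wald 95% CI. The effect is
  reported as control − glaucoma (positive = shallower in glaucoma).
  Singular or failed fits return a flagged result, falling back to the
  group-mean difference. Calibration (checked in the acceptance suite):
  estimate bias < 5%, CI coverage 92–98%, LRT type-I error 3–7%.
* **Post-hocs**: Welch t (the fractional dfs reported with such analyses
  imply unequal-variance tests) per sector plus the weighted average, both
  indices → family of 14, threshold 0.05/14 ≈ 0.0036.
* **pAUC**: empirical ROC with ties moving diagonally; trapezoid area over
  FPR ∈ [0, 0.10] with linear interpolation at the boundary; standardized
  by the McClish map 0.5·(1 + (raw − 0.005)/0.095) so 0.5 is chance and 1
  is perfect. Bootstrap CIs resample within class (percentile 2.5/97.5),
  seeded. Low scores indicate disease for every measure here
  (`direction="lower"`).
* **Paired comparisons**: classical DeLong theory covers the full AUC, so
  `method="delong"` tests full AUCs; the default `method="bootstrap"`
  resamples subjects and tests the standardized-pAUC difference — the two
  are both provided because how to apply "the DeLong method" to a partial
  area is genuinely underdetermined.
* **rmcorr**: common-slope ANCOVA with subject intercepts;
  r = sign(slope)·√(SS_x/(SS_x+SS_err)), identical to the Pearson
  correlation of within-subject-demeaned data; df = N − subjects − 1; p from
  F(1, df); CI by Fisher transform with SE 1/√(df−1) (analytic, not
  bootstrap — the choice is exposed by the result object).
* **Power**: minimum detectable r solves the bias-corrected Fisher-z
  equation √(n−3)·(atanh r + r/(2(n−1))) = z_{1−α/2} + z_{power} by brentq
  on (0, 1); this variant reproduces the published 0.48 (n=40) and 0.65
  (n=20) at 90% power, which is why it was adopted.

## Tolerances and test design

Oracle-equivalence suites (attenuation vs brute-force tail sums, trapezoid
pAUC vs threshold sweep, DeLong vs Mann–Whitney, rmcorr vs demeaned
Pearson) assert to 1e-10…1e-12; the pAUC sweep oracle uses a dense FPR grid
and is compared at 2e-4. The degenerate zero-variance mixed-model case is
asserted at 1e-4 — the ML optimizer's tolerance, not the model's. The
bootstrap-coverage study uses binormal scores (separation 1.8, 200 per
class, B = 400): percentile bootstrap CIs for pAUC are known to undercover
at small n, and 200/class is the regime where the nominal 95% level is
attained. The 50-eye recovery test compares depths within ±1 slab and
requires the reported first-gap angle to point into a true gap (run
midpoints are not compared directly: when several runs qualify at one slab,
truth and extractor may legitimately pick different ones).

## Known limitations

* The grader surrogate is deterministic; it does not model human grading
  variability, and its thresholds assume a normalized stack whose deepest
  slabs are bundle-free (an eye with bundles persisting past ~174 µm would
  contaminate the reference pool and, at full depth, be mistaken for
  vessel).
* Montaging takes integer pixel offsets as given; registration is out of
  scope.
* Beam-incidence-angle correction is deliberately absent.
* The synthetic MD is a labelling device, not a visual-field model.
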