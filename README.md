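# enfaceoct

Peripapillary **enface OCT reflectance analysis** for glaucoma research.

In enface OCT, thin transverse slabs below the inner limiting membrane (ILM)
show retinal nerve fiber bundles (RNFBs) as hyperreflective striations
radiating from the optic nerve head (ONH). Glaucoma thins the nerve fiber
layer and dims bundle reflectivity, so bundles disappear from the slabs at
shallower depths. This package implements, as a tested and reusable
pipeline, a simple grading of that phenomenon on the standard 3.5 mm
peripapillary circle, together with the statistics needed to evaluate it as
a diagnostic index — and a synthetic-eye generator with known ground truth
so the whole pipeline is testable without patient data.

## What it computes

**Enface stack construction** (`enfaceoct.enface`). From an ILM-flattened
intensity volume, per-A-scan depth-resolved attenuation coefficients

    μ_i = I_i / (2 Δ Σ_{j>i} I_j)        [mm⁻¹, Δ = axial step in mm]

are sliced into 50 single-sample slabs on a 3.87 µm grid (0–193.5 µm below
the ILM; slab *k* spans [3.87k, 3.87(k+1)) µm and is reported at its
anterior edge 3.87k). Overlapping scans are montaged by the maximum rule;
the stack is normalized to [0, 1] by subtracting a bundle-free raphe
background (35 µm slab) and dividing by the mean per-slab 99th percentile.

**Sector geometry** (`enfaceoct.geometry`). A six-sector grid — temporal
90°, temporal/nasal superior 40° each, nasal 110°, nasal/temporal inferior
40° each — tilted to the individual fovea–disc axis, with angles increasing
clockwise for right eyes and anticlockwise for left eyes. Reflectance is
sampled on the 1750 µm-radius circle by bilinear interpolation.

**Index extraction** (`enfaceoct.indices`). An objective surrogate for the
human grader: bundle presence is thresholded against a deep bundle-free
reference (median + k·MAD), blood vessels — the only elements that stay
hyperreflective at every depth — are masked by persistence, and per sector
the pipeline reports

* **first gap** — shallowest depth at which a bundle-free run ≥ 3° crosses
  the circle in the sector (0 µm when bundles are absent at the first slab);
* **last visible bundle** — deepest depth at which a bundle run ≥ 1° still
  crosses the circle;

plus sector-width-weighted averages and circumpapillary RNFL thickness
interpolated at the matching angles.

**Statistics** (`enfaceoct.stats`). Linear mixed models
`y ~ disease + (1|eye) + (1|sector)` with ML likelihood-ratio tests; Welch
post-hoc t-tests with a Bonferroni family of 14; standardized partial AUC at
specificity 90–100% (trapezoid rule, McClish scaling: 0.5 = chance, 1 =
perfect) with stratified-bootstrap CIs; paired pAUC comparisons (DeLong on
full AUC or paired bootstrap); repeated-measures correlation (ANCOVA with
subject intercepts, df = N − subjects − 1); Pearson correlations with
Fisher-z CIs; minimum detectable correlation at given power; and the
early-glaucoma subgroup filter (mean deviation ≥ −4 dB).

**Synthetic data** (`enfaceoct.synthetic`). Image-level eyes (striated
bundles with a smooth ISNT-like depth-extent profile, optional wedge
defects, persistent vessels, Gaussian noise) whose true per-sector indices
are derived analytically, and index-level cohorts drawn from a
variance-components model with configurable disease offsets and
depth–thickness correlation.

## Worked example

Simulate a 20 + 20 cohort with the package defaults (disease offsets 39.1
and 48.1 µm; group correlations 0.92/0.80), run the full battery, report:

```bash
enfaceoct simulate-cohort --out demo --seed 7
enfaceoct analyze demo/cohort.csv --out demo/ana --seed 7 --bootstrap 2000
enfaceoct report demo/ana/results.json
```

```
eyes: {'control': 20, 'glaucoma': 20}
first_gap_um: difference 37.3 um (95% CI 31.8 to 42.8), LRT chi2(1) = 66.8, p = 3.00e-16
last_visible_um: difference 45.9 um (95% CI 40.3 to 51.6), LRT chi2(1) = 78.8, p = 6.77e-19
rmcorr first_gap_um|all: r(df=199) = 0.85 (95% CI 0.80 to 0.88)
rmcorr first_gap_um|control: r(df=99) = 0.93 (95% CI 0.90 to 0.95)
rmcorr first_gap_um|glaucoma: r(df=99) = 0.77 (95% CI 0.68 to 0.84)
min detectable r: 0.48 (all), 0.65 (per group)
```

The first-gap depth is ~37 µm shallower in the simulated glaucoma eyes
(truth: 39.1 µm), the index–thickness coupling is strong in both groups and
weaker under disease, and `demo/ana/diagnostic_table.csv` holds the
standardized pAUC (with bootstrap CI) per sector and weighted average for
both enface indices and their thickness counterparts.

Image-level, with ground truth:

```bash
enfaceoct simulate-eye --out eye --seed 1 --noise-sd 0.05
enfaceoct extract-indices eye/stack.tiff --geometry eye/geometry.json --out eye/idx
```

`eye/idx/indices.csv` then matches the analytic truth in `eye/truth.json`
to within one slab (3.87 µm), e.g. temporal first gap 112.23 µm extracted
vs 112.23 µm true.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated data, the analytically forced quantities
the pipeline must reproduce: the repeated-measures-correlation error degrees
of freedom for the three cohort layouts analyzed (full cohort, one group,
one group with a censored sector) and the minimum detectable Pearson
correlations at 90% power for n = 40 and n = 20.

## Layout

```
src/enfaceoct/     constants, enface, geometry, indices, synthetic,
                   stats, analysis, io, cli
tests/             unit + property tests; test_acceptance.py holds the
                   calibration suites (mixed-model recovery/type-I error,
                   bootstrap-CI coverage, oracle equivalences, 50-eye
                   noiseless index recovery)
docs/methods.md    model assumptions, parameter defaults, numerical choices
```

Real-data mode consumes an ILM-flattened volume (or precomputed enface
stack) as multi-page TIFF, an ONH-center/fovea/laterality JSON sidecar, and
a circumpapillary thickness CSV (`angle_deg,thickness_um`); scanner-vendor
file ingestion, ILM segmentation, image registration and beam-incidence
correction are out of scope.
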