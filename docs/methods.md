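# Methods

This note records the model underlying `maculamap`, the choices made
where the design was genuinely open, and what the synthetic-cohort
tests do and do not establish about real data.

## Coordinate conventions

All analysis is carried out in right-eye visual-field degrees. Left-eye
data are mirrored horizontally (`to_right_eye_format`). The only
retinal correspondence applied is the vertical flip of the VF about the
horizontal midline: a stimulus at VF (x, y) probes retina (x, −y).
`x` is carried through the flip unchanged, so in the retinal frame the
nasal retina sits at x > 0 and the temporal retina at x < 0.
Superpixels are numbered row-major from the superior-temporal corner
(x = −12°, y = +12°), columns temporal → nasal, rows superior →
inferior.

## Perimetric pattern and unit maps

The 10–2 pattern is generated as all odd-integer (x, y) with
|x|, |y| ≤ 9 and x² + y² ≤ 82. This rule yields exactly 68 locations,
17 per quadrant, symmetric under both axis reflections and coordinate
exchange, which matches the published cardinality and spacing of the
device pattern; individual unit memberships of the clinical grid
cannot be verified against a printed table, so the pattern is also
constructible from user data via the `VFPattern` container.

For the conventional scheme the 8 × 8 grid has boundaries at
{−12, −9, …, 12}; odd-coordinate stimuli with |coordinate| ∈ {3, 9}
fall exactly on cell boundaries. Ties are broken toward the
**peripheral** cell (away from fixation): cell intervals are half-open
with the closed edge on the peripheral side. This is the only simple
axis-aligned rule we found that reproduces the published 40 units with
memberships between 1 and 4. The localized 12 × 12/2° grid needs no
tie-break: its cell centres coincide with the stimuli.

Per-eye anatomical rotation (the fovea–Bruch's-membrane-opening axis)
is applied to the *grid*, not the data: membership tests counter-rotate
the query point about the fovea, so centre-to-centre distances — and
therefore vector lengths — are rotation-invariant. The default
simulated FoBMO angle is Normal(−7°, 2.5°) per subject, a typical
anatomical distribution; unit maps themselves are built on the
unrotated canonical grid.

Optic-nerve-head exclusion removes superpixels whose centre falls
inside a configurable disc (default centre (15.5°, −1.5°) nasal,
radius 2°, which lies outside the 24° analysis square, so nothing is
excluded by default). Excluded cells keep their correlations in the
atlas but never participate in the argmax.

## Correlation atlas and vector maps

Sensitivities are converted to the linear reciprocal-luminance scale,
linear = 10^(dB/10), **before** averaging within units and before
correlation. Whether averaging should precede or follow linearization
is an open choice; linear-first is the default and the alternative is
available (`linearize_first=False`). Pearson correlations are computed
across all pooled subjects (patients and healthy). Pairs with zero
variance on either side are undefined (NaN) and are excluded from the
argmax rather than treated as zero. Exact argmax ties are broken
toward the mapped superpixel (conservative toward "hit"), then by
distance to the mapped superpixel, then by lowest id. Vector length is
the Euclidean distance between superpixel centres; the attainable
extremes (3°–12.73° on the conventional grid, 2°–12.81° on the
localized grid) bracket the published vector-length ranges.

## Statistics

Correlations are Fisher z-transformed (atanh) before the two-sided
Wilcoxon signed-rank test. Zero differences are dropped; ties receive
mid-ranks. For n ≤ 25 the exact null distribution is computed by
dynamic programming over all 2ⁿ sign assignments of the doubled
mid-ranks — this conditions on the observed ties, which the exact
method of `scipy.stats.wilcoxon` does not — and above that the normal
approximation with the tie-corrected variance Σrᵢ²/4 is used.
Empirical size under the null is checked at α = 0.05 (criterion:
rejection rate within [0.02, 0.09] over 200 seeded replicates).

The published scheme comparison pairs 40 conventional units with 68
localized ones without stating a rule. The default here averages the
Fisher-z of each conventional unit's member locations' localized
values (40 pairs); a spatial-nearest alternative is provided. No
multiplicity correction is applied.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not retinal images:

* **Normative profile** (per layer): rotationally symmetric; a smooth
  sin² rise from the foveal value to the peak at 4.5°, then a Gaussian
  decay to a peripheral floor. Defaults (GCL: 8 → 54 → 19.5 µm, decay
  4.5°; IPL: 18 → 42 → 20 µm, decay 4.5°) give a healthy grid-mean GCL
  of ≈ 32 µm, consistent with the mild tertile boundary (≥ 28 µm).
* **Damage**: arcuate patterns — depth × smooth angular window ×
  smooth eccentricity window, hard-zeroed across the horizontal raphe;
  multiple patterns combine as 1 − Π(1 − dᵢ). Severity tertiles draw
  damage from per-tertile parameter ranges and rejection-sample until
  the *measured* mean GCL and MD classify into the intended tertile
  (tertile 1: two deep wide patterns; tertile 3: one shallow narrow
  one). The default cohort is 38 patients split near-evenly across
  tertiles plus 10 healthy eyes; simulated MD spans ≈ −21 to +0.3 dB.
* **Sensitivity link**: healthy surface 33 dB minus 0.1 dB/°, minus
  max_loss (30 dB) × damage at the ganglion-cell position, plus
  Gaussian noise (1.5 dB), clamped to [0, 35]. MD is the unweighted
  mean deviation over the 68 locations (the device statistic weights by
  normative variance, which has no synthetic analogue).
* **Displacement**: stimuli are pushed radially outward by
  dmax·exp(−ecc/τ) (defaults 2°, τ = 3°), zero beyond 8°.
* **Fixation jitter**: standard perimetry adds a Normal(0, 1.5°) offset
  per location; fundus tracking zeroes it.
* **Thickness sampling**: cell means over a fixed 5 × 5 interior
  quadrature lattice (deterministic, matching the analysis resolution)
  plus Normal(0, 2.5 µm) noise, clipped at zero.

All randomness flows from one `numpy` Generator per cohort; the same
seed reproduces byte-identical exports.

## Validation experiments

* **Identity recovery** (`experiments.identity_recovery`): zero noise,
  displacement and jitter off, and a diagnostic link that reports the
  thickness of the containing analysis-grid cell in place of a
  psychophysical response. The unit ↔ mapped-superpixel association is
  then exact by construction, so *every* damaged unit must be a hit;
  any miss indicates a defect in the grids, unit assignment or argmax.
* **Localized damage** (`experiments.localized_damage_recovery`): all
  patients share one defect scaled to a single superpixel's footprint,
  varying only in depth. Under low noise, that superpixel carries the
  largest damage-driven thickness variance, so its correlation with
  every in-band unit survives noise attenuation best and all in-band
  vectors must converge on it. The experiment uses 100 patients: the
  linearized dB scale is strongly right-skewed, which inflates the
  sampling variability of Pearson correlations, and smaller cohorts
  occasionally let an adjacent cell win by sampling luck.
* **Aggregation / tracking contrast**: at matched modality, the
  conventional scheme (sensitivity averaged over up to 4 locations,
  thickness over 3° cells) yields a higher median maximum correlation
  than the localized scheme, and at matched aggregation, tracked
  perimetry is never worse than standard perimetry under jitter. The
  test averages medians over three seeded replicates because single
  cohorts of 48 leave the tracked-modality aggregation gap (~0.015)
  within Monte-Carlo noise.

## What the simulator does *not* show

Passing these tests demonstrates that the mapping machinery is correct
and that the aggregation and tracking mechanisms behave as the analysis
assumes — not that the synthetic cohort reproduces clinical effect
sizes. In particular, the clinical observation that the conventional
approach on *standard* perimetry out-performed the localized approach
on *tracked* perimetry is not reproduced by the defaults: in the
simulator, removing fixation jitter helps more than 2°-scale
aggregation hurts. In the clinic, additional factors — subjects'
greater experience with standard perimetry, different thresholding
strategies between devices — penalized the tracked exams; such
device-asymmetric noise can be emulated by raising
`sensitivity_noise_db` for the tracked runs but is deliberately not
part of the defaults. Other absent features: no learning effects, no
reliability indices, no B-scan-level segmentation error, fixation
jitter i.i.d. per location rather than drifting, and one eye per
subject with no inter-eye correlation.

## Problem sizes

Default problem sizes were chosen so a full pipeline run (48 subjects,
both schemes, both modalities, both layers, with figures) completes in
seconds and the entire test suite in well under a minute: cohorts of
9–48 subjects, recovery experiments of 30–115 subjects, 200 replicates
for the null-calibration and noise-recovery checks.
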