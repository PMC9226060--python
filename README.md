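# maculamap

Structure–function correlation mapping in the glaucomatous macula.

Glaucoma thins the inner retinal layers — the ganglion cell layer (GCL)
and inner plexiform layer (IPL) — and depresses visual-field (VF)
sensitivity. How tightly the two kinds of damage correspond *spatially*
is a long-standing question: OCT measures thickness over superpixels of
the macula, perimetry measures sensitivity at discrete stimulus
locations, and the mapping between them is imperfect (ganglion cells
are displaced from the photoreceptors they serve, fixation wanders
during non-tracked perimetry, and both instruments are noisy).

`maculamap` implements the exhaustive correlation-mapping analysis for
the central 10°:

* the **10–2 perimetric pattern** — 68 stimuli on the odd-integer
  lattice, 2° apart, with x² + y² ≤ 82;
* two superpixel schemes over a 24° fovea-centred square, in right-eye
  retinal coordinates with the VF flipped along the horizontal midline:
  * **CMA** (conventional mapped approach): an 8 × 8 grid of 3°
    superpixels; the 68 stimuli group into **40 VF units** of 1–4
    locations each;
  * **LMA** (localized mapped approach): a 12 × 12 grid of 2°
    superpixels whose cell centres coincide with the stimuli; **68
    units** of a single location each;
* the **correlation atlas**: sensitivities are converted from decibels
  to the linear scale (dB = 10 log₁₀(1/L), so linear = 10^(dB/10)),
  averaged within units, and Pearson-correlated across subjects with
  mean thickness in *every* superpixel — a (units × superpixels) matrix
  per layer;
* the **vector map**: for each unit, an arrow from its mapped
  superpixel to the superpixel of maximum correlation; length in
  degrees, a zero-length vector is a "hit";
* **comparisons**: Fisher z-transformation followed by the two-sided
  Wilcoxon signed-rank test (exact for n ≤ 25, handling ties in the
  mid-ranks), for scheme-vs-scheme, modality-vs-modality and
  superior-vs-inferior hemimacula contrasts.

Because clinical OCT volumes and perimetry exams are not distributable,
the package ships a **synthetic cohort simulator** with known ground
truth: bull's-eye normative thickness profiles that thin rapidly beyond
8° eccentricity, arcuate damage that respects the horizontal raphe, a
monotone damage → sensitivity link, centrifugal ganglion-cell
displacement (≤ 2–3°, central retina only), fixation jitter for
non-tracked perimetry, and severity stratified into tertiles of mean
GCL thickness (≤ 23 / 24–27 / ≥ 28 µm) and 10–2 mean deviation
(≤ −10 / −10..−4 / ≥ −4 dB).

## Worked example

```python
import numpy as np
from maculamap import (simulate_cohort, assign_units, correlation_atlas,
                       vector_map, summarize_vectors, hemimacula_split)
from maculamap.stats import distribution_summary

cohort = simulate_cohort(n_glaucoma=38, n_healthy=10, seed=1)
um    = assign_units(cohort.pattern, cohort.grids["CMA"], "CMA")
atlas = correlation_atlas(cohort, um, um.grid, "GCL", "standard")
vmap  = vector_map(atlas)

print(summarize_vectors(vmap))
print({k: round(v, 2) for k, v in distribution_summary(vmap.frame["r_max"]).items()})
split = hemimacula_split(vmap)
print("superior %.2f inferior %.2f" %
      (np.median(split["superior"]), np.median(split["inferior"])))
```

prints

```
{'n_units': 40, 'hit_count': 10, 'hit_rate': 0.25,
 'median_nonzero_length': 4.242640687119285, 'min_nonzero_length': 3.0,
 'max_nonzero_length': 20.12461179749811, 'crossings': 5}
{'median': 0.74, 'q1': 0.61, 'q3': 0.83, 'min': 0.37, 'max': 0.93}
superior 0.70 inferior 0.79
```

Read: of the 40 conventional VF units, only 10 (25%) have their maximum
correlation in their own mapped superpixel; the nonzero vectors have a
median length of 4.2° — far beyond any ganglion-cell displacement model
(1–3°) — and 5 cross the horizontal midline. The median maximum
correlation is 0.74, and the inferior hemimacula (superior VF) shows
stronger correlations than the superior one, because the simulated
arcuate damage and the thick central annulus concentrate the usable
between-subject variance there. Measurement noise and the spatial
pattern of damage, not mapping accuracy, decide where the vectors
point.

The command-line pipeline wraps the same calls:

```bash
maculamap report --seed 7 --outdir run7      # simulate -> analyze -> compare
maculamap analyze --seed 7 --outdir run7 --scheme LMA --modality tracked --layer GCL
```

Every figure (heatmap panels, vector maps, box plots) is written next
to a CSV twin; a run is reproducible byte-for-byte from its
`config.yaml`.

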