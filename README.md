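# ihcquant

Dual quantification of immunostained tissue area, with the statistics needed
to decide whether the fast way agrees with the trusted way.

## The problem

In immunohistochemistry (IHC), inflammatory infiltrates are quantified as the
**area fraction** — the percentage of a 400× field occupied by DAB-brown
stained tissue (CD3, CD4, CD8, CD15, CD20, CD68, CD138 markers in
periodontal/peri-implant lesions, for instance). Two workflows are in use:

- **Manual counting (MC)** — the stereological point count. A systematic grid
  of *n* points (594 by default, laid out 27×22) is superimposed on the image
  and the observer counts the points falling on stained tissue:
  `A_A ≈ P_P = 100 · hits / n`. With random point placement this is an
  unbiased binomial estimator with SD `100·√(p(1−p)/n)`.
- **Digital counting (DC)** — seeded color-range selection. The stain color
  is sampled from a stained structure; every pixel within a *fuzziness*
  tolerance (default 100, Chebyshev distance in RGB) of a sampled color is
  selected, and `100 · selected / total` pixels is reported.

DC is fast but color-blind in the worst sense: diffuse non-specific brown
background ("NOISE" slides) enters the selection, while a human point-counter
simply ignores it. `ihcquant` implements both estimators, a synthetic-field
generator with exact ground truth to probe them, the method-agreement
statistics (one-way random-effects ICC with Fleiss labels `>0.75` excellent /
`0.40–0.75` good / `<0.40` poor; Bland–Altman bias and limits of agreement
`d̄ ± 1.96·SD(d)`; Pearson proportional-bias check), the two-group cohort
comparison (Mann–Whitney, Wilcoxon signed-rank with exact small-sample
enumeration, D'Agostino–Pearson normality), and an end-to-end study runner
that replays the whole two-observer × two-timepoint agreement design in
silico.

## Worked example

```python
import numpy as np
from ihcquant import (FieldGenParams, generate_field, add_background_noise,
                      sample_stain_color, ColorRangeSpec, dc_area_fraction)

good = generate_field(FieldGenParams(target_fraction=12.0, seed=5, extent=(256, 256)))
noise = add_background_noise(good, noise_intensity=0.5, seed=6)

color = sample_stain_color(good.image, tuple(np.argwhere(good.truth_mask)[0]), median3=True)
spec = ColorRangeSpec(sampled_colors=(color,), fuzziness=100)
print(good.true_fraction, dc_area_fraction(good.image, spec), dc_area_fraction(noise.image, spec))
```

prints (see `examples/color_range_counting.py`):

```
ground truth        : 12.000%
digital count, GOOD : 12.000%
digital count, NOISE: 13.716%
```

On the clean field the color selection recovers the true fraction exactly
(the generator guarantees color separability at fuzziness 100); on the noisy
field the brown haze inflates the count by ~1.7 percentage points even though
the underlying staining is identical. The agreement side
(`examples/method_agreement.py`), on 200 simulated pairs with differences
drawn Normal(−0.44, 1):

```
ICC(1,1) = 0.991 (excellent); between-subject var 68.45, error var 0.60
Bland-Altman: bias -0.419%, limits [-2.400, +1.561]%, 94.5% of pairs inside
```

i.e. nearly all variance is real between-sample variation, and ~95% of paired
differences fall inside the limits of agreement, as normal theory predicts.

Each script in `examples/` is a self-contained narrative for one capability:
field generation, point counting, color-range counting, agreement statistics,
the PI-vs-PD cohort comparison, and the full simulated study
(`examples/full_study.py`, which writes the ICC and Bland–Altman tables).

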