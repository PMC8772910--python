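# thermotex

Texture analysis of pseudo-color infrared thermography (IRT) images of the
equine thoracolumbar region, built to ask a welfare question: does the
rider:horse bodyweight ratio leave a measurable imprint on the horse's back
surface temperature pattern after exercise?

Conventional thermography reduces a region of interest (ROI) to three
numbers — the average, maximal and minimal temperature (Taver, Tmax, Tmin,
°C) — and is known to be insensitive to rider load in the common 10–18 %
range. `thermotex` instead decomposes the pseudo-color thermogram into its
red, green and blue component planes and quantifies the *texture* of each
plane within each ROI with 31 features from three classic families:

* **HS** — 13 first-order statistics of the normalized gray-level histogram
  H(k): mean Σ k·H(k), variance, skewness, kurtosis, the 1/10/50/90/99th
  percentiles, and the dominant/maximum statistics of H and of its 10-bin
  moving sum (Domn01/Domn10, Maxm01/Maxm10);
* **GLRLM** — 7 features of the gray-level run-length matrix p(i, j) (runs
  of gray level i and length j along a scan direction): GLN, RLN, LRE, SRE,
  Fraction, MRLN, MGLN;
* **GLCM** — the 11 Haralick features of the symmetric, normalized
  gray-level co-occurrence matrix at offset d = 1 (AngScMom, Contrast,
  Correlat, SumOfSqs, InvDefMom, SumAverg, SumVarnc, SumEntrp, Entropy,
  DifVarnc, DifEntrp), averaged over the 0°/45°/90°/135° directions.

With 4 ROIs (withers; thoracic spine; left/right back musculature) and 3
components this yields 372 texture feature keys per image. The statistical
screen mirrors the study design it serves: riders are banded by the ratio
R/H = 100·(rider + saddle weight)/horse bodyweight into light (10–12 %),
moderate (>12–15 %) and heavy (>15–<18 %) groups; each feature key is first
tested pre- vs post-exercise within every group (paired t-test when both
series pass a Shapiro–Wilk gate, Wilcoxon signed-rank otherwise, α = 0.05)
and carried forward only if significant in all three groups simultaneously;
carried-forward keys are then compared across groups (ANOVA + Tukey when
Gaussian, Kruskal–Wallis + Dunn otherwise) and the pairwise outcomes are
classified into difference patterns I (L≠H), II (L,M≠H) or III (all differ).

Because no radiometric image archive of such a study is publicly available,
the package ships a synthetic study generator that emulates the design end
to end — 12 horses × 6 riders (2 per group) imaged pre/post exercise (144
images), with exercise warming plus group-dependent temperature
heterogeneity confined to the muscle-rich ROIs — so the whole pipeline is
testable and its statistical behaviour can be calibrated.

Intended users: veterinary imaging researchers and image-analysis
developers who need a transparent, tested reference implementation of
HS/GLRLM/GLCM texture screening for thermal (or other pseudo-color) images.

## Worked example

```python
import numpy as np
from thermotex import (build_combination_table, summarize_groups,
                       texture_feature_vector, generate_study, SimulationConfig)
from thermotex.study_design import reference_riders, reference_horses

# the published study design: 6 riders x 12 horses
combos = build_combination_table(reference_riders(), reference_horses())
for g, s in summarize_groups(combos).items():
    print(f"group {g}: mean ratio {s['mean']}% (range {s['range'][0]}-{s['range'][1]}%), n={s['n']}")

# texture of the red component in ROI 1 of one synthetic post-exercise image
study = generate_study(SimulationConfig(seed=0))
red = study.images[("A", "1", "post")][:, :, 0]
vec = texture_feature_vector(red, study.masks[0])
for name in ("Mean", "Variance", "Entropy", "SumEntrp", "InvDefMom", "SRE"):
    print(f"{name:10s} {vec[name]:.4f}")
```

prints

```
group L: mean ratio 11.2% (range 10.6-11.8%), n=24
group M: mean ratio 14.2% (range 13.5-14.9%), n=24
group H: mean ratio 16.9% (range 16.3-17.7%), n=24
Mean       200.0844
Variance   67.2888
Entropy    9.5760
SumEntrp   5.8049
InvDefMom  0.1385
SRE        0.9593
```

The group summaries reproduce the published design arithmetic exactly; the
feature values describe the red-plane texture of the withers ROI — for a
rider in the light group the co-occurrence entropy (9.58 bits here) sits
systematically below the values produced under moderate and heavy riders.

The same pipeline is available from the shell:

```bash
thermotex simulate --seed 1 --out study/
thermotex extract  --study study/ --out features.csv
thermotex analyze  --features features.csv --out analysis/
thermotex report   --analysis analysis/ --out report.md
```

Estimator-style entry points (`TextureFeatureExtractor`,
`ExerciseGroupScreen`) follow scikit-learn conventions (`fit`/`transform`,
`get_params`, trailing-underscore fitted attributes) and compose with
sklearn pipelines.

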