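# halluxmetry

Axis-based automatic goniometry of dorsoplantar foot radiographs.

Hallux valgus severity is graded on two radiographic indices: the hallux
valgus angle (**HVA**) between the bone axes of the first proximal phalanx
(PH1) and the first metatarsal (MT1), and the first–second intermetatarsal
angle (**IMA**) between the MT1 and MT2 axes. Manual goniometry is reliable
only to within a few degrees and varies between raters; segmentation-based
automation struggles when deformity makes bone regions overlap.

`halluxmetry` implements an axis-based alternative aimed at researchers who
need reproducible HVA/IMA measurements and at methodologists studying
landmark/axis regression:

1. **Annotation encoding** — an expert-drawn axis segment per bone
   (PH1, MT1–MT5) is rasterized (1 px, 8-connected), thickened to a 5-px
   band, and blurred with a Gaussian whose standard deviation is
   σ = h/(2.5·L) for PH1 and σ = h/L for the metatarsals (h = image height,
   L = segment length), giving one probabilistic heatmap per bone. Channels
   are independent, so overlapping bones pose no labeling conflict.
2. **Heatmap regression** — an encoder–decoder network with five resolution
   levels and skip connections maps the standardized 512×512 radiograph to
   the 6-channel heatmap stack, trained with an RMSE loss (Adam, minibatch
   7, ≤12 epochs, validation every 200 iterations, patience 10).
3. **Axis extraction** — the high-value area of each predicted channel
   (≥ 0.5 × channel max) is fitted by its value-weighted principal axis
   (total least squares, well-conditioned for near-vertical bones); axes
   are oriented proximal→distal and the inclinations θ (counterclockwise
   from the right-facing horizontal) yield

       HVA = PH1a − MT1a,    IMA = MT2a − MT1a.

4. **Validation statistics** — mean absolute error against the median of
   three raters, a one-tailed t-test against the 3° acceptability margin,
   error bands (<3°, 3–5°, >5°), pairwise inter-rater differences
   Diff_12/Diff_23/Diff_31 and their mean Diff_123, paired t-tests of MAE
   vs Diff_123, and the noncentral-t power analysis for sizing a validation
   cohort.

Because clinical radiographs cannot ship with the package, a **phantom
generator** renders capsule-shaped "bones" with exactly known axis angles
(and controllable noise, crowding and left/right mirroring), and a **rater
simulator** jitters the ground truth to emulate human measurement spread.
Every stage is tested end-to-end against these known truths.

## Worked example

```python
from halluxmetry import (PhantomSpec, generate_phantom, make_heatmaps,
                         measure_stack, derive_angles, required_sample_size)

spec = PhantomSpec(image_height=512, image_width=512, side="right",
                   true_HVA=-28.0, true_IMA=-13.0, seed=42)
sample = generate_phantom(spec)

truth = derive_angles(sample.annotation)
result = measure_stack(make_heatmaps(sample.annotation))  # network bypassed
print("truth:    HVA = %.2f  IMA = %.2f" % (truth.HVA, truth.IMA))
print("measured: HVA = %.2f  IMA = %.2f" % (result.angles.HVA, result.angles.IMA))
print("cohort size:", required_sample_size())
```

prints

```
truth:    HVA = -28.00  IMA = -13.00
measured: HVA = -28.26  IMA = -13.05
cohort size: 92
```

The phantom was built with a hallux deviated 28° laterally from the first
metatarsal; encoding its ground-truth axes as heatmaps and fitting them
back recovers the angle to a quarter degree (the residual is rasterization
and blur discretization). The cohort size is the smallest n at which a
one-sided one-sample t-test (α = 0.05) of "mean absolute error < 3°"
reaches power 0.99 when the true error is 1.5° with SD 3.58°.

The same stages are exposed on the command line:

```
halluxmetry phantoms generate --n 20 --seed 1 --out data/
halluxmetry train --data data/ --out model.ckpt.npz
halluxmetry measure --model model.ckpt.npz --images data/ --out angles.csv
halluxmetry validate --auto angles.csv --raters r1.csv r2.csv r3.csv --out report.csv
halluxmetry power --mae 1.5 --sd 3.58 --bound 3 --power 0.99
halluxmetry e2e --n 200 --size 128 --seed 1 --out run/
```

`e2e` runs the whole loop — phantoms → heatmaps → training → measurement →
simulated raters → agreement report — reproducibly from one seed. On one
CPU core the 200-phantom run above takes a few minutes and ends with

```
             MAE  CI95_upper  p_vs_bound  n_lt3  n_3to5  n_gt5  Diff_123_mean  p_MAE_vs_Diff123
parameter
HVA        2.107       2.703       0.009     14       5      1          3.598             0.027
IMA        1.092       1.451       0.000     19       1      0          2.965             0.000
PH1a       1.552       2.022       0.000     17       3      0          2.926             0.020
MT1a       1.022       1.280       0.000     20       0      0          2.144             0.003
MT2a       0.935       1.271       0.000     19       1      0          2.231             0.000
MT3a       1.429       1.750       0.000     19       1      0          1.882             0.165
MT4a       1.161       1.546       0.000     19       1      0          1.931             0.002
MT5a       1.276       1.554       0.000     20       0      0          1.889             0.071
```

Read it like an agreement table: on the 20 held-out phantoms the trained
network's HVA error against the median of three simulated raters is 2.1°
on average (one-sided 95% upper bound 2.7°), significantly below the 3°
acceptability margin (p = 0.009), with 14/20 cases under 3°; it is also
significantly smaller than the raters' own disagreement (Diff_123 = 3.6°,
paired p = 0.027). A desk-scale run trains a thin network on small images,
so its errors are larger than a clinical-scale model's would be; the
structure of the conclusions is what carries over.

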