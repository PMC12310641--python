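# lidcurve

Automated measurement of eyelid-margin curvature from anterior-segment
photographs.

Eyelid contour shape is a clinically useful morphological indicator
(ptosis, entropion/ectropion assessment, post-surgical evaluation), but
manual annotation of the lid margin is slow and subjective. `lidcurve`
automates the pipeline end to end:

1. **Segmentation** — a dual-decoder attention U-Net (AtDU-Net) with a
   shared hierarchical encoder segments the palpebral fissure and the
   cornea simultaneously. The encoder stacks Hierarchical Attention
   Sampling Modules (strided compression + squeeze-excite channel gating
   + large-kernel global-context aggregation) and Split Axial Detail
   Modules (single-head self-attention applied separately along rows and
   columns, residually combined). Each region gets its own U-Net style
   decoder with skip connections and a sigmoid output map.
2. **Measurement** — from the binary masks, the fissure's inner boundary
   is traced in a bottom-left y-up pixel frame and split into upper and
   lower lid chains (one y per column). The smallest enclosing circle of
   the corneal mask gives the corneal centre c(m, n) and radius r; both
   chains are restricted to the corneal span [m − r, m + r] and fitted
   by ordinary least squares with a quadratic y = ax² + bx + c. The
   plane-curve curvature

       K(x) = |y″| / (1 + y′²)^{3/2} = |2a| / (1 + (2ax + b)²)^{3/2}

   is averaged over every integer column of the span and also evaluated
   at the key positions x ∈ {m − r, m, m + r}. Curvature converts from
   pixel⁻¹ to mm⁻¹ using the pixel scale implied by the corneal
   horizontal diameter (11.5 mm), so every image self-calibrates.
3. **Evaluation** — IoU/Dice overlap and HD95/ASSD surface distances for
   segmentation; r², MAE, RMSE and Bland–Altman limits of agreement for
   curvature series.

Because clinical photographs are not distributable, the package ships a
seeded synthetic-eye generator: almond-shaped fissures bounded by two
quadratic arcs meeting at the canthi, a corneal disc, four-layer
intensity rendering plus noise, with the exact generating coefficients
stored per image. All accuracy claims in the test suite are scored
against this analytic ground truth.

## Worked example

```bash
# 20 synthetic eyes with ground-truth masks and geometry
lidcurve simulate --n 20 --seed 1 --out data/

# train the dual-decoder network and keep the best-Dice epoch
lidcurve train --data data/manifest.json --out model.ckpt --epochs 30 --seed 0

# measure curvature from a mask pair
lidcurve measure --fissure data/masks/eye_0000_fissure.png \
                 --cornea  data/masks/eye_0000_cornea.png  --out report.json
```

The measure command prints, for seed 1's first sample:

```
upper 0.1408 mm^-1  lower 0.1388 mm^-1  scale 0.05494 mm/px
```

meaning the upper lid margin bends with a mean curvature of
0.1408 mm⁻¹ (mean local radius ≈ 7.1 mm) over the corneal span, the
lower with 0.1388 mm⁻¹, and one pixel spans 0.05494 mm as calibrated
from the fitted corneal circle. Mean curvature over the span is lower
than the sampled vertex curvature (0.19–0.26 mm⁻¹) because the
(1 + y′²)^{3/2} factor suppresses K away from the vertex. `report.json` carries the full record: fitted
quadratic coefficients, corneal circle, point curvatures at the three
key positions, and the pixel scale.

The same stages are available as a library; the learnable stage also has
a scikit-learn style facade:

```python
from lidcurve import AtDUNetSegmenter, measure_eye

est = AtDUNetSegmenter(epochs=30, random_state=0).fit(images, masks)
pred = est.predict(images)                      # (n, H, W, 2) boolean
report = measure_eye(pred[0, ..., 0], pred[0, ..., 1])
print(report.upper_mean_mm, report.lower_mean_mm)
```

`lidcurve run --out results/ --n 20` executes the whole pipeline
(simulate → train → segment → measure → evaluate) and writes
seed-stamped CSV/JSON reports.

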