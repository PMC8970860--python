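# strabmetric

Pixel-wise ocular deviation measurement from photographs of the nine
cardinal gaze positions.

Given nine gaze-labeled eye images (or their binary sclera/limbus masks),
`strabmetric`:

1. registers every eccentric gaze onto the primary-gaze frame using a 2D
   similarity transform derived from the reference line joining the
   innermost (nasal-most) points of the two sclera regions;
2. models each eye's limbus as the minimum enclosing circle of its mask and
   the sclera as a circle with 2.5x the limbus radius;
3. locates the corneal light reflex inside the limbus of the primary gaze
   (the reflex is detected once and reused as the fixed anchor for all
   gazes);
4. recovers the limbus center in eccentric gazes by fitting an ellipse to
   the limbus boundary and stepping one limbus radius back from the outer
   short-axis contour point (near-circular fits keep the ellipse center);
5. reports per-gaze, per-eye pixel distances from the recovered limbus
   center to the primary reflex, plus declarative movement-percentage
   comparisons (within-eye or between-eye), and renders annotated overlays.

Because no patient photographs ship with the package, a synthetic nine-gaze
scene generator (`strabmetric.synthetic`) renders two-eye scenes with exact
ground-truth masks, reflex positions, camera jitter, and cranial-nerve-palsy
presets (`CN4_bilateral`, `CN6_left`), so the whole pipeline is testable end
to end. A pluggable segmenter contract (`Segmenter`) lets a trained model
replace the reference intensity-threshold segmenter without touching the
measurement code.

## CLI

```sh
# render a synthetic nine-gaze set (PNG images + masks + truth.json)
strabmetric simulate --preset CN6_left --ratio 0.3 --seed 3 --out scenes/

# run the measurement pipeline on a directory of <gaze>.png images
# (optional <gaze>.sclera.png / <gaze>.limbus.png masks are used if present)
strabmetric run --input-dir scenes/ --config config.yaml \
    --out report.json --csv report.csv --overlay-dir overlays/

# confusion-matrix metrics (accuracy/sensitivity/specificity/DSC) between
# two directories of mask PNGs with matching names
strabmetric eval-seg --pred pred/ --truth truth/ --out metrics.csv
```

Gaze file names use the fixed vocabulary `up_left, up, up_right, left,
primary, right, down_left, down, down_right`. A YAML config can set the
reflex thresholds, circularity threshold, sclera/limbus ratio, minimum
component area, eye-laterality labeling, and the comparison rows, e.g.:

```yaml
comparisons:
  - label: outwards
    numerator: [left, left]     # (gaze, eye)
    denominator: [right, right]
```

## Library

```python
import strabmetric as sm

subject = sm.default_subject((512, 512))
spec = sm.simulate_palsy_preset("CN6_left", excursion_px=32, ratio=0.3)
scenes, truth = sm.make_nine_gaze_set(subject, spec,
                                      jitter_spec=sm.JitterSpec(), seed=1)
report = sm.run_pipeline(scenes)
print(report.ratios)
```

## Conventions

- Pixel coordinates, origin top-left, x rightward, y downward; points are
  `(x, y)`; masks are boolean rasters (nonzero = foreground in PNG form).
- "left eye" / "right eye" are image-left / image-right; set
  `anatomical_laterality: true` to relabel mirrored.
- Images warp with bilinear interpolation, masks with nearest-neighbor;
  angles are degrees in (-180, 180].
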