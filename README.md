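# myofind

Automatic detection of beating adult cardiomyocytes in brightfield video
microscopy, with FFT-based sarcomere-length measurement.

## The problem

Contractility measurements on isolated adult cardiomyocytes require finding a
healthy, beating, rod-shaped cell under a 20x objective, centring and
focusing on it, aligning its striation pattern with the measurement axis and
picking the sub-region with the cleanest sarcomere signal — traditionally a
slow, manual, operator-biased process. `myofind` implements the software side
of an automated scanning workflow for this task:

- **Static detection** — cardiomyocytes have strong edges at the cell border
  and along the internal sarcomere striations. A Sobel edge map is smoothed
  (Gaussian, radius 5), contrast-stretched (0.4% saturation), thresholded by
  Otsu's method and cleaned by morphological opening; connected components
  are screened by area (1500–5500 µm²), bounding-box aspect ratio (0.1–0.7),
  distance to the frame border (10 px), fill ratio (≥ 0.55, to exclude
  multi-cell regions) and mutual separation.
- **Motion detection** — per-pixel temporal variance over a ~1 s stream at
  20 fps, computed in one pass with the shifted-data formula
  `var = (Ex2 − Ex²/n)/(n−1)` using the first frame as the shift K. A
  candidate is *beating* when motion pixels cover ≥ 5% of its mask.
- **Spectral scoring** — a 256×30 region is column-averaged into a profile;
  in the 1D magnitude spectrum the band corresponding to sarcomere spacings
  of 1–2 µm is searched for a peak `Fmax`. The baseline `Fbase` is the
  higher of the two minima flanking the peak and `FSNR = Fmax / Fbase`
  scores signal quality (cells below 2.5 are excluded). Sarcomere length is
  the reciprocal of the sub-bin-refined peak frequency.
- **Filter layer** — bilinear reorientation of the cell's long axis to
  horizontal, two-sweep fine autofocus (coarse sweep maximises `Fmax`, fine
  sweep maximises `FSNR`), residual striation-angle correction from a double
  2D FFT, and selection of the best of three stacked regions by `FSNR`.
- **Scan + validation** — outward square-spiral tiling with 30% FOV overlap,
  duplicate suppression across overlap zones, and detection validation
  against point annotations (sensitivity, precision, F1; Eqs
  `TP/(TP+FN)`, `TP/(TP+FP)`, harmonic mean).

Everything is exercised against a built-in synthetic phantom generator that
renders striped rod cells with exact ground-truth annotations, periodic
raised-cosine contraction under 2 Hz field pacing, defocus blur, background
texture and camera noise.

## Worked example

```python
import myofind as mf

# a 256x256 µm phantom dish: 3 cells, half of them beating
spec = mf.PhantomSpec(n_cells=3, beat_fraction=1.0, seed=7)
stack, truth = mf.generate_video(spec)

cands = mf.detect_static(stack.frame(0))
variance, normalized = mf.variance_map(stack)
mask = mf.motion_mask(normalized, variance=variance)
for c in cands:
    if c.accepted:
        mf.is_beating(c, normalized, precomputed_mask=mask)

cell = next(c for c in cands if c.accepted and c.is_beating)
frame = mf.reorient(stack.frame(0), cell)
region, _ = mf.select_region(frame, cell.centroid)
spectrum = mf.measure_frame(frame, region)
print(f"cell area {cell.area:.0f} µm², motion ratio {cell.motion_ratio:.2f}")
print(f"SL {spectrum.sarcomere_length:.3f} µm (truth "
      f"{truth[0].sarcomere_period:.3f}), FSNR {spectrum.FSNR:.1f}")
```

prints (seed 7):

```
cell area 2544 µm², motion ratio 0.32
SL 1.871 µm (truth 1.862), FSNR 6.3
```

i.e. the first beating cell covers 2544 µm², a third of its pixels move
during a beat, and its sarcomere spacing is recovered to within 0.01 µm at a
spectral SNR well above the 2.5 quality threshold.

The same steps are available from the shell:

```bash
myofind phantom --out dish.tif --annotations gt.json --seed 7 --n-cells 3
myofind detect dish.tif --out detections.json
myofind validate detections.json gt.json
myofind scan --fov 512 --grid 3 --overlap 0.3
```

## Layout

| module | contents |
| --- | --- |
| `myofind.phantom` | synthetic video/focal-stack generator, ground truth |
| `myofind.static_detect` | edge map, Otsu segmentation, rejection criteria |
| `myofind.motion` | shifted-data variance, beating classification |
| `myofind.spectral` | profiles, in-band spectrum, FSNR, SL traces |
| `myofind.focus` | reorientation, autofocus, angle correction, region pick |
| `myofind.pipeline` | spiral planning, dish orchestration, validation |
| `myofind.benchmark` | the standard seeded phantom benchmark |
| `myofind.io`, `myofind.cli` | TIFF/JSON/YAML round trips, `myofind` CLI |

See `docs/methods.md` for the measurement model, parameter rationale and
known limitations.
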