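# Methods

This note documents the measurement model behind `myofind`, the parameters
that matter, what the synthetic phantom does and does not emulate, and the
design choices made where the underlying procedure left room.

## Detection model

### Static (single-frame) finding

Isolated adult cardiomyocytes in brightfield are rod-shaped with strong
intensity edges at the cell border and along the internal striation. The
detector therefore works entirely on edge information:

1. Sobel gradient, combined as the Euclidean magnitude of the horizontal and
   vertical responses (rotation-tolerant; the operator itself is standard).
2. Gaussian smoothing, sigma = `gaussian_radius` (default 5 px), which fuses
   the striation edges into a filled cell-interior response.
3. Linear contrast stretch saturating `saturated_fraction` (default 0.4%)
   of pixels at each end, rescaled into the input intensity range.
4. Otsu threshold on the full edge histogram (global, 256 bins; ties resolve
   to the lowest maximiser), mask = edges ≥ threshold.
5. Morphological opening with a disk (default radius 3 px) to delete specks
   and split near-touching cells, then hole filling (cell interiors can be
   locally edge-dark).

Connected components (8-connectivity) are screened in a fixed order, and
only the first failed criterion is recorded per candidate, so diagnostics
are reproducible:

| # | criterion | default | note |
|---|---|---|---|
| 1 | area | 1500–5500 µm² | pixel count × pixel_size², inclusive bounds |
| 2 | bbox aspect (short/long) | 0.1–0.7 | the stated range is < 1, so the ratio is taken short-side/long-side |
| 3 | border margin | 10 px | whole bbox must clear every frame border |
| 4 | fill ratio (mask/bbox) | ≥ 0.55 | rejects multi-cell regions; rejection is strictly-below |
| 5 | centroid separation | ≥ 40 µm | against already-accepted candidates, in scan order |

The aspect and fill criteria use the *axis-aligned* bounding box. A
consequence worth knowing: a 3.6:1 rod tilted beyond ~12° falls below the
0.55 fill threshold purely by geometry, so the detector intrinsically
prefers roughly axis-aligned cells. The phantom's default orientation range
(±8°) stays within the compliant regime; wider orientations are available
and are rejected exactly as a real tilted cell would be.

### Motion (beating) finding

Beating is decided from the per-pixel variance of intensity through time
over a short stream (default 20 frames ≈ 1 s at 20 fps — at 2 Hz pacing at
least one full beat). The variance uses the one-pass shifted-data form with
the first frame as the shift K:

    Ex  += x − K        Ex2 += (x − K)²
    var = (Ex2 − Ex·Ex/n) / (n − 1)

which is algebraically the two-pass sample variance for any constant K and
numerically stable when K lies inside the sample range. Accumulators are
float64, so 16-bit input is safe over at least 10⁴ frames. The variance map
is affinely normalised to [0, 255].

The procedure that defines "motion pixels" before the area ratio is not
fixed by the underlying method; this package's choice (configurable) is Otsu
on the normalised map, guarded by a noise floor: when the raw variance
maximum is below 4× its median the map is considered sensor noise and no
pixel counts as motion. A candidate is beating when motion pixels cover at
least 5% of its mask — boundary inclusive, evaluated over the mask (not the
bbox).

## Sarcomere spectral measurement

A 256×30 window (long axis along image columns) is column-averaged into a
256-sample profile; the profile is mean-subtracted (so DC can never be the
peak) and transformed with a real FFT. Bins whose spatial period lies in
1–2 µm form the measurement band — at 0.25 µm/px that is bins 32–64, and
pixel sizes above 0.5 µm/px (fewer than 3 bins) are rejected with the bound
named in the error.

* `Fmax` — largest in-band magnitude; `peak_bin` its bin.
* `Fbase` — walk outward from the peak on each side while the magnitude
  decreases, clipped to the band edges; `Fbase` is the **higher** of the two
  flanking minima.
* `FSNR = Fmax / Fbase` — quality score; the conventional cell-exclusion
  threshold is 2.5, boundary inclusive.
* Sarcomere length — 1 / peak frequency after 3-point parabolic refinement
  on log magnitudes (sub-bin resolution is needed for contraction traces;
  switchable off), clipped to the band.

No window function is applied by default; a Hann taper is available and is
used by the autofocus sweeps (below). Per-frame traces report NaN whenever
the frame's FSNR is below threshold — never a fabricated length.

## Filter layer

**Reorientation.** The frame is rotated about the candidate centroid by the
negated long-axis angle with bilinear interpolation (out-of-frame pixels
take the frame median), making striation bands vertical to match the
column-averaging direction.

**Two-sweep autofocus.** Sweep 1 scans ±10 µm in 2 µm steps and keeps the
plane maximising `Fmax`; sweep 2 scans ±2 µm in 0.5 µm steps around that
plane and keeps the plane maximising `FSNR`. Ties break toward the sweep
centre, then the lower z. Two numerical choices matter and are deliberate:

1. *Hann window in the sweep spectra.* With a rectangular window the
   baseline `Fbase` is dominated by sidelobe leakage of the peak itself;
   leakage scales with the peak, so `FSNR` barely depends on focus.
2. *Score averaging over 4 frames per plane* (`frames_per_plane`). A real
   instrument dwells several camera frames at each z; averaging the per-frame
   scores (not the images) halves the jitter of the single-bin flanking
   minimum without touching the noise floor. A source that returns identical
   frames just contributes identical scores.

With these defaults, the fine sweep recovers the true plane within one fine
step in ≥ 96% of the seeded focal-stack benchmark. Note also the regime
assumption: `FSNR` discriminates focus only when its baseline is
noise-limited. On a nearly noise-free image the baseline is pure leakage and
all near-focus planes score alike — which is also the case where fine focus
hardly matters.

**Angle correction.** The measurement window is mean-subtracted,
Hann-tapered and zero-padded to a square; the magnitude of its 2D FFT is
transformed a second time. Periodic bands then appear as a bright line
through the origin along the band direction, modulated by the window's own
double-FFT envelope. The line angle is found by maximising the
envelope-normalised magnitude summed along sampled lines (0.5° grid,
parabolic refinement); both the taper and the envelope normalisation are
necessary — without them the anisotropic 256×30 window support collapses
every estimate onto the window axes. The estimate is gated by the first
spectrum: if the in-band annulus maximum is below 6× the annulus median
(isotropic noise sits at ≤ 4, striped cells at ≥ 11 even under extreme
noise) no estimate is returned. Noise-free stripes over ±40° are recovered
within 0.5°.

**Region selection.** Three stacked 256×30 regions (centre, ±30 px
perpendicular) are scored by FSNR; the maximum wins, ties go to the centre,
and the offsets shrink symmetrically when the frame is too small.

## Scan, duplicates, validation

The dish is tiled by an outward square spiral (first move +x, then
counter-clockwise) with steps of (1 − overlap) × FOV (default overlap 30%,
chosen so cells cut by one FOV border appear whole in a neighbour). Each
accepted beating cell is re-centred (the objective moves to the cell), then
measured; a cell whose dish-coordinate centroid lies within the minimum
separation of an already-measured cell is skipped, which de-duplicates the
overlap zones. Per-FOV failures are logged and skipped — a scanning
instrument must not halt.

Validation matches detections to *point* annotations: a detection is a true
positive when an unmatched annotation point lies in its bounding box
(nearest centroid wins ties; one-to-one); bbox-IoU matching is available for
mask-level ground truth. Sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
F1 their harmonic mean; undefined ratios (zero denominators) are reported
as missing, never as 0. Across-dish summaries report unweighted means and
sample standard deviations, rounded half-even to 2 decimals (values are
pre-truncated to 10 decimals so binary float noise cannot tip an exact
half); raw values are always kept. "Successful measurement" is
operationalised as a trace whose FSNR stays at or above 2.5 in at least 80%
of frames.

## The phantom

The generator renders what the detector assumes: rod cells (default
60–100 µm × 25–40 µm, i.e. 1500–4000 µm²) with a dark 1.5 µm border and
sinusoidal striping (period 1.6–1.9 µm) perpendicular to the long axis, on a
smooth textured background (Gaussian field, sigma 40 px, amplitude 60) with
additive clipped Gaussian camera noise (default sd 40 on a ~2000 background).
Beating cells shorten along the long axis by 8% in a raised-cosine pulse of
0.1 s at 2 Hz field pacing (all cells in phase, first pulse at 0.25 s so
frame 0 is at rest); the striping compresses proportionally. Cells are
placed by rejection sampling with a separating-axis overlap test, a 50 µm
minimum centroid separation and optional placement boxes (the dish benchmark
uses the FOV interiors so every ground-truth cell is detectable somewhere).
Defocus is a Gaussian blur of sigma `blur_per_z`·|z − z_true| (default
2.5 px/µm ≈ 0.6 µm blur per µm defocus, in line with a 0.75 NA objective);
`FocalSource` emulates a live camera, drawing fresh noise on every call.

What the phantom does **not** emulate: realistic point-spread optics,
intensity vignetting, debris and dead (hypercontracted) cells, cell-to-cell
contact, irregular striation phase or amplitude, stage drift, and
fluorescence. Passing the phantom benchmark therefore demonstrates that the
implementation is faithful and self-consistent — not that it would reach the
same scores on real dishes, where published sensitivity is markedly lower
than on these clean synthetics.

## Benchmark problem sizes

The standard dish benchmark uses 3×3 FOVs of 320 px at 0.5 µm/px (dish
768 px ≈ 384 µm square), 20 frames at 20 fps, 8 cells per dish of which 6
beat; the multi-dish run uses 20 dishes. These sizes keep the full benchmark
to well under a minute while preserving the governing geometry (cell size
relative to FOV, ≥ 3 stripe samples per period, 30% overlap). The
focal-sweep benchmark centres a single 70×30 µm cell under the measurement
region at 0.25 µm/px with camera noise sd 220 (see the autofocus regime note
above).

## Known limitations

- Segmentation dilates masks by roughly the Gaussian radius, so candidate
  areas run a few hundred µm² above the geometric cell area; the screening
  bounds absorb this at the defaults.
- The fill-ratio and aspect criteria are axis-aligned, so strongly tilted
  rods are rejected by design (see above).
- `Fbase` is a single-bin statistic and noisy on single frames; anything
  ranking planes or regions by FSNR should average several frames, as the
  autofocus does.
- The angle estimator assumes one dominant striation orientation inside the
  window; two crossing cells in one window produce an arbitrary winner
  (upstream separation criteria make this rare).
- Duplicate suppression is centroid-distance based; two genuinely distinct
  cells closer than the minimum separation would be measured once — the
  same condition the separation rejection criterion already enforces
  within a FOV.
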