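# Methods

## The measurement model

The instrument performs absolute counting: stained whole blood fills a
rectangular minichannel (600 µm wide, 100 µm deep) wound helically
around a 6 mm cartridge, and a camera synchronized to the cartridge
rotation captures one field of view per fluorescence channel every 20°.
Each 0.6 × 0.49 mm field spans the full channel depth, so one frame
pair interrogates

V_frame = 600 µm × 490 µm × 100 µm = 0.0294 µL,

and a scan of *n* frame pairs interrogates n·V_frame. The estimator is
a ratio of totals,

Ĉ = (Σᵢ Nᵢ) / (n · V_frame),

where Nᵢ is the number of colocalized CD4/CD3 particles in pair *i*.
Summing counts before dividing (rather than averaging per-frame
concentrations) makes Ĉ the maximum-likelihood estimate under the
Poisson sampling model and keeps empty frames informative.

Geometry helpers (helix arc length `n_turns·√((πd)² + p²)`, channel
capacity, arc per angular step) support consistency checks: a plan
whose total sampled volume exceeds the channel capacity re-images
fluid, and a step whose surface arc is shorter than the frame height
overlaps consecutive frames; both raise warnings, not errors. The
helix pitch (700 µm = channel width + 100 µm wall) and threaded length
(56 mm of the 66 mm cartridge) are assumptions, configurable in the
`geometry:` block.

## Synthetic scans

No raw scans are available, so the pipeline is validated by parameter
recovery on a generative model of the acquisition:

- **Sampling.** Per frame, the cell count is Poisson with mean
  `cd3_concentration × V_frame`; positions are uniform in the field;
  each cell is CD4⁺ independently with probability `cd4_fraction`.
  Defaults (800 CD3⁺/µL, fraction 0.5) put the CD4 count at
  400 cells/µL, near the clinically decisive 350 cells/µL ART
  threshold.
- **Rendering.** A cell is an anisotropic Gaussian blob with
  σ = cell_diameter/4 (default diameter 8 µm, a typical lymphocyte),
  so the visible spot roughly matches the cell footprint. CD3-channel
  amplitude is 60 gray levels; CD4-channel blobs are twice as bright
  (the two stains share one excitation source and respond unequally);
  per-cell amplitudes scatter with CV 0.2. These values are declared
  stand-ins chosen to land the signal-to-background ratio in the 2–4
  range of real low-light images; no measured brightness distributions
  exist to calibrate against.
- **Background and noise.** Illumination background 20 gray levels
  with a radial quadratic vignette (30% corner falloff — the uneven
  background that rolling-ball correction exists to remove), Poisson
  shot noise of the noiseless image, additive Gaussian read noise
  (SD 2), rounding and clipping to 8 bits.
- **Under-fill.** `fill_fraction < 1` leaves the trailing frames empty
  of cells, emulating a channel whose far end holds no sample — a
  realistic failure mode that biases counts low.

The generator does **not** model red-cell debris or autofluorescence,
Airy rings or defocus gradients, cell clumping, or flow; passing
recovery tests therefore demonstrates correctness of the counting
chain under the stated statistical model, not robustness to every
artifact of real blood. Pixel grids: the physical sensor is 1280 × 960
(0.469 × 0.510 µm/px); tests and examples use the same field on a
320 × 240 grid, which keeps a cell core at 3–6 px and one frame-pair
analysis at ~0.15 s.

### Exact-recovery conditions

`exact_recovery_conditions()` defines the regime in which the pipeline
is provably lossless and recovery must be *exact*: shot and read noise
off, deterministic amplitudes (with the default 20% CV, a 3.5-σ dim
cell renders at ~18 gray levels and is undetectable by any threshold
that also rejects blank noise — amplitude scatter is part of the noise
being switched off), 20 µm minimum cell separation (no merged blobs)
and a 10 µm border margin (no clipped blobs). Counts and positions
remain random.

## The counting pipeline

Per frame, in order:

1. **Rolling-ball background subtraction.** The background estimate is
   the grayscale opening of the intensity surface by a ball
   (spherical-cap) structuring element; the output is the input minus
   that estimate. This is the idealized form of the classic
   shrink-and-roll plugin algorithm: deterministic, and exactly
   testable against a per-pixel brute-force oracle. Openings are
   computed by minimum/maximum reductions over shifted views of the
   padded frame (~3× faster than generic grayscale morphology at these
   kernel sizes, bit-identical results). Edge pixels use the window
   clipped to the frame. Default radius 50 px at full resolution,
   rescaled with the pixel pitch (12 px on the test grid): large
   against a 4–5 px cell core, small against the vignette scale.
2. **Bernsen local threshold.** With local max M and min m over a disk
   window (radius 15 px full-res / 4 px test grid): where
   M − m ≥ contrast the pixel is foreground iff its value ≥ (M+m)/2;
   low-contrast windows are assigned wholly to one class by comparing
   (M+m)/2 with midgray 128 — on background-subtracted frames this
   sends all blank regions to background.
3. **Particle detection.** 8-connected components, area-gated to the
   4–20 µm cell-diameter bracket (3–82 px on the test grid), unweighted
   centroids, mean intensity from the corrected frame.
4. **Colocalization.** Pixel-wise AND of the two channel masks,
   re-detected with the same minimum area, so a grazing overlap does
   not count. On binary masks AND, MIN and MULTIPLY coincide. An
   event counts as a CD4⁺ T-cell only here — CD4-dim monocytes lack
   CD3 and are excluded by construction.

### Choice of the contrast parameter

No standard parameter values exist for imagery like this, so the
operating point was set from the two error populations of the image
model, measured directly: windowed max−min on blank shot-noise background (~20 gray
mean) reaches 38–40 only in rare two-tail events (~2.5·10⁻³/frame at
the test scale: a high spike and a dark pixel sharing one window),
while windows containing a cell blob sit at ≥ ~48 even in the dim CD3
channel. The default contrast 40 yields a dim-cell miss rate of ~3%
(recovery ratio 0.966 ± 0.013 across seeds) and a per-channel false-
particle rate small against ~12 true cells/frame. The plugin's stock
contrast of 15 lies *inside* the blank-noise distribution and floods
empty frames with false particles at this noise level. Raising
contrast further (42+) empties blank frames entirely but pushes the
recovery bias toward −5%. Per-channel false particles almost never
survive colocalization: the two channels' noise is independent, so a
blank scan counts zero cells.

The minimum area of 3 px (4 µm disk) is load-bearing: cell cores at
this grid are often exactly 3–4 px, and raising the gate to 4 px loses
~13% of cells.

## Comparison statistics

Differences are always `method_a − method_b` with `method_b` the
reference; sample SDs use n−1; limits of agreement are
bias ± 1.96·SD(d); the paired t-test is two-sided with n−1 degrees of
freedom; no multiple-testing correction is applied across strata
(agreement panels report raw p-values). Degenerate inputs
(zero-variance differences, zero reference values, n < 2) raise
errors rather than returning NaNs.

WHO strata are bracketed [0,200), [200,350], (350,500], (500,∞) — the
published stratum labels overlap at 350 and 500, and boundary values
are assigned to the lower-count stratum; ART eligibility is strictly
< 350 cells/µL, independent of the stratum label.

## Validation experiment sizes

The recovery experiments use the 320 × 240 grid and the following
sizes, chosen to give each assertion a ≥3σ margin under its own
sampling variability: exact recovery on 100 frame pairs; noisy
recovery on one 100-pair scan (±10% check) plus 50 seeds × 30 pairs
(mean-error check, expected bias −3%); under-fill on 150 pairs per
fill fraction {0.25, 0.5, 0.75, 1} under exact-recovery populations
with full camera noise, slope fitted through the origin (an empty
channel yields zero counts); operator oracles on 100 random ≤ 32 × 32
frames; statistics calibration at n = 10⁴ (parameter recovery) and
2000 × 30 (type-I error).

## Known limitations

- Touching cells are not split (no watershed); at 800 cells/µL the
  merge probability is ~1% per cell and appears as part of the −3%
  recovery bias. Densities several-fold higher would need splitting.
- The rolling-ball background estimate rides the lower envelope of the
  noise, leaving a ~10-gray residual pedestal under blobs; counting is
  unaffected, but intensity measurements should subtract the frame
  median (as the brightness-ratio test does).
- Saturation is only warned about, not modeled away: amplitudes plus
  background above 255 clip.
- Frame-to-frame independence is assumed; the arc-per-step overlap
  check flags plans that would double-count, but no deduplication is
  attempted.
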