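# helicount

Absolute CD4+ T-cell counting for helical-minichannel fluorescence scans.

## The problem

Monitoring HIV/AIDS in resource-limited settings requires the absolute
CD4+ T-lymphocyte concentration in blood (WHO guidance triggers
antiretroviral therapy below 350 cells/µL), but flow cytometry is
expensive and complex. A low-cost alternative images stained blood held
in a helical minichannel — a thread-like channel of known cross-section
(600 µm × 100 µm) wound around a rotating cylindrical cartridge. Each
camera trigger captures one 0.6 × 0.49 mm field of view per fluorescence
channel, so a single image interrogates a known volume:

    V_frame = 0.6 mm × 0.49 mm × 0.1 mm = 0.0294 µL

and the absolute concentration is simply a total count over a total
volume,

    C = N_cells / (n_frames · V_frame)   [cells/µL].

`helicount` implements the full computational side of such an
instrument:

- **geometry** — channel/cartridge geometry, frame and scan volumes,
  helix arc length and capacity, frame-overlap checks;
- **photometry** — SNR = signal/background, the Airy radius
  `1.22·λ·F/#`, and optical-train power bookkeeping;
- **synthgen** — a synthetic paired-channel scan generator with
  per-cell ground truth (Poisson cell counts in the frame volume,
  Gaussian blobs, vignetting, shot/read noise, under-filled channels);
- **imgproc** — the per-frame counting pipeline: rolling-ball
  background subtraction (grayscale opening by a ball structuring
  element), Bernsen local thresholding, connected-component particle
  detection with an area gate;
- **quantify** — CD4/CD3 colocalization (mask AND + re-detection),
  concentration estimation, WHO clinical strata;
- **methodcomp** — Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD of paired differences), paired t-test, Pearson
  correlation, percent difference, replicate-SD ratio.

Cells are counted as CD4+ T-cells only when a particle appears at the
same position in both the CD4 and the CD3 (pan-T-cell) channel, which
excludes CD4-dim monocytes.

## Worked example

Simulate a scan with known ground truth, then count it:

```sh
helicount simulate --seed 7 --out scan/ --config examples/small.yaml
helicount count --cd4 scan/scan_cd4.tif --cd3 scan/scan_cd3.tif \
    --config examples/small.yaml --out report.json
```

or from Python:

```python
import helicount as hc

plan = hc.AcquisitionPlan(n_frame_pairs=100).downscaled(4)  # 320x240 grid
ds = hc.generate_scan(seed=0, plan=plan)     # 800 CD3/µL, half CD4+
res = hc.run_scan(ds)
print(ds.truth_cd4_count(), res.n_colocalized, round(res.concentration, 1))
print(hc.who_group(res.concentration))
```

prints

```
1188 1150 391.2
WhoGroup(group='350–500', art_eligible=False)
```

— 1188 CD4+ cells were simulated across 100 frame pairs (2.94 µL), the
pipeline recovered 1150 of them as colocalized particles, and the
resulting 391.2 cells/µL (truth: 400) falls in the 350–500 WHO stratum,
above the ART-initiation threshold. Under noise-free well-separated
conditions (`hc.exact_recovery_conditions()`) the recovery is exact.

Compare two methods' counts on the same samples:

```sh
helicount compare counts.csv --out agreement.json
```

which reports bias, 95% limits of agreement, paired-t p-value and
Pearson r, overall and optionally per stratum.

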