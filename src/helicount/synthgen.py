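"""Synthetic paired-channel fluorescence scans with per-cell ground truth.

No raw scan data ship with the instrument, so the counting pipeline is
validated as parameter recovery on simulated scans.  The forward model
mirrors the acquisition: T-cells suspended uniformly in a known channel
volume, imaged in two fluorescence channels (CD3 stains every T-cell,
CD4 only the helper subset), each cell a dim diffraction-blurred blob on
an unevenly illuminated background, digitized to 8 bits with shot and
read noise.

Model in brief, per frame of volume ``V``:

* cell count ~ Poisson(``cd3_concentration`` · V); positions uniform;
* each cell is CD4-positive independently with probability
  ``cd4_fraction``; CD4-channel blobs are ``cd4_over_cd3_brightness``
  (default 2) times brighter than CD3-channel blobs;
* a blob is an anisotropic Gaussian with σ = ``cell_diameter`` / 4 so
  the visible spot roughly matches the cell footprint;
* pixel value = ``background_level`` · vignette + Σ blobs, then Poisson
  shot noise, additive Gaussian read noise, and clipping to 0–255.

An under-filled channel — a real failure mode that biases counts low —
is emulated by leaving the trailing ``1 − fill_fraction`` of frames
empty of cells.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionPlan, ChannelSpec, frame_volume

__all__ = [
    "PopulationSpec",
    "NoiseSpec",
    "exact_recovery_conditions",
    "GroundTruthRecord",
    "ScanDataset",
    "sample_cells",
    "render_frame",
    "generate_scan",
    "write_dataset",
    "load_scan",
]

CD4 = "CD4"
CD3 = "CD3"


@dataclass(frozen=True)
class PopulationSpec:
    """Cell population and staining brightness.

    Defaults put the CD4 count at 400 cells/µL (800 CD3+ T-cells/µL,
    half CD4-positive) — the clinically interesting neighbourhood of the
    350 cells/µL ART threshold.  Amplitudes (CD3 blobs 60 gray levels,
    CD4 blobs twice that, over background ~20) land the simulated SNR in
    the 2–4 range of the real low-light images; they are a declared
    stand-in, not measured values.

    ``min_separation_um``/``edge_margin_um`` are 0 by default (cells are
    dropped uniformly at random); set them to generate the well-separated
    layouts used for exact-recovery checks.
    """

    cd3_concentration: float = 800.0  # cells/µL
    cd4_fraction: float = 0.5
    cell_diameter_um: float = 8.0
    cd3_amplitude: float = 60.0  # gray levels above background
    cd4_over_cd3_brightness: float = 2.0
    amplitude_cv: float = 0.2
    min_separation_um: float = 0.0
    edge_margin_um: float = 0.0

    def __post_init__(self) -> None:
        if self.cd3_concentration < 0:
            raise ValueError("cd3_concentration must be >= 0")
        if not (0 <= self.cd4_fraction <= 1):
            raise ValueError("cd4_fraction must be in [0, 1]")
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be > 0")
        if self.cd3_amplitude < 0 or self.cd4_over_cd3_brightness < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Background and detector noise of the simulated camera.

    ``vignette_strength`` is the fractional radial falloff of the
    illumination at the frame corners (the uneven background that
    rolling-ball correction removes).  ``fill_fraction`` < 1 models a
    channel whose trailing portion holds no sample.
    """

    background_level: float = 20.0
    vignette_strength: float = 0.3
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    fill_fraction: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not (0 <= self.vignette_strength < 1):
            raise ValueError("vignette_strength must be in [0, 1)")
        if not (0 < self.fill_fraction <= 1):
            raise ValueError("fill_fraction must be in (0, 1]")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit output is supported")

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0


@dataclass(frozen=True)
class GroundTruthRecord:
    """One simulated cell: where it is, its subset, and its brightness."""

    frame_index: int
    x_um: float
    y_um: float
    is_cd4_positive: bool
    cd3_amp: float
    cd4_amp: float


@dataclass
class ScanDataset:
    """Paired CD4/CD3 frame stacks plus (for synthetic data) the truth table."""

    cd4_frames: np.ndarray  # (n, pixels_y, pixels_x) uint8
    cd3_frames: np.ndarray
    plan: AcquisitionPlan
    channel: ChannelSpec
    truth: list[GroundTruthRecord] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cd4_frames.shape != self.cd3_frames.shape:
            raise ValueError("CD4 and CD3 stacks must have identical shapes")
        n, h, w = self.cd4_frames.shape
        if n != self.plan.n_frame_pairs:
            raise ValueError(
                f"stack length {n} != plan.n_frame_pairs {self.plan.n_frame_pairs}"
            )
        if (h, w) != (self.plan.pixels_y, self.plan.pixels_x):
            raise ValueError("frame pixel dimensions do not match the plan")

    @property
    def n_frame_pairs(self) -> int:
        return self.cd4_frames.shape[0]

    def truth_cd4_count(self) -> int:
        if self.truth is None:
            raise ValueError("dataset carries no ground truth")
        return sum(r.is_cd4_positive for r in self.truth)


def exact_recovery_conditions(
    cd3_concentration: float = 800.0,
    cd4_fraction: float = 0.5,
    **noise_overrides,
) -> tuple[PopulationSpec, NoiseSpec]:
    """Population/noise specs under which counting is provably lossless.

    "Noise-free, well-separated": every stochastic nuisance of the image
    model is switched off — shot noise, read noise and the per-cell
    amplitude scatter (a dim-tail cell three CVs below the mean is
    undetectable by *any* threshold that rejects blank noise, so
    deterministic amplitudes are part of the noise-free condition) — and
    cells keep a 20 µm minimum separation and a 10 µm border margin so
    no two blobs merge and none is clipped.  Cell counts and positions
    stay random: that sampling structure is what the volumetric
    estimator is built on.  Used by the exact parameter-recovery tests.
    """
    pop = PopulationSpec(
        cd3_concentration=cd3_concentration,
        cd4_fraction=cd4_fraction,
        amplitude_cv=0.0,
        min_separation_um=20.0,
        edge_margin_um=10.0,
    )
    noise = NoiseSpec(shot_noise=False, read_noise_sd=0.0, **noise_overrides)
    return pop, noise


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    plan: AcquisitionPlan,
    pop: PopulationSpec,
) -> np.ndarray:
    """Uniform cell positions, optionally with a margin and a minimum
    pairwise separation (dart-throwing rejection)."""
    lo_x, hi_x = pop.edge_margin_um, plan.frame_width_um - pop.edge_margin_um
    lo_y, hi_y = pop.edge_margin_um, plan.frame_height_um - pop.edge_margin_um
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("edge_margin_um leaves no room for cells")
    if pop.min_separation_um <= 0:
        xs = rng.uniform(lo_x, hi_x, n)
        ys = rng.uniform(lo_y, hi_y, n)
        return np.column_stack([xs, ys])
    placed: list[tuple[float, float]] = []
    min_d2 = pop.min_separation_um**2
    attempts = 0
    while len(placed) < n:
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_d2 for px, py in placed):
            placed.append((x, y))
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError(
                "cannot place cells at the requested density and separation"
            )
    return np.array(placed).reshape(-1, 2)


def sample_cells(
    seed: int | np.random.SeedSequence,
    pop: PopulationSpec,
    plan: AcquisitionPlan,
    channel: ChannelSpec,
) -> list[GroundTruthRecord]:
    """Draw the ground-truth cell table for a whole scan.

    Per frame the cell count is Poisson with mean concentration × frame
    volume; positions are uniform; CD4 positivity is an independent
    Bernoulli(``cd4_fraction``) mark.  Per-cell blob amplitudes scatter
    around the channel means with coefficient of variation
    ``amplitude_cv`` (truncated at zero).
    """
    rng = np.random.default_rng(seed)
    mean_per_frame = pop.cd3_concentration * frame_volume(plan, channel)
    records: list[GroundTruthRecord] = []
    for fi in range(plan.n_frame_pairs):
        n = rng.poisson(mean_per_frame)
        pos = _sample_positions(rng, n, plan, pop)
        is_cd4 = rng.random(n) < pop.cd4_fraction
        cd3_amp = np.maximum(
            0.0, pop.cd3_amplitude * (1 + pop.amplitude_cv * rng.standard_normal(n))
        )
        cd4_base = pop.cd4_over_cd3_brightness * pop.cd3_amplitude
        cd4_amp = np.where(
            is_cd4,
            np.maximum(
                0.0, cd4_base * (1 + pop.amplitude_cv * rng.standard_normal(n))
            ),
            0.0,
        )
        for i in range(n):
            records.append(
                GroundTruthRecord(
                    frame_index=fi,
                    x_um=float(pos[i, 0]),
                    y_um=float(pos[i, 1]),
                    is_cd4_positive=bool(is_cd4[i]),
                    cd3_amp=float(cd3_amp[i]),
                    cd4_amp=float(cd4_amp[i]),
                )
            )
    return records


def _vignette(plan: AcquisitionPlan, strength: float) -> np.ndarray:
    """Radial quadratic illumination falloff, 1 at centre, 1-strength at corners."""
    if strength == 0:
        return np.ones((plan.pixels_y, plan.pixels_x))
    ys = (np.arange(plan.pixels_y) + 0.5) * plan.pixel_scale_y_um
    xs = (np.arange(plan.pixels_x) + 0.5) * plan.pixel_scale_x_um
    cy, cx = plan.frame_height_um / 2, plan.frame_width_um / 2
    r2 = ((ys - cy) ** 2)[:, None] + ((xs - cx) ** 2)[None, :]
    r2_max = cy**2 + cx**2
    return 1.0 - strength * r2 / r2_max


def render_frame(
    records: Sequence[GroundTruthRecord],
    channel_id: str,
    plan: AcquisitionPlan,
    pop: PopulationSpec,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence | None = 0,
) -> np.ndarray:
    """Render one 8-bit frame of one fluorescence channel.

    ``records`` must all belong to the same frame.  Each cell contributes
    an anisotropic Gaussian blob (σ = cell_diameter/4, converted to the
    per-axis pixel scale) with its per-channel amplitude; CD3-negative
    amplitude entries contribute nothing in the CD4 channel.  Shot noise
    (Poisson of the noiseless image), read noise and 8-bit quantization
    follow in that order.
    """
    if channel_id not in (CD4, CD3):
        raise ValueError(f"channel_id must be {CD4!r} or {CD3!r}")
    frames = {r.frame_index for r in records}
    if len(frames) > 1:
        raise ValueError(f"records span several frames: {sorted(frames)}")
    rng = np.random.default_rng(seed)
    h, w = plan.pixels_y, plan.pixels_x
    img = noise.background_level * _vignette(plan, noise.vignette_strength)

    sx = (pop.cell_diameter_um / 4.0) / plan.pixel_scale_x_um
    sy = (pop.cell_diameter_um / 4.0) / plan.pixel_scale_y_um
    half_x = int(np.ceil(5 * sx))
    half_y = int(np.ceil(5 * sy))
    for r in records:
        amp = r.cd4_amp if channel_id == CD4 else r.cd3_amp
        if amp <= 0:
            continue
        # pixel-centre coordinates of the cell
        px = r.x_um / plan.pixel_scale_x_um - 0.5
        py = r.y_um / plan.pixel_scale_y_um - 0.5
        x0, x1 = max(0, int(px) - half_x), min(w, int(px) + half_x + 2)
        y0, y1 = max(0, int(py) - half_y), min(h, int(py) + half_y + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - px
        ys = np.arange(y0, y1) - py
        img[y0:y1, x0:x1] += amp * np.exp(
            -0.5 * ((ys[:, None] / sy) ** 2 + (xs[None, :] / sx) ** 2)
        )

    peak = noise.background_level + max(
        (r.cd4_amp if channel_id == CD4 else r.cd3_amp for r in records), default=0.0
    )
    if peak > 255 or img.max() > 255:
        warnings.warn(
            f"blob amplitude over background reaches {max(peak, img.max()):.1f} "
            "gray levels; 8-bit output will saturate",
            stacklevel=2,
        )
    if noise.shot_noise:
        img = rng.poisson(img).astype(float)
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scan(
    seed: int,
    pop: PopulationSpec | None = None,
    noise: NoiseSpec | None = None,
    plan: AcquisitionPlan | None = None,
    channel: ChannelSpec | None = None,
) -> ScanDataset:
    """Generate a complete paired-channel scan with ground truth.

    Both channels are rendered from one shared truth table, so every
    CD4-channel blob coincides spatially with a CD3-channel blob.  Frames
    with index ≥ ``fill_fraction × n_frame_pairs`` are left empty of
    cells, emulating an under-filled channel; the truth table only lists
    cells actually present.  Deterministic in ``seed``.
    """
    pop = pop or PopulationSpec()
    noise = noise or NoiseSpec()
    plan = plan or AcquisitionPlan()
    channel = channel or ChannelSpec()

    ss = np.random.SeedSequence(seed)
    truth_ss, render_ss = ss.spawn(2)
    records = sample_cells(truth_ss, pop, plan, channel)
    n_filled_limit = noise.fill_fraction * plan.n_frame_pairs
    records = [r for r in records if r.frame_index < n_filled_limit]

    by_frame: dict[int, list[GroundTruthRecord]] = {}
    for r in records:
        by_frame.setdefault(r.frame_index, []).append(r)

    frame_seeds = render_ss.spawn(2 * plan.n_frame_pairs)
    cd4 = np.empty((plan.n_frame_pairs, plan.pixels_y, plan.pixels_x), np.uint8)
    cd3 = np.empty_like(cd4)
    for fi in range(plan.n_frame_pairs):
        recs = by_frame.get(fi, [])
        cd4[fi] = render_frame(recs, CD4, plan, pop, noise, frame_seeds[2 * fi])
        cd3[fi] = render_frame(recs, CD3, plan, pop, noise, frame_seeds[2 * fi + 1])
    return ScanDataset(
        cd4_frames=cd4, cd3_frames=cd3, plan=plan, channel=channel,
        truth=records, seed=seed,
    )


def _truth_frame(truth: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": r.frame_index,
                "x_um": r.x_um,
                "y_um": r.y_um,
                "is_cd4": int(r.is_cd4_positive),
                "cd3_amp": r.cd3_amp,
                "cd4_amp": r.cd4_amp,
            }
            for r in truth
        ],
        columns=["frame", "x_um", "y_um", "is_cd4", "cd3_amp", "cd4_amp"],
    )


def write_dataset(
    ds: ScanDataset,
    out_dir: str | Path,
    prefix: str = "scan",
    pop: PopulationSpec | None = None,
    noise: NoiseSpec | None = None,
) -> dict[str, Path]:
    """Write TIFF stacks, truth CSV and a JSON sidecar; returns the paths.

    Stacks are plain multi-page 8-bit grayscale TIFFs; channel identity
    is carried by the filename suffix and the sidecar, not TIFF tags.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cd4": out / f"{prefix}_cd4.tif",
        "cd3": out / f"{prefix}_cd3.tif",
        "sidecar": out / f"{prefix}_sidecar.json",
    }
    tifffile.imwrite(paths["cd4"], ds.cd4_frames, photometric="minisblack")
    tifffile.imwrite(paths["cd3"], ds.cd3_frames, photometric="minisblack")
    if ds.truth is not None:
        paths["truth"] = out / f"{prefix}_truth.csv"
        _truth_frame(ds.truth).to_csv(paths["truth"], index=False)
    sidecar = {
        "seed": ds.seed,
        "plan": dataclasses.asdict(ds.plan),
        "channel": dataclasses.asdict(ds.channel),
        "population": dataclasses.asdict(pop) if pop else None,
        "noise": dataclasses.asdict(noise) if noise else None,
        "n_truth_cells": len(ds.truth) if ds.truth is not None else None,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def load_scan(
    cd4_path: str | Path,
    cd3_path: str | Path,
    plan: AcquisitionPlan | None = None,
    channel: ChannelSpec | None = None,
) -> ScanDataset:
    """Load paired multi-page TIFF stacks into a :class:`ScanDataset`.

    If no plan is given, one is inferred from the stack dimensions with
    the default physical field of view.
    """
    cd4 = tifffile.imread(cd4_path)
    cd3 = tifffile.imread(cd3_path)
    if cd4.ndim == 2:
        cd4 = cd4[None]
    if cd3.ndim == 2:
        cd3 = cd3[None]
    if cd4.shape != cd3.shape:
        raise ValueError(
            f"stack shapes differ: CD4 {cd4.shape} vs CD3 {cd3.shape}"
        )
    if plan is None:
        n, h, w = cd4.shape
        plan = AcquisitionPlan(n_frame_pairs=n, pixels_x=w, pixels_y=h)
    return ScanDataset(
        cd4_frames=cd4.astype(np.uint8),
        cd3_frames=cd3.astype(np.uint8),
        plan=plan,
        channel=channel or ChannelSpec(),
        truth=None,
    )
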