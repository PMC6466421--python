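"""Colocalization counting, absolute concentration, WHO stratification.

CD4 is also expressed (dimly) by monocytes, so a particle only counts as
a CD4+ T-cell if it appears at the same position in both the CD4 and the
CD3 (pan-T-cell) channel.  Colocalization is the pixel-wise AND of the
two binary masks followed by re-detection with the same minimum-area
filter — on binary masks AND, MIN and MULTIPLY coincide, so this matches
any of the usual image-calculator idioms.

The absolute concentration is the total colocalized count over the total
interrogated volume (counts are summed over frames *before* dividing —
the estimator is a ratio of totals, not a mean of per-frame ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import frame_volume
from .imgproc import BinaryMask, PipelineParams, find_particles, process_frame
from .synthgen import ScanDataset

__all__ = [
    "ScanCountResult",
    "WhoGroup",
    "coloc_mask",
    "count_colocalized",
    "match_centroids",
    "estimate_concentration",
    "who_group",
    "run_scan",
]

ART_THRESHOLD = 350.0  # cells/µL; WHO treatment-initiation threshold


@dataclass(frozen=True)
class ScanCountResult:
    """Totals of one analyzed scan."""

    n_colocalized: int
    n_cd4_channel: int
    n_cd3_channel: int
    n_frames_used: int
    sampled_volume_ul: float
    concentration: float  # CD4+ T-cells per µL
    per_frame_colocalized: tuple[int, ...] = field(default=())


class WhoGroup(NamedTuple):
    """Clinical CD4 stratum and antiretroviral-therapy eligibility."""

    group: str
    art_eligible: bool


def coloc_mask(cd4_mask: BinaryMask, cd3_mask: BinaryMask) -> BinaryMask:
    """Pixel-wise AND of the two channel masks."""
    a = np.asarray(cd4_mask, dtype=bool)
    b = np.asarray(cd3_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    return a & b


def count_colocalized(
    cd4_mask: BinaryMask,
    cd3_mask: BinaryMask,
    params: PipelineParams | None = None,
) -> int:
    """Number of particles present in both channels.

    The intersection mask is re-analyzed with the same area filter, so a
    grazing overlap smaller than ``min_area`` does not count.
    """
    particles = find_particles(coloc_mask(cd4_mask, cd3_mask), None, params)
    return len(particles)


def match_centroids(
    cd4_particles, cd3_particles, max_distance_px: float
) -> int:
    """Alternative colocalization: greedy nearest-centroid pairing.

    Each CD4-channel particle is matched to the nearest unmatched
    CD3-channel particle within ``max_distance_px``; the number of
    matches is the colocalized count.  Kept behind the ``coloc_method``
    flag of :func:`run_scan` — mask intersection is the default because
    it is what an image-calculator AND computes — but useful when the
    two channels are slightly misregistered.
    """
    available = list(cd3_particles)
    n_matched = 0
    for p in cd4_particles:
        best_i, best_d = -1, max_distance_px
        for i, q in enumerate(available):
            d = np.hypot(p.centroid_x - q.centroid_x, p.centroid_y - q.centroid_y)
            if d <= best_d:
                best_i, best_d = i, d
        if best_i >= 0:
            available.pop(best_i)
            n_matched += 1
    return n_matched


def estimate_concentration(n_cells: int, n_frames: int, frame_vol_ul: float) -> float:
    """Absolute concentration: total count over total volume, cells/µL."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_vol_ul <= 0:
        raise ValueError("frame volume must be > 0")
    return n_cells / (n_frames * frame_vol_ul)


def who_group(cd4_concentration: float) -> WhoGroup:
    """WHO clinical stratum of a CD4 count, plus the ART-eligibility flag.

    Strata: [0, 200), [200, 350], (350, 500], (500, ∞).  The published
    stratum labels overlap at 350 and 500; the bracketing here places
    each boundary value in the lower-count stratum.  ART eligibility is
    strictly below 350 cells/µL.
    """
    if cd4_concentration < 0:
        raise ValueError("concentration must be >= 0")
    if cd4_concentration < 200:
        group = "<200"
    elif cd4_concentration <= 350:
        group = "200–350"
    elif cd4_concentration <= 500:
        group = "350–500"
    else:
        group = ">500"
    return WhoGroup(group=group, art_eligible=cd4_concentration < ART_THRESHOLD)


def run_scan(
    dataset: ScanDataset,
    params: PipelineParams | None = None,
    coloc_method: str = "mask",
    centroid_tolerance_px: float = 3.0,
) -> ScanCountResult:
    """Analyze a paired-channel scan end to end.

    Each frame pair is processed independently (background subtraction,
    Bernsen threshold, particle detection per channel, colocalization
    count); counts are summed over frames and divided by the total
    sampled volume.  When no parameters are given they are rescaled to
    the dataset's pixel grid via :meth:`PipelineParams.for_plan`.

    ``coloc_method`` selects mask intersection (``"mask"``, default) or
    greedy centroid matching within ``centroid_tolerance_px``
    (``"centroid"``).
    """
    if coloc_method not in ("mask", "centroid"):
        raise ValueError(f"unknown coloc_method {coloc_method!r}")
    n = dataset.n_frame_pairs
    if n < 1:
        raise ValueError("dataset contains no frame pairs")
    params = params or PipelineParams.for_plan(dataset.plan)

    n_cd4 = n_cd3 = 0
    per_frame: list[int] = []
    for fi in range(n):
        cd4_m, cd4_p = process_frame(dataset.cd4_frames[fi], params, frame_index=fi)
        cd3_m, cd3_p = process_frame(dataset.cd3_frames[fi], params, frame_index=fi)
        n_cd4 += len(cd4_p)
        n_cd3 += len(cd3_p)
        if coloc_method == "mask":
            per_frame.append(count_colocalized(cd4_m, cd3_m, params))
        else:
            per_frame.append(match_centroids(cd4_p, cd3_p, centroid_tolerance_px))

    n_coloc = int(sum(per_frame))
    fv = frame_volume(dataset.plan, dataset.channel)
    return ScanCountResult(
        n_colocalized=n_coloc,
        n_cd4_channel=n_cd4,
        n_cd3_channel=n_cd3,
        n_frames_used=n,
        sampled_volume_ul=n * fv,
        concentration=estimate_concentration(n_coloc, n, fv),
        per_frame_colocalized=tuple(per_frame),
    )
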