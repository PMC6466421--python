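"""Independent brute-force reference implementations for oracle tests.

Direct per-pixel evaluation of the operator definitions: for every pixel
the disk window is materialized and reduced, with out-of-frame and
out-of-disk positions excluded via NaN.  Deliberately shares no code
with ``helicount.imgproc``.
"""

import numpy as np


def _cap_heights(radius: int) -> np.ndarray:
    """Spherical-cap heights on the disk footprint, NaN outside the disk."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = (yy**2 + xx**2).astype(float)
    s = np.sqrt(np.maximum(radius**2 - d2, 0.0)) - radius
    s[d2 > radius**2] = np.nan
    return s


def brute_rolling_ball_subtract(frame: np.ndarray, radius: int) -> np.ndarray:
    """frame − grayscale opening by a ball element, edge-clipped windows."""
    f = np.asarray(frame, dtype=float)
    h, w = f.shape
    s = _cap_heights(radius)
    pad = np.pad(f, radius, constant_values=np.nan)

    eroded = np.empty_like(f)
    for y in range(h):
        for x in range(w):
            win = pad[y : y + 2 * radius + 1, x : x + 2 * radius + 1]
            eroded[y, x] = np.nanmin(win - s)

    pad_e = np.pad(eroded, radius, constant_values=np.nan)
    opened = np.empty_like(f)
    for y in range(h):
        for x in range(w):
            win = pad_e[y : y + 2 * radius + 1, x : x + 2 * radius + 1]
            opened[y, x] = np.nanmax(win + s)

    return np.rint(f - opened).astype(np.uint8)


def brute_bernsen(
    frame: np.ndarray, radius: int, contrast: float, midgray: float
) -> np.ndarray:
    """Per-pixel Bernsen rule from windowed min/max over the clipped disk."""
    f = np.asarray(frame, dtype=float)
    h, w = f.shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy**2 + xx**2 <= radius**2).astype(float)
    disk[disk == 0] = np.nan
    pad = np.pad(f, radius, constant_values=np.nan)

    out = np.empty((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            win = pad[y : y + 2 * radius + 1, x : x + 2 * radius + 1] * disk
            local_max = np.nanmax(win)
            local_min = np.nanmin(win)
            mid = (local_max + local_min) / 2.0
            if local_max - local_min >= contrast:
                out[y, x] = f[y, x] >= mid
            else:
                out[y, x] = mid >= midgray
    return out
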