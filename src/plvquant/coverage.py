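"""Smooth-muscle coverage quantification on 2D whole-mount vessels.

The coverage readout follows a fixed-threshold protocol: the median of
the per-vessel median signal intensities of the control (WT) vessels is
halved and applied as one set threshold to every vessel; coverage is the
area fraction of vessel-mask pixels at or above that threshold. A
constant square window (default 500 x 500 um) swept over the vessel
locates the region of minimum mean masked intensity for the minimum-ROI
measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoverageRecord",
    "derive_wt_threshold",
    "coverage_fraction",
    "intensity_stats",
    "min_roi_scan",
]


@dataclass
class CoverageRecord:
    """Per-vessel coverage summary row."""

    vessel_id: str
    group: str
    limb_id: str
    threshold_au: float
    coverage_pct: float
    mean_au: float
    median_au: float
    minroi_center: tuple[int, int]
    minroi_coverage_pct: float
    minroi_mean_au: float
    minroi_median_au: float


def derive_wt_threshold(wt_vessel_medians: list[float] | np.ndarray) -> float:
    """Half the median of the control vessels' per-vessel medians.

    The median of an even count is the midpoint of the two central
    values.
    """
    med = np.asarray(wt_vessel_medians, dtype=float)
    if med.size == 0:
        raise ValueError("no WT vessel medians provided")
    if (med < 0).any():
        raise ValueError("medians must be >= 0")
    return float(np.median(med)) / 2.0


def _mask_pixels(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if mask.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    if not mask.any():
        raise ValueError("vessel mask is empty")
    return channel[mask]


def coverage_fraction(
    channel: np.ndarray, mask: np.ndarray, threshold_au: float
) -> float:
    """Percent of mask pixels with intensity >= threshold.

    The comparison is inclusive of the threshold value, matching
    histogram-threshold area-fraction tools.
    """
    px = _mask_pixels(channel, mask)
    return 100.0 * float(np.count_nonzero(px >= threshold_au)) / px.size


def intensity_stats(channel: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and median over mask pixels."""
    px = _mask_pixels(channel, mask).astype(np.float64)
    return float(px.mean()), float(np.median(px))


def _window_bounds(center: int, size: int, extent: int) -> tuple[int, int]:
    """Half-open [lo, hi) of a size-px window centered on ``center``.

    The window spans center - (size-1)//2 .. center + size//2 and is
    clipped at the raster border.
    """
    lo = center - (size - 1) // 2
    hi = lo + size
    return max(lo, 0), min(hi, extent)


def _scan_min_window(
    channel: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    window_um: float,
) -> tuple[tuple[int, int], float, float, int]:
    """Locate the square window of minimum mean masked intensity.

    Every pixel is a candidate center (stride 1); the window is clipped
    at the raster border and scored on mask-and-window pixels only.
    Ties break to the smallest (row, col) center.

    Returns
    -------
    center : (row, col) of the winning window center
    mean_au, median_au : intensity stats on mask-and-window pixels
    window_px : realized window side in pixels
    """
    if mask.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    if not mask.any():
        raise ValueError("mask is empty: no candidate window covers the vessel")
    w = int(round(window_um / pixel_size_um))
    if w < 3:
        raise ValueError(f"window {window_um} um is {w} px; need >= 3 px")

    h, wid = channel.shape
    vals = channel.astype(np.int64)
    masked = np.where(mask, vals, 0)
    # exact integer summed-area tables -> bit-equal means for equal windows
    s = np.zeros((h + 1, wid + 1), dtype=np.int64)
    c = np.zeros((h + 1, wid + 1), dtype=np.int64)
    np.cumsum(np.cumsum(masked, axis=0), axis=1, out=s[1:, 1:])
    np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1, out=c[1:, 1:])

    lo_off = (w - 1) // 2
    hi_off = w - lo_off
    rows = np.arange(h)
    cols = np.arange(wid)
    r0 = np.clip(rows - lo_off, 0, h)
    r1 = np.clip(rows + hi_off, 0, h)
    c0 = np.clip(cols - lo_off, 0, wid)
    c1 = np.clip(cols + hi_off, 0, wid)

    def rect(tab: np.ndarray) -> np.ndarray:
        return (
            tab[np.ix_(r1, c1)]
            - tab[np.ix_(r0, c1)]
            - tab[np.ix_(r1, c0)]
            + tab[np.ix_(r0, c0)]
        )

    counts = rect(c)
    sums = rect(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.inf)
    best = means.min()
    if not np.isfinite(best):
        raise ValueError("mask-and-window intersection empty for all candidates")
    # lexicographic (row, col) tie-break: first flat index of the minimum
    flat = int(np.flatnonzero(means.ravel() == best)[0])
    center = (flat // wid, flat % wid)

    rr0, rr1 = _window_bounds(center[0], w, h)
    cc0, cc1 = _window_bounds(center[1], w, wid)
    sub = channel[rr0:rr1, cc0:cc1]
    submask = mask[rr0:rr1, cc0:cc1]
    px = sub[submask].astype(np.float64)
    return center, float(px.mean()), float(np.median(px)), w


def min_roi_scan(
    channel: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    threshold_au: float,
    window_um: float = 500.0,
) -> tuple[tuple[int, int], float, float, float]:
    """Minimum-signal ROI analysis with a constant square window.

    Finds the window of minimum mean masked intensity (see
    ``_scan_min_window``) and reports, on mask-and-window pixels only:
    (center, coverage_pct at ``threshold_au``, mean_au, median_au).
    """
    center, mean_au, median_au, w = _scan_min_window(
        channel, mask, pixel_size_um, window_um
    )
    r0, r1 = _window_bounds(center[0], w, channel.shape[0])
    c0, c1 = _window_bounds(center[1], w, channel.shape[1])
    win_mask = np.zeros_like(mask)
    win_mask[r0:r1, c0:c1] = True
    cov = coverage_fraction(channel, mask & win_mask, threshold_au)
    return center, cov, mean_au, median_au
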