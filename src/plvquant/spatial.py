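"""Centerline length, intensity-vs-distance profiling, and Sy.x.

The spatial-patterning statistic Sy.x is the standard deviation of
signal intensity about its fitted mean as a function of position along
the vessel. Fitting the constant model y-hat = y-bar leaves n - 1
residual degrees of freedom, so Sy.x reduces exactly to the sample
standard deviation of the sampled intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["IntensityProfile", "polyline_length", "sample_profile", "syx"]


@dataclass
class IntensityProfile:
    """Intensities sampled at monotone arc-length positions (um)."""

    arc_positions_um: np.ndarray
    intensities_au: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.arc_positions_um, dtype=float)
        y = np.asarray(self.intensities_au, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1D")
        if x.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if not (np.diff(x) > 0).all():
            raise ValueError("arc positions must be strictly increasing")
        self.arc_positions_um = x
        self.intensities_au = y

    @property
    def n(self) -> int:
        return self.arc_positions_um.size


def polyline_length(centerline: np.ndarray, pixel_size_um: float) -> float:
    """Arc length of an ordered (row, col) point list, in mm."""
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centerline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(seg.sum()) * pixel_size_um / 1000.0


def _arc_parametrize(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def sample_profile(
    channel: np.ndarray,
    centerline: np.ndarray,
    pixel_size_um: float,
    step_um: float | None = None,
) -> IntensityProfile:
    """Sample intensity at uniform arc-length steps along the centerline.

    Positions are spaced ``step_um`` apart (default: one pixel of arc
    length); intensity is bilinearly interpolated at each position.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centerline needs at least 2 points")
    h, w = channel.shape
    for i, (r, c) in enumerate(pts):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(
                f"centerline vertex {i} at (row={r}, col={c}) exits the "
                f"{h}x{w} image"
            )
    if step_um is None:
        step_um = pixel_size_um
    if step_um <= 0:
        raise ValueError("step_um must be > 0")

    arc_px = _arc_parametrize(pts)
    total_px = arc_px[-1]
    if total_px <= 0:
        raise ValueError("centerline has zero length")
    step_px = step_um / pixel_size_um
    pos_px = np.arange(0.0, total_px + 1e-9, step_px)
    rows = np.interp(pos_px, arc_px, pts[:, 0])
    cols = np.interp(pos_px, arc_px, pts[:, 1])
    vals = ndimage.map_coordinates(
        channel.astype(np.float64), np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return IntensityProfile(
        arc_positions_um=pos_px * pixel_size_um, intensities_au=vals
    )


def syx(profile: IntensityProfile) -> float:
    """SD of intensity about the fitted mean along the vessel.

    The constant model has one parameter, so
    Sy.x = sqrt(sum (y_i - y_bar)^2 / (n - 1)).
    """
    y = profile.intensities_au
    return float(np.std(y, ddof=1))
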