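"""Core containers shared across the pipeline.

Conventions: 2D arrays are indexed (row, col), 3D arrays (z, y, x);
physical positions are in micrometers, vessel lengths reported in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlanarImage:
    """Named-channel 2D intensity raster with physical pixel size.

    channels maps a role name (e.g. "asma", "hoechst") to a 2D uint16
    array; all channels share shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class VolumeImage:
    """Named-channel 3D raster with anisotropic voxel size.

    voxel_size_um is (x, y, z); arrays are (z, y, x). The default z step
    of 1.417 um matches the confocal acquisition the pipeline targets.
    """

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        x, y, z = self.voxel_size_um
        return (z, y, x)

    @property
    def voxel_volume_um3(self) -> float:
        x, y, z = self.voxel_size_um
        return x * y * z


@dataclass
class VesselROI:
    """One vessel: closed contour polygon, boolean mask, ordered centerline.

    contour and centerline are (N, 2) float arrays of (row, col) pixel
    coordinates; mask is a boolean raster aligned with the image.
    """

    contour: np.ndarray
    mask: np.ndarray
    centerline: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if not self.mask.any():
            raise ValueError("vessel mask is empty")


@dataclass
class NucleusObject:
    """One segmented nucleus with its intensity summaries."""

    label: int
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (x, y, z)
    hoechst_median_au: float
    brdu_median_au: float = 0.0
    brdu_positive: bool = False


@dataclass
class GroupSample:
    """A named experimental group's values with simulation provenance."""

    group: str
    values: np.ndarray
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    seed: int | None = None


@dataclass
class GroundTruth:
    """Ground truth emitted alongside a synthetic scene.

    2D scenes fill coverage/centerline fields, 3D scenes the nucleus
    fields; either may leave the other side None.
    """

    coverage_true_pct: float | None = None
    centerline: np.ndarray | None = None
    length_mm_true: float | None = None
    fg_label: np.ndarray | None = None  # boolean raster of foreground pixels
    nucleus_labels: np.ndarray | None = None  # int32 label volume
    inside_ids: list[int] = field(default_factory=list)
    distractor_ids: list[int] = field(default_factory=list)
    brdu_flags: dict[int, bool] = field(default_factory=dict)
    sheath_mask: np.ndarray | None = None
    turnover_true_pct_per_week: float | None = None
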