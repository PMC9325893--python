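"""File formats, configuration, blinding, and the end-to-end driver.

Formats: multi-page TIFF for images (2D as a (C, H, W) page series, 3D
as a channel-major (C, Z, Y, X) series), CSV for tables and cohorts,
JSON for ground truth and statistics, YAML for run configuration.
Coordinates are 0-based (row, col[, z]) pixel indices; physical
positions in um; vessel lengths in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import coverage as cov
from . import spatial, turnover
from .datatypes import GroundTruth, GroupSample, PlanarImage, VesselROI, VolumeImage
from .stats import kruskal_dunn, one_way_anova_tukey
from .synthgen import NucleiScene3D, VesselScene2D, gen_confocal3d, gen_vessel2d

__all__ = [
    "read_image",
    "save_planar",
    "save_volume",
    "save_ground_truth",
    "save_cohort_csv",
    "assign_blind_codes",
    "RunConfig",
    "run_pipeline",
]


def _promote(arr: np.ndarray) -> np.ndarray:
    """Promote 8-bit data into the 16-bit range (x257); pass 16-bit through."""
    if arr.dtype == np.uint8:
        return arr.astype(np.uint16) * 257
    if arr.dtype == np.uint16:
        return arr
    raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")


def read_image(
    path: str | Path,
    channel_names: list[str],
    pixel_size_um: float | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> PlanarImage | VolumeImage:
    """Read a multi-page TIFF into a named-channel image.

    A 3D (C, H, W) array becomes a PlanarImage, a 4D (C, Z, Y, X) array
    a VolumeImage; the leading axis must match ``channel_names``. 8-bit
    input is promoted to the 16-bit range (x257).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} channel pages but "
            f"{len(channel_names)} channel names {channel_names}"
        )
    arr = _promote(arr)
    channels = {name: arr[i] for i, name in enumerate(channel_names)}
    if arr.ndim == 3:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for 2D images")
        return PlanarImage(channels=channels, pixel_size_um=pixel_size_um)
    if arr.ndim == 4:
        if voxel_size_um is None:
            raise ValueError("voxel_size_um (x, y, z) required for stacks")
        return VolumeImage(channels=channels, voxel_size_um=voxel_size_um)
    raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def _ordered_channels(
    channels: dict[str, np.ndarray], order: list[str] | None
) -> tuple[list[str], np.ndarray]:
    names = order if order is not None else sorted(channels)
    return names, np.stack([channels[n] for n in names])


def save_planar(
    image: PlanarImage, path: str | Path, channel_order: list[str] | None = None
) -> list[str]:
    """Write one TIFF page per channel; returns the page order used."""
    names, arr = _ordered_channels(image.channels, channel_order)
    tifffile.imwrite(str(path), arr)
    return names


def save_volume(
    volume: VolumeImage, path: str | Path, channel_order: list[str] | None = None
) -> list[str]:
    """Write a channel-major (C, Z, Y, X) TIFF page series."""
    names, arr = _ordered_channels(volume.channels, channel_order)
    tifffile.imwrite(str(path), arr)
    return names


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth scalars and centerline as JSON (unit-suffixed keys)."""
    payload: dict[str, Any] = {}
    if truth.coverage_true_pct is not None:
        payload["coverage_true_pct"] = truth.coverage_true_pct
    if truth.length_mm_true is not None:
        payload["length_mm_true"] = truth.length_mm_true
    if truth.centerline is not None:
        payload["centerline_px"] = np.asarray(truth.centerline).tolist()
    if truth.turnover_true_pct_per_week is not None:
        payload["turnover_true_pct_per_week"] = truth.turnover_true_pct_per_week
    if truth.brdu_flags:
        payload["n_nuclei_true"] = len(truth.inside_ids)
        payload["n_brdu_true"] = int(sum(truth.brdu_flags.values()))
    Path(path).write_text(json.dumps(payload, indent=1))


def save_cohort_csv(groups: list[GroupSample], path: str | Path) -> None:
    rows = [
        {"group": g.group, "value": v, "seed": g.seed}
        for g in groups
        for v in g.values
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def assign_blind_codes(ids: list[str], seed: int) -> dict[str, int]:
    """Bijective map id -> random 4-digit code (1000-9999), seeded."""
    if len(ids) > 9000:
        raise ValueError("at most 9000 ids can receive distinct 4-digit codes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    codes = rng.choice(np.arange(1000, 10000), size=len(ids), replace=False)
    return {i: int(c) for i, c in zip(ids, codes)}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``vessels`` entries are dicts with id/group/limb plus either a
    ``scene`` block (synthetic generation) or ``path`` + ``contour`` +
    ``centerline`` files; ``stacks`` entries likewise with a ``scene``
    block or a TIFF ``path``. ``threshold`` is a number or the string
    "derive-from-WT" (half the median of the WT vessels' medians).
    """

    out_dir: str
    seed: int = 0
    pixel_size_um: float = 1.0
    voxel_size_um: tuple[float, float, float] = (0.8, 0.8, 1.417)
    window_um: float = 500.0
    weeks: float = 6.0
    seed_diameter_um: float = 3.5
    threshold: float | str = "derive-from-WT"
    wt_group: str = "WT"
    blind: bool = False
    channel_map: dict[str, str] = field(
        default_factory=lambda: {"asma": "asma", "hoechst": "hoechst", "brdu": "brdu"}
    )
    vessels: list[dict] = field(default_factory=list)
    stacks: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("physical sizes must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "voxel_size_um" in data:
            data["voxel_size_um"] = tuple(data["voxel_size_um"])
        return cls(**data)


def _load_polyline(path: str | Path) -> np.ndarray:
    """(row, col) polyline from CSV (columns row,col) or JSON list."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return np.asarray(json.loads(p.read_text()), dtype=float)
    df = pd.read_csv(p)
    return df[["row", "col"]].to_numpy(dtype=float)


def _roi_from_files(
    contour_path: str | Path, centerline_path: str | Path, shape: tuple[int, int]
) -> VesselROI:
    from skimage.draw import polygon

    contour = _load_polyline(contour_path)
    centerline = _load_polyline(centerline_path)
    rr, cc = polygon(contour[:, 0], contour[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return VesselROI(contour=contour, mask=mask, centerline=centerline)


def _vessel_inputs(
    entry: dict, config: RunConfig
) -> tuple[PlanarImage, VesselROI]:
    if "scene" in entry:
        scene = VesselScene2D(
            pixel_size_um=config.pixel_size_um, **entry["scene"]
        )
        image, roi, _ = gen_vessel2d(scene)
        return image, roi
    image = read_image(
        entry["path"],
        channel_names=entry.get("channels", ["asma"]),
        pixel_size_um=config.pixel_size_um,
    )
    roi = _roi_from_files(entry["contour"], entry["centerline"], image.shape)
    return image, roi


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the 2D coverage/spatial and 3D turnover analyses end to end.

    Emits per-vessel coverage + Sy.x + length CSV, per-stack turnover
    CSV, group-statistics JSON, and a run log with every derived
    threshold and seed. Identical config + seed reproduces identical
    outputs. Returns the tables in memory keyed by output name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    asma_role = config.channel_map.get("asma", "asma")

    limb_ids = sorted(
        {str(v.get("limb", v["id"])) for v in config.vessels}
        | {str(s.get("limb", s["id"])) for s in config.stacks}
    )
    codes = assign_blind_codes(limb_ids, config.seed) if config.blind else None
    if codes:
        pd.DataFrame(
            [{"limb_id": k, "code": v} for k, v in sorted(codes.items())]
        ).to_csv(out / "blind_key.csv", index=False)

    def limb_label(limb: str) -> str:
        return str(codes[limb]) if codes else limb

    # ---- 2D vessels -------------------------------------------------
    loaded: list[tuple[dict, PlanarImage, VesselROI]] = []
    for entry in config.vessels:
        image, roi = _vessel_inputs(entry, config)
        loaded.append((entry, image, roi))

    threshold_au = config.threshold
    if threshold_au == "derive-from-WT":
        wt_medians = [
            cov.intensity_stats(img.channels[asma_role], roi.mask)[1]
            for entry, img, roi in loaded
            if entry["group"] == config.wt_group
        ]
        if not wt_medians:
            raise ValueError(
                f"threshold is derive-from-WT but no vessels belong to "
                f"group {config.wt_group!r}"
            )
        threshold_au = cov.derive_wt_threshold(wt_medians)

    vessel_rows = []
    for entry, image, roi in loaded:
        chan = image.channels[asma_role]
        mean_au, median_au = cov.intensity_stats(chan, roi.mask)
        center, mr_cov, mr_mean, mr_median = cov.min_roi_scan(
            chan, roi.mask, image.pixel_size_um, threshold_au, config.window_um
        )
        profile = spatial.sample_profile(chan, roi.centerline, image.pixel_size_um)
        vessel_rows.append(
            {
                "vessel_id": str(entry["id"]),
                "group": entry["group"],
                "limb_id": limb_label(str(entry.get("limb", entry["id"]))),
                "threshold_au": threshold_au,
                "coverage_pct": cov.coverage_fraction(chan, roi.mask, threshold_au),
                "mean_au": mean_au,
                "median_au": median_au,
                "minroi_row": center[0],
                "minroi_col": center[1],
                "minroi_coverage_pct": mr_cov,
                "minroi_mean_au": mr_mean,
                "minroi_median_au": mr_median,
                "length_mm": spatial.polyline_length(
                    roi.centerline, image.pixel_size_um
                ),
                "syx_au": spatial.syx(profile),
                "profile_step_um": image.pixel_size_um,
            }
        )
    coverage_df = pd.DataFrame(vessel_rows)
    if len(coverage_df):
        coverage_df.to_csv(out / "coverage.csv", index=False)

    # ---- 3D stacks --------------------------------------------------
    stack_rows = []
    for entry in config.stacks:
        if "scene" in entry:
            scene = NucleiScene3D(
                voxel_size_um=config.voxel_size_um,
                weeks=config.weeks,
                **entry["scene"],
            )
            volume, _ = gen_confocal3d(scene)
        else:
            volume = read_image(
                entry["path"],
                channel_names=entry.get("channels", ["asma", "brdu", "hoechst"]),
                voxel_size_um=config.voxel_size_um,
            )
        result, _ = turnover.run_stack(
            volume, weeks=config.weeks, seed_diameter_um=config.seed_diameter_um
        )
        stack_rows.append(
            {
                "stack_id": str(entry["id"]),
                "group": entry["group"],
                "limb_id": limb_label(str(entry.get("limb", entry["id"]))),
                "n_total": result.n_total,
                "n_brdu": result.n_brdu,
                "weeks": result.weeks,
                "rate_pct_per_week": result.rate_pct_per_week,
            }
        )
    turnover_df = pd.DataFrame(stack_rows)
    if len(turnover_df):
        turnover_df.to_csv(out / "turnover.csv", index=False)

    # ---- group statistics ------------------------------------------
    stats_payload: dict[str, Any] = {}

    def groups_of(df: pd.DataFrame, column: str) -> list[GroupSample]:
        return [
            GroupSample(group=g, values=sub[column].to_numpy())
            for g, sub in df.groupby("group", observed=True)
            if len(sub) >= 2
        ]

    def testdict(result) -> dict[str, Any]:
        return {
            "test": result.test_name,
            "statistic": result.statistic,
            "p_value": result.p_value,
            "pairwise": [
                {"group_a": a, "group_b": b, "adjusted_p": p}
                for a, b, p in result.pairwise
            ],
        }

    if len(coverage_df) and coverage_df["group"].nunique() >= 2:
        for column, test in (
            ("coverage_pct", kruskal_dunn),
            ("syx_au", one_way_anova_tukey),
            ("length_mm", one_way_anova_tukey),
        ):
            gs = groups_of(coverage_df, column)
            if len(gs) >= 2:
                stats_payload[column] = testdict(test(gs))
    if len(turnover_df) and turnover_df["group"].nunique() >= 2:
        gs = groups_of(turnover_df.dropna(subset=["rate_pct_per_week"]),
                       "rate_pct_per_week")
        if len(gs) >= 2:
            stats_payload["rate_pct_per_week"] = testdict(one_way_anova_tukey(gs))
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=1))

    import skimage

    log = {
        "seed": config.seed,
        "threshold_au": threshold_au,
        "window_um": config.window_um,
        "seed_diameter_um": config.seed_diameter_um,
        "weeks": config.weeks,
        "pixel_size_um": config.pixel_size_um,
        "voxel_size_um": list(config.voxel_size_um),
        "blind": config.blind,
        "versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "skimage": skimage.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return {
        "coverage": coverage_df,
        "turnover": turnover_df,
        "stats": stats_payload,
        "threshold_au": threshold_au,
    }
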