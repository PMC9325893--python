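"""Synthetic vessel whole-mounts, confocal stacks, and cohorts with ground truth.

The generator emulates the three data modalities the pipeline quantifies:

* 2D whole-mount vessels (~5 mm long) with either a WT-like
  ``banded_heterogeneous`` muscle-coverage pattern (circumferential bands
  of strong signal separated by gaps, high along-length variance) or a
  disease-like ``uniform_dim`` pattern (spatially uniform speckle at a
  fraction of the foreground intensity, low along-length variance);
* 3D confocal stacks with ellipsoidal nuclei inside a smooth-muscle
  sheath, a labeled (BrdU+) subset, and distractor nuclei outside the
  sheath;
* cohort samples drawn from published group summary statistics
  (mean, SD, n), optionally truncated at zero for nonnegative quantities.

Every scene is generated from an integer seed and is bit-reproducible;
ground truth records exact pixel/voxel bookkeeping so downstream
measurements can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GroundTruth, GroupSample, PlanarImage, VesselROI, VolumeImage

__all__ = [
    "VesselScene2D",
    "NucleiScene3D",
    "SizingError",
    "DensityError",
    "gen_vessel2d",
    "gen_confocal3d",
    "gen_cohort",
]

SEED_DIAMETER_UM = 3.50


class SizingError(ValueError):
    """Requested geometry is too small to rasterize meaningfully."""


class DensityError(ValueError):
    """Requested nucleus density cannot honor the minimum separation."""


@dataclass
class VesselScene2D:
    """Parameters of one synthetic 2D whole-mount vessel.

    Defaults reflect a typical dissected popliteal lymphatic vessel:
    ~5 mm long, 100 um wide, imaged at 1 um/px, with foreground and
    background intensities (40000 / 2000 AU, noise SD 1500) separated
    widely enough that a half-median threshold cleanly splits the
    classes.
    """

    coverage_true: float = 0.85
    pattern: str = "banded_heterogeneous"
    length_mm: float = 5.0
    width_um: float = 100.0
    fg_intensity: float = 40000.0
    bg_intensity: float = 2000.0
    noise_sd: float = 1500.0
    pixel_size_um: float = 1.0
    dim_fraction: float = 0.45  # uniform_dim foreground = dim_fraction * fg
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_true <= 1.0:
            raise ValueError("coverage_true must be in [0, 1]")
        if not self.fg_intensity > self.bg_intensity >= 0:
            raise ValueError("require fg_intensity > bg_intensity >= 0")
        if self.length_mm <= 0 or self.width_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("length, width, and pixel size must be > 0")
        if self.pattern not in ("banded_heterogeneous", "uniform_dim"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _banded_columns(n_cols: int, target: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean per-column foreground with band/gap run structure.

    Runs alternate foreground bands (~mean 150 um at 1 um/px) and gaps
    sized so the duty cycle approximates the target, then single columns
    are flipped at random to land exactly on ``target`` foreground
    columns.
    """
    cov = target / n_cols if n_cols else 0.0
    fg = np.zeros(n_cols, dtype=bool)
    if target == 0:
        return fg
    if target == n_cols:
        return np.ones(n_cols, dtype=bool)
    mean_band = 150.0
    mean_gap = max(mean_band * (1.0 - cov) / max(cov, 1e-9), 1.0)
    pos = 0
    state = rng.random() < cov
    while pos < n_cols:
        mean_len = mean_band if state else mean_gap
        run = max(1, int(round(rng.exponential(mean_len))))
        if state:
            fg[pos : pos + run] = True
        pos += run
        state = not state
    # exact bookkeeping: flip random columns toward the target count
    have = int(fg.sum())
    if have > target:
        idx = rng.choice(np.flatnonzero(fg), size=have - target, replace=False)
        fg[idx] = False
    elif have < target:
        idx = rng.choice(np.flatnonzero(~fg), size=target - have, replace=False)
        fg[idx] = True
    return fg


def gen_vessel2d(scene: VesselScene2D) -> tuple[PlanarImage, VesselROI, GroundTruth]:
    """Render one synthetic vessel and its exact ground truth.

    Returns the image (single ``asma`` channel), the vessel ROI (mask,
    contour, ordered centerline), and ground truth whose
    ``coverage_true_pct`` is the exact foreground-pixel fraction of the
    emitted mask (recomputable from ``fg_label``).
    """
    p = scene.pixel_size_um
    width_px = int(round(scene.width_um / p))
    if width_px < 3:
        raise SizingError(
            f"vessel width {scene.width_um} um is {width_px} px at "
            f"{p} um/px; need at least 3 px"
        )
    n_seg = int(round(scene.length_mm * 1000.0 / p))
    if n_seg < 1:
        raise SizingError("vessel length under one pixel")
    margin = 10
    n_cols = n_seg + 1
    shape = (width_px + 2 * margin, n_cols + 2 * margin)

    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 2]))
    mask = np.zeros(shape, dtype=bool)
    r0, r1 = margin, margin + width_px
    c0, c1 = margin, margin + n_cols
    mask[r0:r1, c0:c1] = True
    n_mask = int(mask.sum())
    target = int(round(scene.coverage_true * n_mask))

    fg_label = np.zeros(shape, dtype=bool)
    if scene.pattern == "banded_heterogeneous":
        col_target = int(round(scene.coverage_true * n_cols))
        cols = _banded_columns(n_cols, col_target, rng)
        fg_label[r0:r1, c0:c1] = cols[np.newaxis, :]
        # column granularity: exact-adjust remaining pixels at random
        have = int(fg_label.sum())
        flat = np.flatnonzero(mask & (fg_label if have > target else ~fg_label))
        delta = abs(have - target)
        if delta:
            idx = rng.choice(flat, size=delta, replace=False)
            fg_label.ravel()[idx] = have < target
        fg_value = scene.fg_intensity
    else:  # uniform_dim
        flat = np.flatnonzero(mask)
        idx = rng.permutation(flat)[:target]
        fg_label.ravel()[idx] = True
        fg_value = scene.dim_fraction * scene.fg_intensity

    img = np.full(shape, scene.bg_intensity, dtype=np.float64)
    img[fg_label] = fg_value
    if scene.noise_sd > 0:
        img += rng.normal(0.0, scene.noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    center_row = r0 + (width_px - 1) / 2.0
    centerline = np.column_stack(
        [np.full(n_cols, center_row), np.arange(c0, c1, dtype=float)]
    )
    contour = np.array(
        [
            [r0, c0],
            [r0, c1 - 1],
            [r1 - 1, c1 - 1],
            [r1 - 1, c0],
            [r0, c0],
        ],
        dtype=float,
    )

    fg_count = int((fg_label & mask).sum())
    truth = GroundTruth(
        coverage_true_pct=100.0 * fg_count / n_mask,
        centerline=centerline,
        length_mm_true=n_seg * p / 1000.0,
        fg_label=fg_label,
    )
    image = PlanarImage(channels={"asma": img}, pixel_size_um=p)
    roi = VesselROI(contour=contour, mask=mask, centerline=centerline)
    return image, roi, truth


@dataclass
class NucleiScene3D:
    """Parameters of one synthetic 3-channel confocal stack.

    Nuclei are ellipsoids with per-axis diameters sampled from
    ``nucleus_diameter_um`` (default 3.5-7 um, so the short axis always
    exceeds the 1.417 um z-step and spans at least two z-planes).
    In-sheath nuclei sit inside a smooth-muscle slab carrying the aSMA
    signal; distractors sit above/below it with no aSMA overlap.
    """

    n_nuclei_inside: int = 200
    frac_brdu: float = 0.03
    n_distractors: int = 40
    nucleus_diameter_um: tuple[float, float] = (3.5, 7.0)
    voxel_size_um: tuple[float, float, float] = (0.8, 0.8, 1.417)
    weeks: float = 6.0
    area_per_nucleus_um2: float = 250.0
    sheath_thickness_um: float = 12.0
    min_separation_um: float = 1.5 * SEED_DIAMETER_UM
    asma_fg: float = 30000.0
    asma_bg: float = 1000.0
    asma_noise_sd: float = 800.0
    hoechst_fg: float = 30000.0
    hoechst_bg: float = 500.0
    hoechst_noise_sd: float = 500.0
    brdu_fg: float = 25000.0
    brdu_bg: float = 300.0
    brdu_noise_sd: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_brdu <= 1.0:
            raise ValueError("frac_brdu must be in [0, 1]")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")
        if self.weeks <= 0:
            raise ValueError("weeks must be > 0")
        lo, hi = self.nucleus_diameter_um
        if lo < SEED_DIAMETER_UM:
            raise ValueError(
                f"nucleus diameter minimum {lo} um below the seed-split "
                f"diameter {SEED_DIAMETER_UM} um: ground truth ill-posed"
            )
        if hi < lo:
            raise ValueError("nucleus_diameter_um must be (lo, hi) with hi >= lo")


def _place_centers(
    n: int,
    radii: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    taken_centers: list[np.ndarray],
    taken_rmax: list[float],
    min_sep: float,
    rng: np.random.Generator,
    max_forced: int = 0,
) -> tuple[list[np.ndarray], int]:
    """Dart-throwing placement with physical minimum separation.

    Separation between two nuclei must exceed both ``min_sep`` and the
    sum of their largest semi-axes plus a small gap, so rendered
    ellipsoids never touch. A nucleus that cannot be placed after many
    attempts counts as a forced merge; exceeding ``max_forced`` raises
    DensityError immediately. Returns centers and the forced count.
    """
    centers: list[np.ndarray] = []
    forced = 0
    gap = 0.8
    for i in range(n):
        rmax_i = float(radii[i].max())
        best, best_d = None, -np.inf
        placed = False
        for _ in range(600):
            c = rng.uniform(lo, hi)
            if taken_centers:
                d = np.linalg.norm(np.asarray(taken_centers) - c, axis=1)
                need = np.maximum(min_sep, rmax_i + np.asarray(taken_rmax) + gap)
                worst = float((d - need).min())
            else:
                worst = np.inf
            if worst >= 0:
                placed = True
                break
            if worst > best_d:
                best, best_d = c, worst
        if not placed:
            forced += 1
            if forced > max_forced:
                raise DensityError(
                    f"more than {max_forced} of {n} nuclei could not honor "
                    f"the minimum separation; reduce density"
                )
            c = best
        centers.append(c)
        taken_centers.append(c)
        taken_rmax.append(rmax_i)
    return centers, forced


def _paint_ellipsoid(
    labels: np.ndarray,
    label: int,
    center_um: np.ndarray,
    radii_um: np.ndarray,
    voxel_zyx: tuple[float, float, float],
) -> None:
    """Assign ``label`` to unclaimed voxels inside the ellipsoid."""
    vz, vy, vx = voxel_zyx
    cz, cy, cx = center_um
    rz, ry, rx = radii_um
    z0 = max(int(np.floor((cz - rz) / vz)), 0)
    z1 = min(int(np.ceil((cz + rz) / vz)) + 1, labels.shape[0])
    y0 = max(int(np.floor((cy - ry) / vy)), 0)
    y1 = min(int(np.ceil((cy + ry) / vy)) + 1, labels.shape[1])
    x0 = max(int(np.floor((cx - rx) / vx)), 0)
    x1 = min(int(np.ceil((cx + rx) / vx)) + 1, labels.shape[2])
    zz = (np.arange(z0, z1) * vz - cz) / rz
    yy = (np.arange(y0, y1) * vy - cy) / ry
    xx = (np.arange(x0, x1) * vx - cx) / rx
    inside = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ) <= 1.0
    sub = labels[z0:z1, y0:y1, x0:x1]
    sub[inside & (sub == 0)] = label


def gen_confocal3d(scene: NucleiScene3D) -> tuple[VolumeImage, GroundTruth]:
    """Render a 3-channel stack (asma, hoechst, brdu) with ground truth.

    Exactly ``n_nuclei_inside`` nuclei have centroids inside the sheath
    slab; ``round(frac_brdu * n_nuclei_inside)`` of them carry BrdU
    signal; distractors carry Hoechst only and never overlap the sheath.
    """
    vx, vy, vz = scene.voxel_size_um
    voxel_zyx = (vz, vy, vx)
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 3]))

    d_lo, d_hi = scene.nucleus_diameter_um
    rmax = d_hi / 2.0
    n_in, n_out = scene.n_nuclei_inside, scene.n_distractors

    y_um = 100.0
    x_um = max(150.0, n_in * scene.area_per_nucleus_um2 / y_um)
    clear = rmax + 2.0  # distractor band half-depth above/below the slab
    slab_half = scene.sheath_thickness_um / 2.0
    z_um = 2.0 * (slab_half + 2.0 * clear + 2.0)
    zc = z_um / 2.0
    slab_z = (zc - slab_half, zc + slab_half)

    shape = (
        int(np.ceil(z_um / vz)) + 1,
        int(np.ceil(y_um / vy)) + 1,
        int(np.ceil(x_um / vx)) + 1,
    )

    # per-axis diameters -> semi-axes (z, y, x)
    radii_in = rng.uniform(d_lo, d_hi, size=(n_in, 3)) / 2.0
    radii_out = rng.uniform(d_lo, d_hi, size=(max(n_out, 1), 3))[:n_out] / 2.0

    taken_c: list[np.ndarray] = []
    taken_r: list[float] = []
    pad = 1.0
    lo_in = np.array([slab_z[0] + pad, rmax + pad, rmax + pad])
    hi_in = np.array([slab_z[1] - pad, y_um - rmax - pad, x_um - rmax - pad])
    centers_in, _ = _place_centers(
        n_in, radii_in, lo_in, hi_in, taken_c, taken_r, scene.min_separation_um,
        rng, max_forced=int(0.05 * n_in),
    )
    # distractors: outside the slab, clear of it so ellipsoids cannot touch it
    centers_out: list[np.ndarray] = []
    if n_out:
        half = n_out - n_out // 2
        for count, (zlo, zhi) in (
            (half, (rmax + pad, slab_z[0] - clear)),
            (n_out // 2, (slab_z[1] + clear, z_um - rmax - pad)),
        ):
            lo_b = np.array([zlo, rmax + pad, rmax + pad])
            hi_b = np.array([zhi, y_um - rmax - pad, x_um - rmax - pad])
            got, _ = _place_centers(
                count,
                radii_out[len(centers_out) : len(centers_out) + count],
                lo_b,
                hi_b,
                taken_c,
                taken_r,
                scene.min_separation_um,
                rng,
                max_forced=int(0.05 * n_out),
            )
            centers_out.extend(got)

    labels = np.zeros(shape, dtype=np.int32)
    all_centers = centers_in + centers_out
    all_radii = np.concatenate([radii_in, radii_out]) if n_out else radii_in
    for i, (c, r) in enumerate(zip(all_centers, all_radii), start=1):
        _paint_ellipsoid(labels, i, c, r, voxel_zyx)

    inside_ids = list(range(1, n_in + 1))
    distractor_ids = list(range(n_in + 1, n_in + n_out + 1))

    n_brdu = int(round(scene.frac_brdu * n_in))
    brdu_ids = set(
        rng.choice(np.array(inside_ids), size=n_brdu, replace=False).tolist()
        if n_brdu
        else []
    )
    brdu_flags = {i: (i in brdu_ids) for i in inside_ids}

    zz = np.arange(shape[0]) * vz
    sheath = np.zeros(shape, dtype=bool)
    sheath[(zz >= slab_z[0] - 1.0) & (zz <= slab_z[1] + 1.0), :, :] = True

    nuc = labels > 0
    brdu_mask = np.isin(labels, list(brdu_ids)) if brdu_ids else np.zeros_like(nuc)

    def render(fg_mask: np.ndarray, fg: float, bg: float, sd: float) -> np.ndarray:
        img = np.full(shape, bg, dtype=np.float64)
        img[fg_mask] = fg
        if sd > 0:
            img += rng.normal(0.0, sd, size=shape)
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    channels = {
        "asma": render(sheath, scene.asma_fg, scene.asma_bg, scene.asma_noise_sd),
        "hoechst": render(
            nuc, scene.hoechst_fg, scene.hoechst_bg, scene.hoechst_noise_sd
        ),
        "brdu": render(brdu_mask, scene.brdu_fg, scene.brdu_bg, scene.brdu_noise_sd),
    }
    truth = GroundTruth(
        nucleus_labels=labels,
        inside_ids=inside_ids,
        distractor_ids=distractor_ids,
        brdu_flags=brdu_flags,
        sheath_mask=sheath,
        turnover_true_pct_per_week=100.0 * scene.frac_brdu / scene.weeks,
    )
    return VolumeImage(channels=channels, voxel_size_um=scene.voxel_size_um), truth


def gen_cohort(
    spec: list[tuple[str, float, float, int]],
    seed: int = 0,
    truncate_at_zero: bool = False,
) -> list[GroupSample]:
    """Draw group samples from summary statistics.

    Each entry of ``spec`` is (group, mean, sd, n); draws come from
    Normal(mean, sd). With ``truncate_at_zero``, negative draws are
    resampled (the printed SDs of several nonnegative quantities exceed
    their means, e.g. 0.81 +/- 1.0 contractions/min). Identical seed
    gives identical draws.
    """
    out: list[GroupSample] = []
    streams = np.random.SeedSequence([int(seed), 5]).spawn(len(spec))
    for (group, mean, sd, n), ss in zip(spec, streams):
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if n < 2:
            raise ValueError("n must be >= 2")
        rng = np.random.default_rng(ss)
        vals = rng.normal(mean, sd, size=n)
        if truncate_at_zero:
            for _ in range(1000):
                neg = vals < 0
                if not neg.any():
                    break
                vals[neg] = rng.normal(mean, sd, size=int(neg.sum()))
            else:
                raise ValueError("truncation failed to converge; mean far below 0?")
        out.append(GroupSample(group=group, values=vals, mean=mean, sd=sd, n=n, seed=seed))
    return out
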