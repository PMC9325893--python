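"""3D sheath masking, nucleus segmentation, BrdU classification, turnover."""

import numpy as np
import pytest
from scipy import ndimage

from plvquant.turnover import (
    classify_brdu,
    mask_within,
    merge_nucleus_lists,
    run_stack,
    segment_nuclei,
    segment_sheath,
    turnover_rate,
)

VOX = (0.8, 0.8, 1.417)  # (x, y, z) um


def _paint(shape, centers_um, radii_um, value=30000.0):
    """Raster ellipsoids into a float volume (zyx order, physical coords)."""
    vz, vy, vx = VOX[2], VOX[1], VOX[0]
    vol = np.zeros(shape)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * vz,
        np.arange(shape[1]) * vy,
        np.arange(shape[2]) * vx,
        indexing="ij",
    )
    for (cz, cy, cx), (rz, ry, rx) in zip(centers_um, radii_um):
        inside = (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        ) <= 1.0
        vol[inside] = value
    return vol


class TestMaskWithin:
    def test_identity_and_annihilation(self, rng):
        chan = rng.integers(0, 1000, size=(4, 5, 6))
        assert np.array_equal(mask_within(chan, np.ones_like(chan, bool)), chan)
        assert mask_within(chan, np.zeros_like(chan, bool)).sum() == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_within(np.zeros((2, 2, 2)), np.ones((2, 2, 3), bool))

    def test_distractor_voxels_zeroed(self, make_stack):
        (vol, gt), _ = make_stack(seed=6, n_distractors=20)
        masked = mask_within(vol.channels["hoechst"], gt.sheath_mask)
        for lab in gt.distractor_ids:
            assert (masked[gt.nucleus_labels == lab] == 0).all()


class TestSegmentSheath:
    def test_trivial_masks(self):
        assert not segment_sheath(np.zeros((3, 4, 4)), 10.0).any()
        assert segment_sheath(np.full((3, 4, 4), 7.0), 0.0).all()

    def test_recovers_generator_sheath(self, make_stack):
        (vol, gt), _ = make_stack(seed=7)
        from plvquant.turnover import background_threshold

        mask = segment_sheath(
            vol.channels["asma"], background_threshold(vol.channels["asma"])
        )
        inter = (mask & gt.sheath_mask).sum()
        union = (mask | gt.sheath_mask).sum()
        assert inter / union >= 0.9


class TestSegmentNuclei:
    def test_single_ellipsoid(self):
        shape = (14, 30, 30)
        chan = _paint(shape, [(9.0, 12.0, 12.0)], [(2.5, 3.0, 2.8)])
        nuclei, labels = segment_nuclei(chan, 1000.0, VOX)
        assert len(nuclei) == 1
        assert labels.max() == 1

    def test_touching_pair_split_by_seed_distance(self):
        # centroids 8 um apart (> 3.50 um seed diameter), ellipsoids touch
        shape = (14, 30, 40)
        chan = _paint(
            shape,
            [(9.0, 12.0, 10.0), (9.0, 12.0, 18.0)],
            [(2.8, 3.0, 4.2), (2.8, 3.0, 4.2)],
        )
        nuclei, _ = segment_nuclei(chan, 1000.0, VOX)
        assert len(nuclei) == 2

    def test_count_recovery_and_partition(self, make_stack):
        (vol, gt), scene = make_stack(seed=8, n_nuclei_inside=200,
                                      n_distractors=0)
        from plvquant.turnover import background_threshold

        masked = mask_within(vol.channels["hoechst"], gt.sheath_mask)
        nuclei, labels = segment_nuclei(
            masked,
            background_threshold(vol.channels["hoechst"]),
            scene.voxel_size_um,
            min_quality_au=1.5 * float(np.median(vol.channels["hoechst"])),
        )
        assert abs(len(nuclei) - 200) <= 10  # within 5%
        # partition: every labeled voxel carries exactly one label and
        # lies in the thresholded foreground
        fg = masked >= background_threshold(vol.channels["hoechst"])
        assert ((labels > 0) <= fg).all()
        ids = np.unique(labels)
        assert set(n.label for n in nuclei) == set(ids[ids > 0])

    def test_requires_physical_voxels(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((3, 3, 3)), 1.0, None)


class TestClassifyBrdu:
    def test_zero_channel_all_negative(self):
        shape = (14, 30, 30)
        chan = _paint(shape, [(9.0, 12.0, 12.0)], [(2.5, 3.0, 2.8)])
        nuclei, labels = segment_nuclei(chan, 1000.0, VOX)
        out = classify_brdu(nuclei, labels, np.zeros(shape), 500.0,
                            voxel_size_um=VOX)
        assert not any(n.brdu_positive for n in out)

    def test_generator_fraction_recovered(self, make_stack):
        (vol, gt), scene = make_stack(seed=9, n_nuclei_inside=100,
                                      frac_brdu=0.03)
        result, nuclei = run_stack(vol, weeks=scene.weeks)
        assert result.n_brdu == 3

    def test_isotype_noise_channel_near_zero_rate(self, make_stack):
        # BrdU channel at pure background: non-specific rate <= 0.25 %/wk
        (vol, gt), scene = make_stack(seed=10, brdu_fg=300.0)
        result, _ = run_stack(vol, weeks=scene.weeks)
        assert result.rate_pct_per_week is not None
        assert result.rate_pct_per_week <= 0.25


class TestTurnoverRate:
    @pytest.mark.parametrize(
        "n_brdu,n_total,weeks,expected",
        [(0, 100, 6, 0.0), (6, 100, 6, 1.0), (3, 100, 6, 0.5)],
    )
    def test_rate_formula(self, n_brdu, n_total, weeks, expected):
        assert turnover_rate(n_brdu, n_total, weeks) == pytest.approx(expected)

    def test_empty_stack_warns_missing(self):
        with pytest.warns(UserWarning):
            assert turnover_rate(0, 0, 6) is None

    def test_bad_weeks(self):
        with pytest.raises(ValueError):
            turnover_rate(1, 10, 0)


class TestPipeline:
    def test_distractors_excluded_from_totals(self, make_stack):
        (vol, gt), scene = make_stack(seed=11, n_nuclei_inside=50,
                                      n_distractors=25)
        result, nuclei = run_stack(vol, weeks=scene.weeks)
        # distractor centroids are far from every reported nucleus
        dist_centroids = [
            ndimage.center_of_mass(gt.nucleus_labels == lab)
            for lab in gt.distractor_ids
        ]
        vz, vy, vx = VOX[2], VOX[1], VOX[0]
        dist_um = np.array([(z * vz, y * vy, x * vx) for z, y, x in dist_centroids])
        got_um = np.array([(c[2], c[1], c[0]) for c in (n.centroid_um for n in nuclei)])
        for d in dist_um:
            assert np.linalg.norm(got_um - d, axis=1).min() > 2.0
        assert abs(result.n_total - 50) <= 3

    def test_end_to_end_recovery_small(self, make_stack):
        rates = []
        for s in range(3):
            (vol, _), scene = make_stack(
                seed=40 + s, n_nuclei_inside=100, frac_brdu=0.03
            )
            result, _ = run_stack(vol, weeks=scene.weeks)
            rates.append(result.rate_pct_per_week)
        assert abs(np.mean(rates) - 0.5) <= 0.2

    def test_half_stack_merge_dedup(self):
        from plvquant.datatypes import NucleusObject

        a = [NucleusObject(1, 50.0, (10.0, 10.0, 5.0), 3e4)]
        b = [
            NucleusObject(1, 48.0, (10.5, 10.2, 5.1), 3e4),  # same nucleus
            NucleusObject(2, 60.0, (30.0, 10.0, 5.0), 3e4),
        ]
        merged = merge_nucleus_lists(a, b)
        assert len(merged) == 2
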