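"""Lamina detection and mask construction against analytic/BFS oracles."""

import math

import numpy as np
import pytest

from omsbseg import (
    NoVesselError,
    SectionSpec,
    SegmentationError,
    build_media_mask,
    collagen_in_plaque,
    detect_laminae,
    generate_section,
    internal_region,
    plaque_pixels,
    segment_section,
    split_lumen_lipid,
)
from omsbseg.segmentation import SegmentationParams

from conftest import bfs_components, bfs_fill_interior, draw_annulus


def two_annuli_mask(shape=(200, 200), center=(100, 100)):
    mask = draw_annulus(shape, center, 40, 45) | draw_annulus(shape, center, 80, 85)
    rng = np.random.default_rng(3)
    # 50 scattered compact 3-px-wide blobs (nuclei/foam-cell stand-ins)
    for _ in range(50):
        r, c = rng.integers(3, shape[0] - 3, size=2)
        mask[r - 1 : r + 2, c - 1 : c + 2] = True
    return mask


class TestDetectLaminae:
    def test_two_concentric_annuli_with_blob_clutter(self):
        laminae = detect_laminae(two_annuli_mask(), min_enclosed_area=1000, closing_radius=0)
        assert len(laminae) == 2
        expected_inner = math.pi * 40**2
        assert laminae.innermost.enclosed_area == pytest.approx(expected_inner, rel=0.03)
        assert laminae.outermost.enclosed_area == pytest.approx(math.pi * 80**2, rel=0.03)

    def test_enclosed_areas_match_bfs_flood_fill_oracle(self):
        mask = draw_annulus((96, 96), (48, 48), 30, 34)
        laminae = detect_laminae(mask, min_enclosed_area=100, closing_radius=0)
        oracle_interior = bfs_fill_interior(mask)
        assert laminae.innermost.enclosed_area == int(oracle_interior.sum())
        assert (laminae.innermost.interior == oracle_interior).all()

    def test_all_zero_mask_raises_with_diagnostics(self):
        with pytest.raises(NoVesselError) as exc:
            detect_laminae(np.zeros((50, 50), dtype=bool))
        assert exc.value.n_components == 0
        assert exc.value.largest_enclosed_area == 0

    def test_blob_only_mask_reports_candidates(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:13, 10:13] = True
        mask[40:43, 40:43] = True
        with pytest.raises(NoVesselError) as exc:
            detect_laminae(mask, closing_radius=0)
        assert exc.value.n_components == 2

    def test_broken_annulus_bridged_by_closing(self):
        mask = draw_annulus((120, 120), (60, 60), 40, 44)
        # slit at the ring's rightmost crossing: nearest remaining pixels 3 px apart
        mask[59:61, 100:] = False
        laminae = detect_laminae(mask, min_enclosed_area=1000, closing_radius=2)
        assert len(laminae) == 1
        assert laminae.innermost.is_closed_ring

    def test_open_arc_rejected_without_closing(self):
        mask = draw_annulus((120, 120), (60, 60), 40, 44)
        mask[:, 95:] = False  # large gap closing cannot bridge
        with pytest.raises(NoVesselError):
            detect_laminae(mask, min_enclosed_area=1000, closing_radius=2)


class TestMediaInternal:
    def test_media_area_matches_analytic_annulus_difference(self):
        laminae = detect_laminae(two_annuli_mask(), min_enclosed_area=1000, closing_radius=0)
        media = build_media_mask(laminae)
        assert media.sum() == pytest.approx(math.pi * (85**2 - 40**2), rel=0.03)

    def test_internal_matches_analytic_disk(self):
        laminae = detect_laminae(two_annuli_mask(), min_enclosed_area=1000, closing_radius=0)
        internal = internal_region(laminae)
        assert internal.sum() == pytest.approx(math.pi * 40**2, rel=0.03)

    def test_media_internal_partition_of_outer_filled(self):
        laminae = detect_laminae(two_annuli_mask(), min_enclosed_area=1000, closing_radius=0)
        media = build_media_mask(laminae)
        internal = internal_region(laminae)
        assert not (media & internal).any()
        assert ((media | internal) == laminae.outermost.filled).all()

    def test_inner_ring_pixels_belong_to_media(self):
        laminae = detect_laminae(two_annuli_mask(), min_enclosed_area=1000, closing_radius=0)
        media = build_media_mask(laminae)
        assert (laminae.innermost.component & media).sum() == laminae.innermost.component.sum()

    def test_single_lamina_errors_unless_degenerate_allowed(self):
        mask = draw_annulus((100, 100), (50, 50), 30, 34)
        laminae = detect_laminae(mask, min_enclosed_area=100, closing_radius=0)
        with pytest.raises(SegmentationError, match="cannot delimit media"):
            build_media_mask(laminae)
        media = build_media_mask(laminae, allow_single=True)
        assert (media == laminae.innermost.component).all()

    def test_media_jaccard_against_ground_truth(self, clean_segmentation):
        seg, truth = clean_segmentation
        inter = (seg.media & truth.media).sum()
        union = (seg.media | truth.media).sum()
        assert inter / union >= 0.95


class TestLumenLipidSplit:
    @staticmethod
    def build_case(min_rbc=5, rbc_pixels=30):
        internal = np.zeros((80, 120), dtype=bool)
        internal[5:75, 5:115] = True
        white = np.zeros_like(internal)
        white[20:40, 10:40] = True  # blob A
        white[20:40, 70:100] = True  # blob B
        rbc = np.zeros_like(internal)
        rbc[25:31, 15:20] = True  # 30 yellow pixels seeded inside blob A
        white &= ~rbc  # stain classes are exclusive: yellow pixels are not white
        assert rbc.sum() == rbc_pixels
        return internal, white, rbc

    def test_erythrocyte_bearing_blob_is_lumen_other_is_lipid(self):
        internal, white, rbc = self.build_case()
        lumen, lipid = split_lumen_lipid(internal, white, rbc, min_rbc_pixels=5)
        blob_a = np.zeros_like(internal)
        blob_a[20:40, 10:40] = True
        assert (lumen == blob_a).all()  # blob A including its RBC pixels
        assert (lumen & rbc).sum() == rbc.sum()
        assert lipid.sum() == 600  # blob B
        assert not (lumen & lipid).any()

    def test_no_white_inside_internal_yields_both_empty(self):
        internal = np.ones((30, 30), dtype=bool)
        empty = np.zeros_like(internal)
        lumen, lipid = split_lumen_lipid(internal, empty, empty, min_rbc_pixels=1)
        assert not lumen.any() and not lipid.any()

    def test_single_component_with_rbcs_leaves_lipid_empty(self):
        internal, white, rbc = self.build_case()
        white[:, 60:] = False  # only blob A remains
        lumen, lipid = split_lumen_lipid(internal, white, rbc, min_rbc_pixels=5)
        assert not lipid.any()
        assert lumen.sum() == (white | rbc).sum()

    def test_yellow_only_component_is_neither_lumen_nor_lipid(self):
        internal = np.ones((40, 40), dtype=bool)
        white = np.zeros_like(internal)
        rbc = np.zeros_like(internal)
        rbc[10:20, 10:20] = True  # entrapped erythrocytes, no white around
        lumen, lipid = split_lumen_lipid(internal, white, rbc, min_rbc_pixels=5)
        assert not lumen.any() and not lipid.any()

    def test_lumen_monotone_in_min_rbc_threshold(self):
        internal, white, rbc = self.build_case()
        previous = None
        for threshold in (1, 5, 10, 30, 31, 100):
            lumen, _ = split_lumen_lipid(internal, white, rbc, min_rbc_pixels=threshold)
            if previous is not None:
                assert lumen.sum() <= previous
            previous = lumen.sum()


class TestPlaqueCollagen:
    def test_plaque_subtraction_arithmetic(self):
        internal = np.zeros((200, 100), dtype=bool)
        internal.flat[:10_000] = True
        lumen = np.zeros_like(internal)
        lumen.flat[:3_000] = True
        assert plaque_pixels(internal, lumen) == 7_000
        assert plaque_pixels(internal, internal) == 0

    def test_lumen_outside_internal_is_invariant_violation(self):
        internal = np.zeros((10, 10), dtype=bool)
        lumen = np.ones_like(internal)
        with pytest.raises(SegmentationError):
            plaque_pixels(internal, lumen)

    def test_collagen_clipped_to_plaque(self):
        internal = np.zeros((60, 60), dtype=bool)
        internal[10:50, 10:50] = True
        lumen = np.zeros_like(internal)
        lumen[15:25, 15:25] = True
        blue = np.zeros_like(internal)
        blue[30:40, 20:70] = True  # extends outside internal
        result = collagen_in_plaque(blue, internal, lumen)
        assert (result == (blue & internal)).all()
        assert not (result & lumen).any()
        blue_inside = np.zeros_like(internal)
        blue_inside[30:40, 25:75] = False
        blue_inside[35:45, 30:40] = True  # 100 px wholly in internal minus lumen
        assert collagen_in_plaque(blue_inside, internal, lumen).sum() == 100
        assert not collagen_in_plaque(~internal & blue, internal, lumen).any()


class TestComponentOracles:
    """skimage labeling / hole filling vs exhaustive BFS on small masks."""

    @pytest.mark.parametrize("seed", range(6))
    def test_labeling_matches_bfs_on_random_masks(self, seed):
        from skimage.measure import label as cc_label
        from scipy import ndimage as ndi

        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.35
        _, n_fast = cc_label(mask, connectivity=2, return_num=True)
        _, n_oracle = bfs_components(mask, connectivity=8)
        assert n_fast == n_oracle

        filled_fast = ndi.binary_fill_holes(mask)
        interior_oracle = bfs_fill_interior(mask)
        assert ((filled_fast & ~mask) == interior_oracle).all()


class TestEndToEnd:
    def test_noise_free_recovery_within_two_percent(self, clean_segmentation):
        seg, truth = clean_segmentation
        recovered = seg.area_summary()
        for key, true_px in truth.areas_px.items():
            assert recovered[key] == pytest.approx(true_px, rel=0.02), key

    def test_noisy_recovery_within_five_percent(self):
        image, truth = generate_section(SectionSpec(seed=21, noise_sigma=8.0))
        seg = segment_section(image)
        recovered = seg.area_summary()
        for key, true_px in truth.areas_px.items():
            assert recovered[key] == pytest.approx(true_px, rel=0.05), key

    def test_blank_white_image_raises_no_vessel(self):
        blank = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(NoVesselError):
            segment_section(blank)

    def test_rotation_changes_areas_below_one_percent(self, clean_section):
        image, _ = clean_section
        base = segment_section(image).area_summary()
        rotated = segment_section(np.rot90(image).copy()).area_summary()
        for key in ("media_px", "internal_px", "lumen_px", "plaque_px", "lipid_px", "collagen_px"):
            if base[key]:
                assert abs(rotated[key] - base[key]) / base[key] < 0.01, key

    def test_min_rbc_scaling_with_calibration(self):
        assert SegmentationParams.for_calibration(0.5).min_rbc_pixels == 10
        assert SegmentationParams.for_calibration(0.25).min_rbc_pixels == 40
        assert SegmentationParams.for_calibration(1.0).min_rbc_pixels == 2
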