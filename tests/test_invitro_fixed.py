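"""Fixed-cell pipeline: preprocessing, segmentation, classification,
Ki-67 scoring, and ground-truth recovery."""

import numpy as np
import pytest

from colonyquant.config import PipelineConfig
from colonyquant.imgops import BinaryMask, GrayImage, LabelMap, ParameterError
from colonyquant.invitro_fixed import (
    build_fixed_result,
    classify_colonies,
    count_cells_per_colony,
    ki67_score,
    preprocess_channel,
    segment_colonies,
    segment_nuclei,
)
from colonyquant.io import InputError
from colonyquant.synthgen import GeneratorConfig, generate_fixed_well
from conftest import match_to_truth


def disk(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestPreprocess:
    def test_all_zero_channel_empty_mask(self, default_config):
        img = GrayImage(np.zeros((64, 64)))
        assert preprocess_channel(img, default_config.colony_pre).foreground_count == 0

    def test_ramp_only_background_empty_mask(self, default_config):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[:256, :256]
        img = 0.1 + 0.1 * xx / 255.0 + rng.normal(0, 0.02, (256, 256))
        mask = preprocess_channel(
            GrayImage(np.clip(img, 0, 1)), default_config.colony_pre
        )
        assert mask.foreground_count == 0

    def test_mask_covers_truth_footprints(self, fixed_well_seed1, default_config):
        channels, truth, _ = fixed_well_seed1
        mask = preprocess_channel(channels["dapi"], default_config.colony_pre)
        covered = mask.pixels & (truth.object_labels.pixels > 0)
        assert covered.sum() / (truth.object_labels.pixels > 0).sum() >= 0.95

    def test_offset_invariance_of_masks(self, default_config):
        channels, _ = generate_fixed_well(GeneratorConfig(n_colonies=5), seed=12)
        img = channels["dapi"]
        shifted = GrayImage(img.pixels + 0.07, img.pixel_pitch_um)
        a = preprocess_channel(img, default_config.colony_pre).pixels
        b = preprocess_channel(shifted, default_config.colony_pre).pixels
        # a constant offset is background; the top-hat removes it
        assert (a == b).mean() > 0.999


class TestSegmentColonies:
    def test_two_distant_disks(self, default_config):
        mask = disk((300, 300), (80, 80), 25) | disk((300, 300), (80, 280 - 40), 25)
        labels = segment_colonies(BinaryMask(mask), default_config)
        assert labels.n_labels == 2

    def test_empty_mask(self, default_config):
        labels = segment_colonies(BinaryMask(np.zeros((32, 32), dtype=bool)), default_config)
        assert labels.n_labels == 0

    def test_chain_of_overlapping_colonies_split(self, default_config):
        # five disks overlapping in a chain, as connected colonies do
        shape = (160, 420)
        mask = np.zeros(shape, dtype=bool)
        for k in range(5):
            mask |= disk(shape, (80, 70 + 70 * k), 25)
        labels = segment_colonies(BinaryMask(mask), default_config)
        assert labels.n_labels == 5

    def test_small_objects_discarded(self, default_config):
        mask = disk((200, 200), (60, 60), 25) | disk((200, 200), (150, 150), 3)
        labels = segment_colonies(BinaryMask(mask), default_config)
        assert labels.n_labels == 1


class TestSegmentNuclei:
    def test_single_blob_single_label(self, default_config):
        yy, xx = np.mgrid[:64, :64]
        img = 0.7 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.2**2))
        labels = segment_nuclei(GrayImage(img), default_config)
        assert labels.n_labels == 1

    def test_fifty_separated_nuclei(self, default_config):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[:500, :500]
        img = np.zeros((500, 500))
        centers = [(25 + 50 * i, 25 + 50 * j) for i in range(10) for j in range(5)]
        for r, c in centers:
            img += 0.7 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 2.2**2))
        img += rng.normal(0, 0.02, img.shape)
        labels = segment_nuclei(GrayImage(np.clip(img, 0, 1)), default_config)
        assert labels.n_labels == 50

    def test_touching_nuclei_split_by_watershed(self, default_config):
        # two overlapping nuclear disks: watershed cuts near the waist
        mask = disk((60, 60), (30, 24), 10) | disk((60, 60), (30, 36), 10)
        from colonyquant.invitro_fixed import _watershed_on_distance

        labels = _watershed_on_distance(
            BinaryMask(mask), default_config.h_nucleus_px, default_config.min_nucleus_area_px
        )
        assert labels.n_labels == 2
        assert labels.pixels[30, 20] != labels.pixels[30, 40]


class TestCounting:
    def test_seven_nuclei_in_one_colony(self):
        colony = LabelMap(disk((80, 80), (40, 40), 30).astype(np.int32))
        nuclei = np.zeros((80, 80), dtype=np.int32)
        for k in range(7):
            nuclei[30 + 3 * k, 30] = k + 1
        counts = count_cells_per_colony(colony, LabelMap(nuclei))
        assert counts == {1: 7}

    def test_nucleus_outside_all_colonies_unassigned(self):
        colony = LabelMap(disk((60, 60), (20, 20), 10).astype(np.int32))
        nuclei = np.zeros((60, 60), dtype=np.int32)
        nuclei[50, 50] = 1
        assert count_cells_per_colony(colony, LabelMap(nuclei)) == {1: 0}

    def test_synthetic_counts_match_truth(self):
        channels, truth = generate_fixed_well(seed=2)
        result = build_fixed_result(channels)
        assert sorted(c.cell_count for c in result.colonies) == sorted(
            truth.objects.cell_count
        )


class TestClassification:
    def test_pure_rfp_colony(self, default_config):
        colony = LabelMap(disk((60, 60), (30, 30), 15).astype(np.int32))
        rfp = BinaryMask(disk((60, 60), (30, 30), 20))
        gfp = BinaryMask(np.zeros((60, 60), dtype=bool))
        assert classify_colonies(colony, gfp, rfp, default_config) == {1: "DsRed+"}

    def test_double_positive_rule(self, default_config):
        shape = (40, 40)
        colony = LabelMap(disk(shape, (20, 20), 10).astype(np.int32))
        area_pixels = disk(shape, (20, 20), 10)
        # both masks cover over half the colony
        gfp = np.zeros(shape, dtype=bool)
        gfp[area_pixels & (np.arange(40)[None, :] <= 24)] = True
        rfp = np.zeros(shape, dtype=bool)
        rfp[area_pixels & (np.arange(40)[None, :] >= 16)] = True
        out = classify_colonies(colony, BinaryMask(gfp), BinaryMask(rfp), default_config)
        assert out == {1: "double"}

    def test_mixed_well_matches_truth(self, fixed_well_seed1):
        channels, truth, result = fixed_well_seed1
        for colony in result.colonies:
            assert colony.fluor_class == match_to_truth(colony, truth.objects).fluor_class


class TestKi67:
    def _nucleus(self, n_overlap):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :] = 1  # 100-px nucleus
        mask = np.zeros((10, 10), dtype=bool)
        mask.ravel()[:n_overlap] = True
        return LabelMap(labels), BinaryMask(mask)

    def test_full_overlap_positive(self):
        labels, mask = self._nucleus(100)
        rec = ki67_score(labels, mask)[0]
        assert rec.ki67_overlap_fraction == 1.0 and rec.ki67_positive

    def test_boundary_fraction_is_negative(self):
        labels, mask = self._nucleus(25)
        rec = ki67_score(labels, mask, threshold=0.25)[0]
        assert rec.ki67_overlap_fraction == pytest.approx(0.25)
        assert not rec.ki67_positive  # strictly greater than

    def test_just_above_boundary_is_positive(self):
        labels, mask = self._nucleus(26)
        rec = ki67_score(labels, mask, threshold=0.25)[0]
        assert rec.ki67_overlap_fraction == pytest.approx(0.26)
        assert rec.ki67_positive

    def test_threshold_out_of_range(self):
        labels, mask = self._nucleus(10)
        with pytest.raises(ParameterError):
            ki67_score(labels, mask, threshold=1.2)

    def test_raising_threshold_monotone(self, fixed_well_seed1):
        channels, _, _ = fixed_well_seed1
        cfg = PipelineConfig()
        from colonyquant.invitro_fixed import preprocess_channel, segment_nuclei

        nuclei = segment_nuclei(channels["dapi"], cfg)
        mask = preprocess_channel(channels["cy5"], cfg.nucleus_pre)
        counts = []
        for thr in (0.1, 0.25, 0.5, 0.9):
            recs = ki67_score(nuclei, mask, thr)
            counts.append(sum(r.ki67_positive for r in recs))
        assert counts == sorted(counts, reverse=True)


class TestBuildResult:
    def test_missing_dapi_errors(self):
        with pytest.raises(InputError):
            build_fixed_result({})

    def test_dapi_only_well(self):
        channels, truth = generate_fixed_well(GeneratorConfig(n_colonies=5), seed=8)
        result = build_fixed_result({"dapi": channels["dapi"]})
        assert len(result.colonies) == 5
        assert all(c.fluor_class == "none" for c in result.colonies)
        assert all(c.ki67_index is None for c in result.colonies)

    def test_full_well_consistency(self, fixed_well_seed1):
        _, truth, result = fixed_well_seed1
        assert len(result.colonies) == len(truth.objects)
        total_cells = sum(c.cell_count for c in result.colonies)
        assert total_cells <= len(result.nuclei)
        for colony in result.colonies:
            t = match_to_truth(colony, truth.objects)
            assert colony.cell_count == t.cell_count
            assert colony.ki67_index == pytest.approx(t.ki67_index)
            assert 0 <= colony.ki67_index <= 1
            assert colony.area_um2 == pytest.approx(
                colony.area_px * result.colony_labels.pixel_pitch_um**2
            )

    def test_gfp_colonies_without_ki67_signal_score_zero(self):
        cfg = GeneratorConfig(ki67_positive_fraction={"DsRed+": 0.9, "GFP+": 0.0})
        channels, truth = generate_fixed_well(cfg, seed=9)
        result = build_fixed_result(channels)
        gfp = [c for c in result.colonies if c.fluor_class == "GFP+"]
        assert gfp and all(c.ki67_index == 0.0 for c in gfp)
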