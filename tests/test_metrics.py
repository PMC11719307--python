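import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from petprior import (
    VolumeGrid,
    asd,
    dice,
    extract_lesions,
    fn_confusion_matrix,
    hd95,
    lesion_precision_recall,
    paired_wilcoxon,
    per_lesion_records,
    stratified_dice,
)

from conftest import random_mask_volume

SPACING = (2.04, 2.04, 3.00)


def vol(values, spacing=SPACING):
    return VolumeGrid(np.asarray(values), spacing)


def brute_force_surface_distances(a, b, spacing):
    """O(n^2) oracle: pooled symmetric surface distances in mm."""

    def surface(mask):
        padded = np.pad(mask, 1)
        inner = ndimage.binary_erosion(padded, ndimage.generate_binary_structure(3, 1))
        return (np.argwhere(padded & ~inner) - 1) * np.asarray(spacing)

    pa, pb = surface(a), surface(b)
    d = cdist(pa, pb)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


class TestDice:
    def test_identical_and_disjoint(self):
        a = vol(np.ones((3, 3, 3), np.uint8))
        assert dice(a, a) == 1.0
        b = vol(np.zeros((3, 3, 3), np.uint8))
        b.values[0, 0, 0] = 1
        c = vol(np.zeros((3, 3, 3), np.uint8))
        c.values[2, 2, 2] = 1
        assert dice(b, c) == 0.0

    def test_partial_overlap_formula(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0, 0, :4] = 1  # |A| = 4
        b[0, 0, 2:4] = 1
        b[0, 1, :2] = 1  # |B| = 4, overlap 2
        assert dice(vol(a), vol(b)) == 0.5

    def test_empty_conventions(self):
        empty = vol(np.zeros((3, 3, 3), np.uint8))
        full = vol(np.ones((3, 3, 3), np.uint8))
        assert dice(empty, empty) == 1.0
        assert dice(full, empty) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(vol(np.ones((3, 3, 3))), vol(np.ones((4, 4, 4))))


class TestSurfaceDistances:
    def test_identical_masks_have_zero_distance(self):
        rng = np.random.default_rng(0)
        m = vol((rng.random((6, 6, 6)) < 0.4).astype(np.uint8))
        m.values[0, 0, 0] = 1  # ensure non-empty
        assert hd95(m, m) == 0.0
        assert asd(m, m) == 0.0

    def test_two_points_three_z_voxels_apart(self):
        a = np.zeros((3, 3, 8), np.uint8)
        b = np.zeros((3, 3, 8), np.uint8)
        a[1, 1, 1] = 1
        b[1, 1, 4] = 1
        assert hd95(vol(a), vol(b)) == pytest.approx(9.0)  # 3 voxels x 3.0 mm
        assert asd(vol(a), vol(b)) == pytest.approx(9.0)

    def test_empty_mask_reports_missing_with_warning(self):
        a = vol(np.zeros((3, 3, 3), np.uint8))
        b = vol(np.ones((3, 3, 3), np.uint8))
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(hd95(a, b))
        with pytest.warns(UserWarning):
            assert np.isnan(asd(a, b))

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        checked = 0
        while checked < 60:
            a = random_mask_volume(rng)
            b = VolumeGrid(
                (rng.random(a.shape) < 0.3).astype(np.uint8), a.spacing_mm
            )
            if not a.values.any() or not b.values.any():
                continue
            pooled = brute_force_surface_distances(
                a.values > 0, b.values > 0, a.spacing_mm
            )
            assert abs(hd95(a, b) - np.percentile(pooled, 95)) < 1e-9
            assert abs(asd(a, b) - pooled.mean()) < 1e-9
            checked += 1

    def test_distances_scale_with_spacing(self):
        a = np.zeros((3, 3, 8), np.uint8)
        b = np.zeros((3, 3, 8), np.uint8)
        a[1, 1, 1], b[1, 1, 4] = 1, 1
        d1 = hd95(vol(a, (1, 1, 1)), vol(b, (1, 1, 1)))
        d2 = hd95(vol(a, (2, 2, 2)), vol(b, (2, 2, 2)))
        assert d2 == pytest.approx(2 * d1)


class TestExtractLesions:
    def test_corner_touching_voxels_are_one_component(self):
        m = np.zeros((4, 4, 4), np.uint8)
        m[0, 0, 0] = 1
        m[1, 1, 1] = 1  # touches only at a corner
        lesions = extract_lesions(vol(m), min_volume_ml=0.0)
        assert len(lesions) == 1

    def test_volume_filter_boundary(self):
        # 24 voxels x 12.48 mm^3 = 0.2996 ml <= 0.3 -> discarded;
        # 25 voxels = 0.3121 ml -> kept
        m24 = np.zeros((10, 10, 10), np.uint8)
        m24[0:2, 0:3, 0:4] = 1
        assert len(extract_lesions(vol(m24))) == 0
        m25 = m24.copy()
        m25[2, 0, 0] = 1
        assert len(extract_lesions(vol(m25))) == 1
        assert extract_lesions(vol(m25)).volumes_ml[0] == pytest.approx(
            25 * 2.04 * 2.04 * 3.0 / 1000.0
        )

    def test_empty_mask_gives_empty_set(self):
        assert len(extract_lesions(vol(np.zeros((3, 3, 3), np.uint8)))) == 0

    def test_raising_filter_never_adds_lesions(self, rng):
        m = vol((rng.random((12, 12, 12)) < 0.2).astype(np.uint8))
        counts = [
            len(extract_lesions(m, min_volume_ml=t)) for t in (0.0, 0.05, 0.1, 0.3, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDetection:
    def _sets(self, pred, truth):
        return (
            extract_lesions(vol(pred), min_volume_ml=0.0),
            extract_lesions(vol(truth), min_volume_ml=0.0),
        )

    def test_recall_two_of_three(self):
        truth = np.zeros((12, 4, 4), np.uint8)
        truth[0:2, 0, 0] = 1
        truth[5:7, 0, 0] = 1
        truth[10:12, 0, 0] = 1
        pred = np.zeros_like(truth)
        pred[0, 0, 0] = 1
        pred[5, 0, 0] = 1
        p, t = self._sets(pred, truth)
        res = lesion_precision_recall(p, t)
        assert res.recall == pytest.approx(2 / 3)
        assert res.tp == 2 and res.fn == 1

    def test_precision_three_of_four(self):
        truth = np.zeros((20, 4, 4), np.uint8)
        pred = np.zeros_like(truth)
        for i, x in enumerate((0, 5, 10, 15)):
            pred[x, 0, 0] = 1
            if i < 3:
                truth[x, 0, 0] = 1
        p, t = self._sets(pred, truth)
        assert lesion_precision_recall(p, t).precision == pytest.approx(3 / 4)
        assert lesion_precision_recall(p, t).fp == 1

    def test_perfect_prediction(self):
        truth = np.zeros((8, 8, 8), np.uint8)
        truth[2:4, 2:4, 2:4] = 1
        p, t = self._sets(truth, truth)
        res = lesion_precision_recall(p, t)
        assert res.precision == res.recall == 1.0

    def test_undefined_ratios_are_nan(self):
        empty = np.zeros((4, 4, 4), np.uint8)
        some = empty.copy()
        some[0, 0, 0] = 1
        p, t = self._sets(some, empty)
        assert np.isnan(lesion_precision_recall(p, t).recall)
        p, t = self._sets(empty, some)
        assert np.isnan(lesion_precision_recall(p, t).precision)

    def test_conservation_on_random_masks(self, rng):
        for _ in range(50):
            shape = (10, 10, 10)
            truth = vol((rng.random(shape) < 0.1).astype(np.uint8))
            pred = vol((rng.random(shape) < 0.1).astype(np.uint8))
            t = extract_lesions(truth, min_volume_ml=0.0)
            p = extract_lesions(pred, min_volume_ml=0.0)
            res = lesion_precision_recall(p, t)
            assert res.tp + res.fn == len(t)
            cm = fn_confusion_matrix(pred, pred, truth, min_volume_ml=0.0)
            assert cm.to_numpy().sum() == len(t)


class TestStratifiedDice:
    def _records(self, volumes):
        return pd.DataFrame(
            {
                "lesion": range(len(volumes)),
                "volume_ml": volumes,
                "mean_suv": [2.0] * len(volumes),
                "detected": [True] * len(volumes),
                "dice": [0.8] * len(volumes),
            }
        )

    def test_lymphoma_preset_boundaries(self):
        table = stratified_dice(self._records([0.8, 14.0]), "lymphoma")
        assert table.loc[table.group == "V1", "n"].item() == 1  # 0.8 ml -> V1
        assert table.loc[table.group == "V5", "n"].item() == 1  # 14 ml -> V5

    def test_single_group_leaves_others_empty(self):
        table = stratified_dice(self._records([0.2, 0.5, 0.9]), "lymphoma")
        assert table.loc[table.group == "V1", "n"].item() == 3
        assert (table.loc[table.group != "V1", "n"] == 0).all()
        assert np.isnan(table.loc[table.group == "V3", "dice_mean"].item())

    def test_all_disease_presets_have_five_groups(self):
        for preset in ("lymphoma", "lung", "melanoma"):
            table = stratified_dice(self._records([1.0]), preset)
            assert list(table.group) == ["V1", "V2", "V3", "V4", "V5"]


class TestFnConfusionMatrix:
    def test_partial_disagreement(self):
        truth = np.zeros((20, 4, 4), np.uint8)
        a = np.zeros_like(truth)
        b = np.zeros_like(truth)
        for x in (0, 6, 12):
            truth[x : x + 2, 0, 0] = 1
        a[0, 0, 0] = a[6, 0, 0] = 1  # detects lesions 1, 2
        b[6, 0, 0] = b[12, 0, 0] = 1  # detects lesions 2, 3
        cm = fn_confusion_matrix(vol(a), vol(b), vol(truth), min_volume_ml=0.0)
        assert cm.loc["Yes", "Yes"] == 1
        assert cm.loc["Yes", "No"] == 1
        assert cm.loc["No", "Yes"] == 1
        assert cm.loc["No", "No"] == 0

    def test_both_detect_everything(self):
        truth = np.zeros((8, 4, 4), np.uint8)
        truth[0:2, 0, 0] = 1
        cm = fn_confusion_matrix(vol(truth), vol(truth), vol(truth), min_volume_ml=0.0)
        assert cm.loc["Yes", "Yes"] == 1
        assert cm.to_numpy().sum() == 1


class TestPairedWilcoxon:
    def test_constant_shift_exact_p(self):
        a = np.linspace(0.1, 1.0, 10)
        p = paired_wilcoxon(a, a + 0.05)
        assert p == pytest.approx(2 / 2**10)

    def test_identical_samples_undefined(self):
        a = np.arange(8.0)
        with pytest.warns(UserWarning, match="zero"):
            assert np.isnan(paired_wilcoxon(a, a))

    def test_symmetry_under_swap(self, rng):
        a = rng.random(12)
        b = rng.random(12)
        assert paired_wilcoxon(a, b) == pytest.approx(paired_wilcoxon(b, a))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [1.0])


class TestPerLesionRecords:
    def test_records_cover_truth_lesions(self, hard_sample):
        records = per_lesion_records(hard_sample.truth, hard_sample.truth,
                                     suv=hard_sample.suv)
        assert len(records) == 3
        assert records["detected"].all()
        assert (records["dice"] == 1.0).all()
        assert (records["volume_ml"] > 0.3).all()
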