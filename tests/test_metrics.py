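import numpy as np
import pytest
from scipy import ndimage, stats

from kevs.metrics import (
    binary_group_dice,
    dice,
    nsd,
    organ_border_metrics,
    organ_overlap_fraction,
    per_slice_metrics,
    precision_recall,
    wilcoxon_one_sided,
)
from kevs.volume import BinaryMask, LabelMap

from .oracles import nsd_bruteforce, wilcoxon_enumeration


def _mask(data, spacing=(1, 1, 1)):
    return BinaryMask(np.asarray(data, dtype=bool), spacing)


def _random_blob_pair(seed, shape=(12, 12, 12)):
    rng = np.random.default_rng(seed)
    a = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5) > 0.1
    b = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5) > 0.1
    return a, b


class TestOverlapMetrics:
    def test_identical_masks(self):
        rng = np.random.default_rng(0)
        a = _mask(rng.random((8, 8, 8)) > 0.5)
        assert dice(a, a) == 1.0
        assert precision_recall(a, a) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_count_arithmetic(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[20:120] = True  # overlap 80
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.8)
        a2 = np.zeros((10, 10, 10), dtype=bool)
        b2 = np.zeros((10, 10, 10), dtype=bool)
        a2.ravel()[:50] = True
        b2.ravel()[10:110] = True  # |A|=50 |B|=100 inter=40
        assert precision_recall(_mask(a2), _mask(b2)) == (pytest.approx(0.8), pytest.approx(0.4))

    def test_strict_subset_has_unit_precision(self):
        b = np.zeros((6, 6, 6), dtype=bool)
        b[1:5, 1:5, 1:5] = True
        a = b.copy()
        a[1, 1, 1] = False
        prec, rec = precision_recall(_mask(a), _mask(b))
        assert prec == 1.0 and rec < 1.0

    def test_empty_conventions(self):
        e = _mask(np.zeros((4, 4, 4)))
        f = _mask(np.ones((4, 4, 4)))
        assert dice(e, e) == 1.0
        assert dice(f, e) == 0.0
        prec, rec = precision_recall(e, f)
        assert np.isnan(prec) and rec == 0.0

    def test_dice_is_harmonic_mean_of_precision_recall(self):
        for seed in range(5):
            a, b = _random_blob_pair(seed)
            if not (a.any() and b.any() and (a & b).any()):
                continue
            d = dice(_mask(a), _mask(b))
            p, r = precision_recall(_mask(a), _mask(b))
            assert d == pytest.approx(2 * p * r / (p + r))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dice(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((5, 5, 5))))


class TestNSD:
    def test_identical_masks_score_one(self):
        a, _ = _random_blob_pair(1)
        m = _mask(a, (1.5, 1.5, 1.5))
        assert nsd(m, m, 2.0) == 1.0

    def test_far_separated_cubes_score_zero(self):
        a = np.zeros((20, 20, 20), dtype=bool)
        b = np.zeros((20, 20, 20), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        b[15:17, 15:17, 15:17] = True
        assert nsd(_mask(a, (1.5, 1.5, 1.5)), _mask(b, (1.5, 1.5, 1.5)), 2.0) == 0.0

    def test_shifted_cube_matches_bruteforce(self):
        a = np.zeros((14, 14, 14), dtype=bool)
        b = np.zeros((14, 14, 14), dtype=bool)
        a[2:12, 2:12, 2:12] = True
        b[3:13, 2:12, 2:12] = True  # one-voxel shift at 1.5 mm
        sp = (1.5, 1.5, 1.5)
        assert nsd(_mask(a, sp), _mask(b, sp), 2.0) == nsd_bruteforce(a, b, sp, 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_anisotropic_blobs(self, seed):
        a, b = _random_blob_pair(seed, shape=(10, 10, 10))
        sp = (1.2, 0.8, 2.5)
        assert nsd(_mask(a, sp), _mask(b, sp), 2.0) == nsd_bruteforce(a, b, sp, 2.0)

    def test_translation_invariance(self):
        a, b = _random_blob_pair(7, shape=(10, 10, 10))
        sp = (1.0, 1.0, 2.0)
        pad = [(3, 3)] * 3
        a2 = np.pad(a, pad)
        b2 = np.pad(b, pad)
        assert nsd(_mask(a2, sp), _mask(b2, sp), 2.0) == nsd(_mask(a, sp), _mask(b, sp), 2.0)
        d1 = dice(_mask(a2, sp), _mask(b2, sp))
        d0 = dice(_mask(a, sp), _mask(b, sp))
        assert d1 == pytest.approx(d0)

    def test_empty_conventions(self):
        e = _mask(np.zeros((4, 4, 4)))
        f = _mask(np.ones((4, 4, 4)))
        assert nsd(e, e) == 1.0
        assert nsd(e, f) == 0.0


class TestGroupDice:
    def test_singleton_group_equals_plain_dice(self):
        rng = np.random.default_rng(2)
        a = (rng.random((8, 8, 8)) > 0.6).astype(np.int32) * 11
        b = (rng.random((8, 8, 8)) > 0.6).astype(np.int32) * 11
        schema = {"liver": 11}
        la = LabelMap(a, (1, 1, 1), schema)
        lb = LabelMap(b, (1, 1, 1), schema)
        assert binary_group_dice(la, lb, ["liver"]) == dice(
            _mask(a == 11), _mask(b == 11))

    def test_identical_maps_score_one(self, phantom_case):
        _, _, labels, _, _ = phantom_case
        organs = [n for n in ("liver", "spleen", "stomach", "pancreas") if n in labels.names_present()]
        assert binary_group_dice(labels, labels, organs) == 1.0

    def test_complementary_errors_boost_group_score(self):
        # two organs, each per-label Dice 0.5, but predictions land inside the
        # union -> the grouped binary Dice is higher than the per-label mean
        truth = np.zeros((4, 4, 1), dtype=np.int32)
        truth[0:2, 0, 0] = 1  # organ A: voxels (0,0),(1,0)
        truth[2:4, 0, 0] = 2  # organ B: voxels (2,0),(3,0)
        pred = np.zeros_like(truth)
        pred[1:3, 0, 0] = 1  # A predicted on (1,0) [correct] and (2,0) [B's voxel]
        pred[3, 0, 0] = 2    # B predicted on (3,0) only
        schema = {"a": 1, "b": 2}
        lt = LabelMap(truth, (1, 1, 1), schema)
        lp = LabelMap(pred, (1, 1, 1), schema)
        da = dice(_mask(pred == 1), _mask(truth == 1))
        db = dice(_mask(pred == 2), _mask(truth == 2))
        group = binary_group_dice(lp, lt, ["a", "b"])
        assert group == pytest.approx(6 / 7)
        assert group > (da + db) / 2


class TestOrganDiagnostics:
    def test_overlap_fraction_cases(self):
        organs = np.zeros((10, 10, 10), dtype=bool)
        organs.ravel()[:500] = True
        pred = np.zeros_like(organs)
        pred.ravel()[477:677] = True  # |pred| = 200, overlap = 23
        assert organ_overlap_fraction(_mask(pred), _mask(organs)) == pytest.approx(0.115)
        assert organ_overlap_fraction(_mask(organs), _mask(organs)) == 1.0
        far = np.zeros_like(organs)
        far.ravel()[-100:] = True
        assert organ_overlap_fraction(_mask(far), _mask(organs)) == 0.0
        assert np.isnan(organ_overlap_fraction(_mask(np.zeros_like(organs)), _mask(organs)))

    def test_border_shell_of_single_voxel_has_24_voxels(self):
        organs = np.zeros((9, 9, 9), dtype=bool)
        organs[4, 4, 4] = True
        pred = np.ones_like(organs)
        out = organ_border_metrics(_mask(pred), _mask(pred), _mask(organs), layers=2)
        assert out["shell_voxels"] == 24  # Manhattan ball radius 2 minus centre
        assert out["dice"] == 1.0

    def test_zero_layers_is_undefined(self):
        organs = _mask(np.ones((4, 4, 4)))
        out = organ_border_metrics(organs, organs, organs, layers=0)
        assert np.isnan(out["dice"]) and out["shell_voxels"] == 0


class TestPerSlice:
    def test_three_slice_overlap_ladder(self):
        # equal-size masks with per-slice overlap 100% / 50% / 0%
        pred = np.zeros((8, 8, 3), dtype=bool)
        truth = np.zeros_like(pred)
        pred[0:4, 0, 0] = truth[0:4, 0, 0] = True
        pred[0:4, 0, 1] = True
        truth[2:6, 0, 1] = True
        pred[0:4, 0, 2] = True
        truth[4:8, 0, 2] = True
        table = per_slice_metrics(_mask(pred), _mask(truth))
        np.testing.assert_allclose(table["dice"], [1.0, 0.5, 0.0])

    def test_both_empty_slices_flagged_with_unit_dice(self):
        pred = np.zeros((4, 4, 2), dtype=bool)
        truth = np.zeros_like(pred)
        pred[1, 1, 0] = truth[1, 1, 0] = True
        table = per_slice_metrics(_mask(pred), _mask(truth))
        assert table.loc[1, "both_empty"]
        assert table.loc[1, "dice"] == 1.0 and table.loc[1, "nsd"] == 1.0
        assert not table.loc[0, "both_empty"]

    def test_single_slice_table_matches_volumetric_2d(self):
        a, b = _random_blob_pair(3, shape=(10, 10, 1))
        sp = (1.5, 1.5, 1.5)
        table = per_slice_metrics(_mask(a, sp), _mask(b, sp))
        assert len(table) == 1
        assert table.loc[0, "dice"] == pytest.approx(dice(_mask(a, sp), _mask(b, sp)))

    def test_z_range_restricts_rows(self, phantom_case):
        _, _, _, vat, _ = phantom_case
        table = per_slice_metrics(vat, vat, z_range=(10, 19))
        assert list(table["z"]) == list(range(10, 20))
        assert np.all(table["dice"] == 1.0)


class TestWilcoxon:
    def test_six_allpositive_distinct_pairs_give_one_in_64(self):
        a = np.array([5.0, 6, 7, 8, 9, 10])
        b = np.array([1.0, 2, 3, 4, 5, 6])
        assert wilcoxon_one_sided(a, b) == pytest.approx(1 / 64)

    def test_all_zero_differences_undefined(self):
        a = np.arange(8.0)
        assert np.isnan(wilcoxon_one_sided(a, a))

    def test_swapping_samples_complements_p(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.3, 1, size=6)
        b = rng.normal(0, 1, size=6)
        p_ab = wilcoxon_one_sided(a, b)
        p_ba = wilcoxon_one_sided(b, a)
        p_eq = wilcoxon_enumeration(a, b) - (1 - wilcoxon_enumeration(b, a))
        assert p_ab + p_ba == pytest.approx(1 + p_eq)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sign_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        a = rng.integers(-3, 6, size=n).astype(float)
        b = np.zeros(n)
        if np.all(a == 0):
            a[0] = 1.0
        assert wilcoxon_one_sided(a, b) == pytest.approx(wilcoxon_enumeration(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.5, 1, size=12)
        b = rng.normal(0.0, 1, size=12)
        ours = wilcoxon_one_sided(a, b)
        ref = stats.wilcoxon(a, b, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.3, 1, size=60)
        b = rng.normal(0.0, 1, size=60)
        ours = wilcoxon_one_sided(a, b)
        ref = stats.wilcoxon(a, b, alternative="greater", method="approx",
                             correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            wilcoxon_one_sided([1.0, 2.0], [1.0])
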