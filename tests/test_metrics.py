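"""DSC / HD95 against brute-force oracles; cohort summaries; mask
interchangeability features (HU histograms, fibrosis-index surrogate)."""

import numpy as np
import pytest

import murineseg as ms
from murineseg.errors import EmptyMaskError, GridMismatchError, UndefinedMetricError
from murineseg.metrics import cohort_mean_sem, lung_histogram, surface_voxels

from conftest import random_blob_mask


def _mask(data, spacing=(0.35, 0.35, 0.35)):
    return ms.Mask(np.asarray(data, dtype=np.uint8), spacing)


# -- brute-force oracles -----------------------------------------------------

def _dice_bruteforce(a, b):
    A = {tuple(i) for i in np.argwhere(a.data)}
    B = {tuple(i) for i in np.argwhere(b.data)}
    if not A and not B:
        return 1.0
    return 2 * len(A & B) / (len(A) + len(B))


def _percentile_linear(values, q):
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


def _hd95_bruteforce(a, b):
    sp = np.array(a.spacing)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = [min(np.sqrt(((p - q) ** 2).sum()) for q in pb) for p in pa]
    d_ba = [min(np.sqrt(((p - q) ** 2).sum()) for q in pa) for p in pb]
    return _percentile_linear(d_ab + d_ba, 95)


class TestDice:
    def test_identical_masks(self):
        m = _mask(np.ones((3, 3, 3)))
        assert ms.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((2, 2, 2)); a[0, 0, 0] = 1
        b = np.zeros((2, 2, 2)); b[1, 1, 1] = 1
        assert ms.dice(_mask(a), _mask(b)) == 0.0

    def test_known_overlap(self):
        a = np.zeros((1, 10, 20)); a[0, :, :10] = 1   # |A| = 100
        b = np.zeros((1, 10, 20)); b[0, :, 2:12] = 1  # |B| = 100, overlap 80
        assert ms.dice(_mask(a), _mask(b)) == pytest.approx(0.8)

    def test_both_empty_is_one_with_warning(self):
        e = _mask(np.zeros((2, 2, 2)))
        with pytest.warns(UserWarning):
            assert ms.dice(e, e) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            ms.dice(_mask(np.ones((2, 2, 2))), _mask(np.ones((2, 2, 3))))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng)
        b = random_blob_mask(rng)
        assert ms.dice(a, b) == pytest.approx(_dice_bruteforce(a, b), abs=0)


class TestHD95:
    def test_identical_masks_zero(self):
        rng = np.random.default_rng(0)
        m = random_blob_mask(rng)
        assert ms.hd95(m, m) == 0.0

    def test_parallel_plates_three_voxels_apart(self):
        a = np.zeros((7, 5, 5)); a[1] = 1
        b = np.zeros((7, 5, 5)); b[4] = 1
        assert ms.hd95(_mask(a), _mask(b)) == pytest.approx(1.05)  # 3 * 0.35 mm

    def test_scales_linearly_with_spacing(self):
        a = np.zeros((7, 5, 5)); a[1] = 1
        b = np.zeros((7, 5, 5)); b[4] = 1
        d1 = ms.hd95(_mask(a), _mask(b), spacing=(0.2, 0.2, 0.2))
        d2 = ms.hd95(_mask(a), _mask(b), spacing=(0.4, 0.4, 0.4))
        assert d2 == pytest.approx(2 * d1)

    def test_empty_mask_undefined(self):
        m = _mask(np.ones((2, 2, 2)))
        e = _mask(np.zeros((2, 2, 2)))
        with pytest.raises(UndefinedMetricError):
            ms.hd95(m, e)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_on_random_masks(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a = random_blob_mask(rng)
        b = random_blob_mask(rng)
        assert ms.hd95(a, b) == pytest.approx(_hd95_bruteforce(a, b), abs=1e-9)

    def test_max_directed_variant_at_least_pooled_95th(self):
        rng = np.random.default_rng(7)
        a = random_blob_mask(rng)
        b = random_blob_mask(rng)
        assert ms.hd95(a, b, variant="max_directed") >= 0.0


class TestSummarize:
    def test_median_of_three(self):
        rep = ms.summarize([{"subject": i, "dsc": v} for i, v in enumerate([0.9, 1.0, 0.8])])
        assert rep.summary.loc["dsc", "median"] == pytest.approx(0.9)

    def test_single_record_collapses(self):
        rep = ms.summarize([{"subject": 0, "dsc": 0.75, "hd95": 1.2}])
        row = rep.summary.loc["dsc"]
        assert row["median"] == row["q25"] == row["q75"] == 0.75

    def test_matches_independent_percentile_rule(self):
        rng = np.random.default_rng(0)
        vals = rng.random(154)
        rep = ms.summarize([{"subject": i, "dsc": v} for i, v in enumerate(vals)])
        assert rep.summary.loc["dsc", "median"] == pytest.approx(_percentile_linear(vals, 50))
        assert rep.summary.loc["dsc", "q25"] == pytest.approx(_percentile_linear(vals, 25))
        assert rep.summary.loc["dsc", "q75"] == pytest.approx(_percentile_linear(vals, 75))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ms.summarize([])


class TestHistogramsAndFI:
    def test_single_bin_histogram(self):
        # ten in-mask voxels all at -750 HU: one occupied bin with count 10
        v = ms.Volume(np.full((1, 2, 5), -750.0), (0.35, 0.35, 0.35))
        m = _mask(np.ones((1, 2, 5)))
        edges = np.arange(-1100, 101, 50)
        hist = lung_histogram(v, m, edges)
        assert hist.sum() == 10
        assert np.count_nonzero(hist) == 1
        assert hist[np.digitize(-750, edges) - 1] == 10

    def test_identical_subjects_sem_zero(self):
        h = np.array([1.0, 2.0, 3.0])
        mean, sem = cohort_mean_sem([h, h])
        np.testing.assert_array_equal(mean, h)
        np.testing.assert_array_equal(sem, 0.0)

    def test_fibrosis_index_zero_for_healthy(self):
        v = ms.Volume(np.full((2, 2, 2), -750.0), (0.35, 0.35, 0.35))
        m = _mask(np.ones((2, 2, 2)))
        assert ms.fibrosis_index(v, m) == 0.0

    def test_fibrosis_index_matches_generated_fraction(self):
        spec = ms.PhantomSpec(fibrosis_fraction=0.3, noise_sd_hu=0.0)
        vol, mask = ms.generate_mouse(spec, seed=11)
        n = mask.num_voxels()
        assert ms.fibrosis_index(vol, mask) == pytest.approx(0.3, abs=1.0 / n + 1e-12)

    def test_fibrosis_index_monotone_in_severity(self):
        vals = []
        for frac in (0.0, 0.15, 0.35):
            vol, mask = ms.generate_mouse(
                ms.PhantomSpec(fibrosis_fraction=frac, noise_sd_hu=0.0), seed=3
            )
            vals.append(ms.fibrosis_index(vol, mask))
        assert vals == sorted(vals) and vals[0] < vals[1] < vals[2]

    def test_empty_mask_rejected(self):
        v = ms.Volume(np.zeros((2, 2, 2)), (0.35, 0.35, 0.35))
        e = _mask(np.zeros((2, 2, 2)))
        with pytest.raises(EmptyMaskError):
            ms.fibrosis_index(v, e)
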