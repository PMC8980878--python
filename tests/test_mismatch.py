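"""Registration recovery, template building and z-score mismatch maps."""

import numpy as np
import pytest
from scipy import ndimage

import murineseg as ms
from murineseg.errors import GridMismatchError
from murineseg.mismatch import (
    MismatchMap,
    RegistrationConfig,
    build_template,
    difference_map,
    register_to_template,
    warp,
    zscore_map,
)

AFFINE_ONLY = RegistrationConfig(do_bspline=False)


class TestDifferenceMap:
    def test_identical_masks_all_zero(self, quiet_mouse):
        _, _, mask, _ = quiet_mouse
        d = difference_map(mask, mask)
        assert not d.data.any()

    def test_sign_convention_reference_minus_network(self):
        ref = ms.Mask(np.ones((2, 2, 2), dtype=np.uint8), (1, 1, 1))
        cnn = ms.Mask(np.zeros((2, 2, 2), dtype=np.uint8), (1, 1, 1))
        d = difference_map(ref, cnn)
        assert np.all(d.data == 1)  # under-segmentation is positive

    def test_values_and_sum_identity(self):
        rng = np.random.default_rng(0)
        a = ms.Mask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8), (1, 1, 1))
        b = ms.Mask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8), (1, 1, 1))
        d = difference_map(a, b)
        assert set(np.unique(d.data)) <= {-1.0, 0.0, 1.0}
        assert d.data.sum() == a.num_voxels() - b.num_voxels()
        np.testing.assert_array_equal(difference_map(b, a).data, -d.data)

    def test_grid_mismatch_rejected(self):
        a = ms.Mask(np.zeros((2, 2, 2), dtype=np.uint8), (1, 1, 1))
        b = ms.Mask(np.zeros((2, 2, 3), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(GridMismatchError):
            difference_map(a, b)


class TestZscore:
    def test_hand_computed_population_z(self):
        shape = (1, 1, 1)
        diffs = [
            ms.Volume(np.full(shape, v), (1, 1, 1), (0, 0, 0), "difference")
            for v in (1.0, 1.0, 1.0, 0.0)
        ]
        mm = zscore_map(diffs)
        # mean 0.75, population sd sqrt(3)/4 = 0.4330 -> z = 1.7320
        assert mm.z.data[0, 0, 0] == pytest.approx(np.sqrt(3), abs=1e-12)
        assert mm.valid[0, 0, 0]
        assert mm.count[0, 0, 0] == 4

    def test_zero_variance_masked_not_infinite(self):
        diffs = [
            ms.Volume(np.zeros((2, 2, 2)), (1, 1, 1), (0, 0, 0), "difference")
            for _ in range(3)
        ]
        mm = zscore_map(diffs)
        assert not mm.valid.any()
        assert np.isfinite(mm.z.data).all()
        assert not mm.z.data.any()

    def test_needs_two_subjects(self):
        d = ms.Volume(np.zeros((2, 2, 2)), (1, 1, 1), (0, 0, 0), "difference")
        with pytest.raises(ValueError):
            zscore_map([d])

    def test_systematic_interface_error_makes_local_hotspot(self):
        rng = np.random.default_rng(0)
        diffs = []
        injected = np.zeros(ms.PhantomSpec().grid_shape, dtype=bool)
        for i in range(8):
            v, m, parts = ms.generate_mouse(ms.PhantomSpec(noise_sd_hu=0.0), seed=50 + i, parts=True)
            interface = ndimage.binary_dilation(m.bool()) & parts["heart"]
            injected |= interface
            over = interface & (rng.random(interface.shape) < 0.7)
            sporadic = (m.bool() & ~ndimage.binary_erosion(m.bool())) & (rng.random(m.shape) < 0.01)
            cnn = (m.bool() | over) & ~sporadic
            diffs.append(difference_map(m, ms.Mask(cnn.astype(np.uint8), m.spacing, m.origin)))
        mm = zscore_map(diffs)
        peak = mm.hotspot()
        assert mm.z.data[peak] < 0  # over-segmentation is negative
        dist = ndimage.distance_transform_edt(~injected)
        assert dist[peak] <= 2.0


class TestRegistration:
    def test_self_registration_is_identity(self, noisy_mouse):
        _, vol, _ = noisy_mouse
        t = register_to_template(vol, vol, AFFINE_ONLY)
        w = warp(vol, t, vol)
        # mean displacement < 0.5 voxel shows up as a tiny residual
        core = (slice(4, -4),) * 3
        assert np.abs(w.data - vol.data)[core].mean() < 5.0

    def test_known_translation_recovered_within_half_voxel(self, noisy_mouse):
        _, vol, _ = noisy_mouse
        shift = (2, 3, -2)  # voxels, (z, y, x)
        moved = ms.Volume(np.roll(vol.data, shift, axis=(0, 1, 2)), vol.spacing, vol.origin, "HU")
        t = register_to_template(moved, vol, AFFINE_ONLY)
        pt = [vol.origin[2] + 32 * 0.35, vol.origin[1] + 32 * 0.35, vol.origin[0] + 24 * 0.35]
        mapped = t.TransformPoint(pt)
        rec_xyz = [(m - p) / 0.35 for m, p in zip(mapped, pt)]
        # the resampling transform maps fixed (reference) points into the
        # moving volume: rolling content by +s means T(x) = x + s
        expected_xyz = (shift[2], shift[1], shift[0])
        for r, e in zip(rec_xyz, expected_xyz):
            assert abs(r - e) <= 0.5

    def test_warped_mask_stays_binary(self, noisy_mouse):
        _, vol, mask = noisy_mouse
        moved = ms.Volume(np.roll(vol.data, (1, 2, 0), axis=(0, 1, 2)), vol.spacing, vol.origin, "HU")
        t = register_to_template(moved, vol, AFFINE_ONLY)
        wm = warp(mask, t, vol)
        assert isinstance(wm, ms.Mask)
        assert set(np.unique(wm.data)) <= {0, 1}


class TestTemplate:
    def test_identical_inputs_reproduce_input(self, noisy_mouse):
        _, vol, _ = noisy_mouse
        tmpl = build_template([vol, vol], n_iter=0, cfg=AFFINE_ONLY)
        core = (slice(6, -6),) * 3
        assert np.abs(tmpl.data - vol.data)[core].mean() < 5.0

    def test_translated_pair_midpoint_alignment(self, noisy_mouse):
        _, vol, _ = noisy_mouse
        moved = ms.Volume(np.roll(vol.data, (0, 4, 0), axis=(0, 1, 2)), vol.spacing, vol.origin, "HU")
        tmpl = build_template([vol, moved], n_iter=1, cfg=AFFINE_ONLY)
        # the mean template keeps a single sharp body: its center of mass sits
        # within a voxel of the first volume's (registration target) center
        w = vol.data - vol.data.min()
        wt = tmpl.data - tmpl.data.min()
        com_in = ndimage.center_of_mass(w)
        com_tmpl = ndimage.center_of_mass(wt)
        assert all(abs(a - b) < 1.0 for a, b in zip(com_in, com_tmpl))
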