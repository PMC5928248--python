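"""Realignment, smoothing and masking against independent oracles."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from rtnf.errors import MaskError
from rtnf.phantom import brain_ellipsoid
from rtnf.preproc import (
    FWHM_TO_SIGMA,
    RigidTransform,
    apply_rigid,
    center_of_mass_mm,
    default_affine,
    make_mask,
    realign,
    smooth,
    OnlinePreprocessor,
)

AFFINE = default_affine((3.0, 3.0, 3.0))


def textured_brain(grid=(32, 32, 20), seed=0):
    """Ellipsoid phantom with smooth texture so registration is well-posed."""
    rng = np.random.default_rng(seed)
    brain = brain_ellipsoid(grid)
    img = np.where(brain, 100.0, 0.0)
    img += ndimage.gaussian_filter(rng.standard_normal(grid), 2) * 30 * brain
    return img


class TestVolume:
    def test_rejects_non_finite_data(self):
        from rtnf.preproc import Volume

        bad = np.zeros((4, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume(bad, AFFINE)

    def test_rejects_singular_affine(self):
        from rtnf.preproc import Volume

        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), np.zeros((4, 4)))

    def test_voxel_size_from_affine(self):
        from rtnf.preproc import Volume

        v = Volume(np.zeros((4, 4, 4)), AFFINE)
        np.testing.assert_allclose(v.voxel_mm, [3, 3, 3])


class TestRigidTransform:
    def test_inverse_round_trip_is_identity(self):
        t = RigidTransform(3.0, -2.0, 1.5, 0.04, -0.03, 0.05)
        round_trip = t.compose(t.inverse())
        assert np.abs(round_trip.as_params()).max() < 1e-8

    def test_matrix_translation_only(self):
        t = RigidTransform(1.0, 2.0, 3.0)
        m = t.matrix(center_mm=(10, 10, 10))
        np.testing.assert_allclose(m[:3, :3], np.eye(3))
        np.testing.assert_allclose(m[:3, 3], [1, 2, 3])


class TestRealign:
    def test_identity_gives_zero_parameters(self):
        ref = textured_brain()
        est, _, _ = realign(ref, ref, AFFINE)
        assert np.abs(est.as_params()).max() < 1e-3

    def test_pure_translation_recovered_with_independent_resampler(self):
        # oracle: scipy.ndimage.shift, independent of apply_rigid
        ref = textured_brain()
        moved = ndimage.shift(ref, (1.0, 0, 0), order=1)   # +1 voxel = +3 mm x
        est, resampled, _ = realign(moved, ref, AFFINE)
        assert abs(est.tx - (-3.0)) < 0.2
        assert np.abs([est.ty, est.tz, est.rx, est.ry, est.rz]).max() < 0.2
        # and the resampled volume actually matches the reference
        brain = ref > 50
        assert np.abs(resampled[brain] - ref[brain]).mean() < 2.0

    def test_small_z_rotation_recovered(self):
        # oracle: scipy.ndimage.rotate in the xy plane, independent path
        ref = textured_brain()
        deg = np.degrees(0.05)
        moved = ndimage.rotate(ref, deg, axes=(0, 1), reshape=False, order=1)
        est, _, _ = realign(moved, ref, AFFINE)
        assert abs(abs(est.rz) - 0.05) < 0.01
        assert np.abs([est.rx, est.ry]).max() < 0.01
        assert np.abs(est.translation).max() < 0.5

    def test_parameter_recovery_rmse_over_seeds(self):
        """inject(T) then realign recovers T^-1 within 0.3 mm / 0.02 rad RMSE."""
        ref = textured_brain()
        com = center_of_mass_mm(ref, AFFINE)
        errs = []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            true = RigidTransform(
                *rng.uniform(-5, 5, 3), *rng.uniform(-0.05, 0.05, 3)
            )
            moved = apply_rigid(ref, true, AFFINE, center_mm=com)
            est, _, _ = realign(moved, ref, AFFINE)
            errs.append(est.as_params() - true.inverse().as_params())
        errs = np.array(errs)
        assert np.sqrt((errs[:, :3] ** 2).mean()) < 0.3
        assert np.sqrt((errs[:, 3:] ** 2).mean()) < 0.02


class TestSmooth:
    def test_fwhm_sigma_conversion(self):
        assert 8.0 * FWHM_TO_SIGMA == pytest.approx(3.39728, abs=1e-5)

    def test_constant_image_preserved(self):
        img = np.full((14, 14, 9), 7.3)
        out = smooth(img, 8.0, (3, 3, 3))
        assert np.abs(out - 7.3).max() < 1e-10

    def test_impulse_matches_direct_summation_oracle(self):
        grid = (15, 15, 9)
        img = np.zeros(grid)
        center = (7, 7, 4)
        img[center] = 1.0
        fwhm, vox = 8.0, 3.0
        out = smooth(img, fwhm, (vox, vox, vox))

        # brute-force: normalised truncated-Gaussian weights by direct summation
        sigma_vox = fwhm * FWHM_TO_SIGMA / vox
        radius = int(4.0 * sigma_vox + 0.5)   # scipy's default truncation
        ax = np.arange(-radius, radius + 1)
        w1 = np.exp(-0.5 * (ax / sigma_vox) ** 2)
        w1 /= w1.sum()
        expected = np.zeros(grid)
        norm = np.zeros(grid)
        for i in range(grid[0]):
            for j in range(grid[1]):
                for k in range(grid[2]):
                    acc = 0.0
                    nrm = 0.0
                    for di in ax:
                        for dj in ax:
                            for dk in ax:
                                wijk = w1[di + radius] * w1[dj + radius] * w1[dk + radius]
                                si, sj, sk = i + di, j + dj, k + dk
                                if 0 <= si < grid[0] and 0 <= sj < grid[1] and 0 <= sk < grid[2]:
                                    nrm += wijk
                                    acc += wijk * img[si, sj, sk]
                    expected[i, j, k] = acc / nrm
                    norm[i, j, k] = nrm
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_sum_conserved_for_interior_supported_image(self):
        # support must sit >= 2 kernel radii from the boundary so the
        # renormalised boundary kernel never touches the image mass
        rng = np.random.default_rng(1)
        img = np.zeros((26, 26, 26))
        img[11:15, 11:15, 11:15] = rng.uniform(50, 150, (4, 4, 4))
        out = smooth(img, 8.0, (3, 3, 3))
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-8


def flood_fill_components(binary):
    """Independent 26-connectivity component labelling by BFS."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.append(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[d] < binary.shape[d] for d in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)
        comps.append(comp)
    return comps


class TestMakeMask:
    def test_bimodal_phantom_recovers_brain_exactly(self):
        brain = brain_ellipsoid((16, 16, 10))
        mean = np.where(brain, 100.0, 0.0)
        np.testing.assert_array_equal(make_mask(mean, 0.5), brain)

    def test_high_threshold_still_below_plateau(self):
        brain = brain_ellipsoid((16, 16, 10))
        mean = np.where(brain, 100.0, 0.0)
        np.testing.assert_array_equal(make_mask(mean, 0.95), brain)

    def test_keeps_largest_of_two_blobs(self):
        img = np.zeros((20, 20, 12))
        img[2:8, 2:8, 2:8] = 100.0       # 216 voxels
        img[14:17, 14:17, 2:5] = 100.0   # 27 voxels
        mask = make_mask(img, 0.5)
        comps = flood_fill_components(img >= 50)
        largest = max(comps, key=len)
        expected = np.zeros_like(mask)
        for v in largest:
            expected[v] = True
        np.testing.assert_array_equal(mask, expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(MaskError):
            make_mask(np.zeros((8, 8, 8)), 0.5)


def test_per_volume_processing_is_stateless(small_run):
    """Processing a volume alone equals processing it inside a stream."""
    data, _, mask, _ = small_run
    pre = OnlinePreprocessor(
        mean=data.mean(axis=-1), affine=AFFINE, mask=mask, fwhm_mm=8.0,
        do_realign=False,
    )
    _, full = pre.process_series(data[..., :5])
    _, single = pre.process(data[..., 3])
    np.testing.assert_array_equal(full[..., 3], single)
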