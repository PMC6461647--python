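"""Map postprocessing: cropping, masks, FSC machinery, resolution criteria,
directional FRC, sharpening, projection geometry."""

import numpy as np
import pytest

from xtal2p import maps, sim
from xtal2p.ctfgeom import EulerTriple


@pytest.fixture(scope="module")
def noise_pair():
    rng = np.random.default_rng(5)
    a = maps.Volume3D(rng.normal(size=(48, 48, 48)), 1.3)
    b = maps.Volume3D(rng.normal(size=(48, 48, 48)), 1.3)
    return a, b


class TestCropSubvolume:
    def test_identity_crop(self):
        vol = maps.Volume3D(np.random.default_rng(0).normal(size=(32,) * 3), 1.3)
        out = maps.crop_subvolume(vol, (0, 0, 0), 32)
        assert np.array_equal(out.data, vol.data)

    def test_index_bookkeeping_with_z_shift(self):
        n, size, dz = 128, 104, 12
        labels = np.arange(n**3, dtype=float).reshape(n, n, n)
        out = maps.crop_subvolume(maps.Volume3D(labels, 1.3), (0, 0, dz), size)
        off = n // 2 - size // 2
        assert out.data[0, 0, 0] == labels[off + dz, off, off]
        assert out.data[5, 3, 2] == labels[off + dz + 5, off + 3, off + 2]
        assert out.pixel_size == 1.3

    def test_out_of_bounds_rejected(self):
        vol = maps.Volume3D(np.zeros((64,) * 3), 1.0)
        with pytest.raises(ValueError, match="exceeds"):
            maps.crop_subvolume(vol, (0, 0, 40), 32)


class TestSoftMask:
    def test_pinned_edge_convention(self):
        box, radius, edge = 64, 20.0, 6.0
        m = maps.soft_spherical_mask(box, radius, edge)
        c = box // 2
        assert m[c, c, c + 20] == 1.0  # r = radius: plateau
        assert m[c, c, c + 23] == pytest.approx(0.5, abs=1e-12)  # r = radius+edge/2
        assert m[c, c, c + 26] == 0.0  # r = radius + edge
        assert m[c, c, c + 30] == 0.0

    def test_clipped_mask_warns(self):
        with pytest.raises(Warning):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("error")
                maps.soft_spherical_mask(32, 30.0, 6.0)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            maps.soft_spherical_mask(32, -1.0)


class TestFSC:
    def test_identical_maps_give_unity(self, noise_pair):
        a, _ = noise_pair
        curve = maps.fsc(a, a)
        assert np.all(np.abs(curve.values - 1.0) < 1e-10)

    def test_negated_map_gives_minus_one(self, noise_pair):
        a, _ = noise_pair
        curve = maps.fsc(a, maps.Volume3D(-a.data, a.pixel_size))
        assert np.all(np.abs(curve.values + 1.0) < 1e-10)

    def test_independent_noise_within_sampling_bound(self, noise_pair):
        a, b = noise_pair
        curve = maps.fsc(a, b)
        bound = 4.0 / np.sqrt(curve.n_voxels)
        assert (np.abs(curve.values) <= bound).mean() >= 0.95

    def test_invariant_under_common_integer_shift(self, noise_pair):
        a, b = noise_pair
        c1 = maps.fsc(a, b)
        sa = maps.Volume3D(np.roll(a.data, (3, -2, 5), (0, 1, 2)), 1.3)
        sb = maps.Volume3D(np.roll(b.data, (3, -2, 5), (0, 1, 2)), 1.3)
        c2 = maps.fsc(sa, sb)
        assert np.allclose(c1.values, c2.values, atol=1e-10)

    def test_shape_mismatch_rejected(self, noise_pair):
        a, _ = noise_pair
        with pytest.raises(ValueError):
            maps.fsc(a, maps.Volume3D(np.zeros((32,) * 3), 1.3))


class TestVolumeCorrection:
    def _curve(self, values):
        values = np.asarray(values, float)
        n = len(values)
        return maps.FSCCurve(np.arange(1, n + 1) / (64 * 1.3), values,
                             np.full(n, 100), 1.3, 64)

    def test_unity_fixed_point(self):
        out = maps.volume_correct_fsc(self._curve([1.0, 1.0]), 300.0, 100.0)
        assert np.allclose(out.values, 1.0)

    def test_identity_at_equal_volumes(self):
        c = self._curve([0.3, 0.7, 0.9])
        out = maps.volume_correct_fsc(c, 500.0, 500.0)
        assert np.allclose(out.values, c.values)

    def test_stated_example_value(self):
        out = maps.volume_correct_fsc(self._curve([0.1]), 200.0, 100.0)
        assert out.values[0] == pytest.approx(0.2 / 1.1, abs=1e-12)

    def test_never_decreases_magnitude_for_larger_mask(self):
        vals = np.linspace(-0.9, 0.95, 25)
        out = maps.volume_correct_fsc(self._curve(vals), 300.0, 100.0)
        assert np.all(np.abs(out.values) >= np.abs(vals) - 1e-12)
        assert np.all(np.sign(out.values) == np.sign(vals))
        # negative (noise) shells pass through untouched
        assert np.allclose(out.values[vals < 0], vals[vals < 0])

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            maps.volume_correct_fsc(self._curve([0.5]), 100.0, 200.0)


class TestResolutionThreshold:
    def _curve(self, values, pixel=1.0, box=64):
        values = np.asarray(values, float)
        n = len(values)
        return maps.FSCCurve(np.arange(1, n + 1) / (box * pixel), values,
                             np.full(n, 50), pixel, box)

    def test_identical_maps_hit_nyquist(self, noise_pair):
        a, _ = noise_pair
        curve = maps.fsc(a, a)
        assert maps.resolution_at_threshold(curve, 0.143) == 2 * a.pixel_size

    def test_linear_interpolation_oracle(self):
        # crossing 0.143 exactly halfway between shells 3 (0.5) and 4 (-0.214)
        vals = [0.9, 0.8, 0.5, -0.214]
        curve = self._curve(vals, pixel=1.0, box=64)
        f3, f4 = 3 / 64, 4 / 64
        frac = (0.5 - 0.143) / (0.5 - (-0.214))
        expected = 1.0 / (f3 + (f4 - f3) * frac)
        assert maps.resolution_at_threshold(curve, 0.143) == pytest.approx(
            expected, abs=1e-12
        )

    def test_below_threshold_everywhere_warns(self):
        curve = self._curve([0.5, 0.4, 0.3])
        with pytest.warns(UserWarning, match="lowest-frequency"):
            res = maps.resolution_at_threshold(curve, 1.0)
        assert res == pytest.approx(64.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vals = np.clip(np.linspace(1.0, -0.1, 30) + rng.normal(0, 0.02, 30), -1, 1)
        curve = self._curve(vals)
        res = [
            maps.resolution_at_threshold(curve, t) for t in (0.1, 0.143, 0.3, 0.5)
        ]
        assert all(r2 >= r1 - 1e-9 for r1, r2 in zip(res, res[1:]))


class TestHalfbitCurve:
    def _flat_curve(self, n_vox):
        n = len(n_vox)
        return maps.FSCCurve(np.arange(1, n + 1) / 64.0, np.ones(n),
                             np.asarray(n_vox), 1.0, 64)

    def test_limits(self):
        # n_eff = 1 gives threshold exactly 1; huge n_eff approaches 0.1716
        curve = self._flat_curve([1, 10**12])
        thr = maps.halfbit_curve(curve, particle_diameter=64.0, symmetry_order=1)
        assert thr[0] == pytest.approx(1.0, abs=1e-12)
        assert thr[1] == pytest.approx(0.2071 / 1.2071, abs=1e-4)

    def test_strictly_decreasing_with_shell_size(self):
        n_vox = (4 * np.pi * np.arange(1, 25) ** 2).astype(int)
        thr = maps.halfbit_curve(self._flat_curve(n_vox), 40.0, 4)
        assert np.all(np.diff(thr) < 0)

    def test_symmetry_raises_threshold(self):
        curve = self._flat_curve([500, 2000])
        t1 = maps.halfbit_curve(curve, 40.0, 1)
        t4 = maps.halfbit_curve(curve, 40.0, 4)
        assert np.all(t4 > t1)

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError):
            maps.halfbit_curve(self._flat_curve([10]), 100.0, 1, box=64, pixel_size=1.0)


class TestDirectionalFRC:
    def test_identical_maps_unity(self, noise_pair):
        a, _ = noise_pair
        for plane in ("xy", "xz", "yz"):
            curve = maps.directional_frc(a, a, plane)
            assert np.all(np.abs(curve.values - 1.0) < 1e-10)

    def test_constructed_anisotropy(self):
        # shared signal band-limited on an ellipsoid: full bandwidth in
        # plane, compressed along kz (a missing-cone-like spectrum), plus
        # independent noise per half.  The xz-plane crossing must move to a
        # coarser resolution than the xy-plane one, while an isotropically
        # band-limited pair keeps the two planes equivalent.  The shift is
        # moderate by construction: rings in the xz plane keep their
        # correlated low-kz sectors, exactly as in real half-maps.
        rng = np.random.default_rng(11)
        n = 48
        k = np.fft.fftfreq(n) * n
        kzg, kyg, kxg = k[:, None, None], k[None, :, None], k[None, None, :]

        def bandlimit(vol, z_keep, xy_keep):
            ft = np.fft.fftn(vol)
            outside = (kzg / z_keep) ** 2 + (kyg**2 + kxg**2) / xy_keep**2 > 1.0
            ft[outside] = 0
            return np.fft.ifftn(ft).real

        common = rng.normal(size=(n,) * 3)
        noise1, noise2 = rng.normal(size=(n,) * 3), rng.normal(size=(n,) * 3)

        def halves(z_keep):
            sig = 5.0 * bandlimit(common, z_keep, 20)
            return (
                maps.Volume3D(sig + noise1, 1.0),
                maps.Volume3D(sig + noise2, 1.0),
            )

        res = {
            (tag, plane): maps.resolution_at_threshold(
                maps.directional_frc(*halves(z_keep), plane), 0.143
            )
            for tag, z_keep in (("iso", 20), ("ani", 3))
            for plane in ("xy", "xz")
        }
        assert res[("ani", "xz")] > 1.05 * res[("ani", "xy")]
        assert abs(res[("iso", "xz")] - res[("iso", "xy")]) <= 0.03 * res[("iso", "xy")]
        assert abs(res[("ani", "xy")] - res[("iso", "xy")]) <= 0.10 * res[("iso", "xy")]

    def test_c4_volume_has_equal_xz_yz(self):
        rng = np.random.default_rng(12)
        raw = rng.normal(size=(48, 48, 48))
        sym = sum(np.rot90(raw, k, axes=(1, 2)) for k in range(4)) / 4.0
        raw2 = rng.normal(size=(48, 48, 48))
        sym2 = sum(np.rot90(raw2, k, axes=(1, 2)) for k in range(4)) / 4.0
        a, b = maps.Volume3D(sym, 1.0), maps.Volume3D(sym2, 1.0)
        xz = maps.directional_frc(a, b, "xz")
        yz = maps.directional_frc(a, b, "yz")
        assert np.allclose(xz.values, yz.values, atol=1e-6)


class TestSharpening:
    def test_identity_at_zero_b_and_nyquist_lowpass(self):
        vol = maps.Volume3D(np.random.default_rng(0).normal(size=(32,) * 3), 1.0)
        out = maps.bfactor_sharpen(vol, 0.0, lowpass=2.0)
        assert np.abs(out.data - vol.data).max() < 1e-10

    def test_amplitude_ratio_at_quarter_inverse_angstrom(self):
        n = 64  # pixel 1.0 A: shell k=16 sits exactly at s = 0.25 1/A
        vol = maps.Volume3D(np.random.default_rng(1).normal(size=(n,) * 3), 1.0)
        out = maps.bfactor_sharpen(vol, -100.0)
        f_in = np.fft.fftn(vol.data)
        f_out = np.fft.fftn(out.data)
        ratio = np.abs(f_out[0, 0, 16]) / np.abs(f_in[0, 0, 16])
        assert ratio == pytest.approx(np.exp(100 * 0.0625 / 4.0), rel=1e-8)

    def test_sharpen_blur_inverse(self):
        vol = maps.Volume3D(np.random.default_rng(2).normal(size=(32,) * 3), 1.0)
        out = maps.bfactor_sharpen(maps.bfactor_sharpen(vol, -80.0), 80.0)
        assert np.abs(out.data - vol.data).max() < 1e-8

    def test_sub_nyquist_lowpass_rejected(self):
        vol = maps.Volume3D(np.zeros((32,) * 3), 1.3)
        with pytest.raises(ValueError, match="Nyquist"):
            maps.bfactor_sharpen(vol, 0.0, lowpass=1.0)


class TestProjectionGeometry:
    def test_untilted_projection_is_z_sum(self, phantom):
        p = maps.project(phantom.data, EulerTriple())
        assert np.abs(p - phantom.data.sum(axis=0)).max() < 1e-12

    def test_c4_phantom_projections_repeat_every_90_degrees(self, phantom):
        pa = maps.project(phantom.data, EulerTriple(10.0, 30.0, 5.0))
        pb = maps.project(phantom.data, EulerTriple(100.0, 30.0, 5.0))
        assert np.abs(pa - pb).max() < 1e-6 * np.abs(pa).max()

    def test_backprojection_round_trip(self, phantom):
        rng = np.random.default_rng(0)
        eulers = [
            EulerTriple(
                rng.uniform(0, 360),
                np.rad2deg(np.arccos(rng.uniform(-1, 1))),
                rng.uniform(0, 360),
            )
            for _ in range(60)
        ]
        imgs = np.stack([maps.project(phantom.data, e) for e in eulers])
        rec = maps.backproject(imgs, eulers, pixel_size=phantom.pixel_size)
        lp = 3 * phantom.pixel_size
        a = maps.bfactor_sharpen(phantom, 0.0, lowpass=lp).data
        b = maps.bfactor_sharpen(rec, 0.0, lowpass=lp).data
        mask = maps.soft_spherical_mask(phantom.box, 18, 4)
        am, bm = (a * mask).ravel(), (b * mask).ravel()
        am -= am.mean()
        bm -= bm.mean()
        corr = am @ bm / np.sqrt((am @ am) * (bm @ bm))
        assert corr >= 0.95
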