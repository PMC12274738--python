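"""Acquisition simulation, gridding, rigid registration and stitching."""

import numpy as np
import pytest

import spiralscan as ss
from spiralscan.scan_sim import PointScan


@pytest.fixture(scope="module")
def phantom():
    return ss.make_phantom(style="parallel", size=256, seed=2)


class TestAcquire:
    def test_constant_phantom_constant_amplitudes(self, phantom):
        ph = ss.make_phantom(style="parallel", size=128, seed=1)
        ph.mu_a[532][:] = 3.25  # uniform scene
        tr = ss.make_trajectory(ss.SpiralParams(pattern="AS", n_points=2048))
        prs = ss.acquire(ph, tr, noise_sigma=0.0, wavelength=532)
        assert np.allclose(prs.amplitude, 3.25)

    def test_pixel_center_sampling_is_exact(self, phantom):
        scan = ss.pixel_center_scan(phantom.shape, phantom.pixel_size)
        prs = ss.acquire(phantom, scan, wavelength=532)
        assert np.allclose(prs.amplitude, phantom.mu_a[532].ravel())

    def test_fixed_seed_reproducible(self, phantom):
        tr = ss.make_trajectory(ss.SpiralParams(pattern="AFS", n_points=4096))
        a = ss.acquire(phantom, tr, noise_sigma=0.1, seed=9, dual_wavelength=True)
        b = ss.acquire(phantom, tr, noise_sigma=0.1, seed=9, dual_wavelength=True)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert a.n_records == 2 * tr.n_points
        assert (a.amplitude >= 0).all()

    def test_out_of_extent_rejected(self, phantom):
        scan = PointScan(x=np.array([0.0, 3.0]), y=np.zeros(2), t=np.arange(2.0))
        with pytest.raises(ValueError, match="pulse 1"):
            ss.acquire(phantom, scan)

    def test_csv_round_trip(self, phantom, tmp_path):
        tr = ss.make_trajectory(ss.SpiralParams(pattern="AS", n_points=1024))
        prs = ss.acquire(phantom, tr, dual_wavelength=True)
        prs.to_csv(tmp_path / "r.csv")
        back = ss.PulseRecordSet.from_csv(tmp_path / "r.csv")
        assert np.allclose(back.amplitude, prs.amplitude)
        assert set(back.wavelengths()) == {532, 558}


class TestReconstruct:
    def test_dense_noiseless_round_trip_exact(self, phantom):
        scan = ss.pixel_center_scan(phantom.shape, phantom.pixel_size)
        prs = ss.acquire(phantom, scan, wavelength=532)
        img = ss.reconstruct(prs, 256, phantom.pixel_size)
        assert img.fill_mask.all()
        assert np.array_equal(img.pixels, phantom.mu_a[532])

    def test_bin_mean_averages_samples(self):
        prs = ss.PulseRecordSet(
            t=np.arange(2.0), x=np.array([0.05, 0.4]), y=np.zeros(2),
            wavelength=np.full(2, 532), amplitude=np.array([1.0, 3.0]),
        )
        img = ss.reconstruct(prs, 4, pixel_size=0.5)
        assert img.pixels.max() == 2.0  # both samples land in one half-open cell
        assert img.fill_mask.sum() == 1

    def test_empty_records_rejected(self):
        prs = ss.PulseRecordSet(
            t=np.zeros(0), x=np.zeros(0), y=np.zeros(0),
            wavelength=np.zeros(0, int), amplitude=np.zeros(0),
        )
        with pytest.raises(ValueError, match="empty"):
            ss.reconstruct(prs, 8, 0.25)

    def test_wavelength_selection_required_for_dual(self, phantom):
        tr = ss.make_trajectory(ss.SpiralParams(pattern="AS", n_points=1024))
        prs = ss.acquire(phantom, tr, dual_wavelength=True)
        with pytest.raises(ValueError, match="wavelength"):
            ss.reconstruct(prs, 64, 2.0 / 64)
        img = ss.reconstruct(prs, 64, 2.0 / 64, wavelength=558)
        assert img.wavelength == 558

    def test_interpolation_fills_gaps(self, phantom):
        tr = ss.make_trajectory(ss.SpiralParams(pattern="AFS", n_points=8192))
        prs = ss.acquire(phantom, tr, wavelength=532)
        raw = ss.reconstruct(prs, 256, phantom.pixel_size, method="bin_mean")
        lin = ss.reconstruct(prs, 256, phantom.pixel_size, method="linear")
        assert not raw.fill_mask.all()
        assert lin.interpolated and not raw.interpolated
        assert np.isfinite(lin.pixels).all()

    def test_edge_rmse_compound_beats_archimedes(self, phantom):
        """Mirrors the rim-undersampling contrast between AS and A-FS scans."""
        from spiralscan._grid import pixel_radius_map

        truth = phantom.mu_a[532]
        rmap = pixel_radius_map((256, 256), phantom.pixel_size)
        edge = (rmap > 0.8) & (rmap <= 1.0)
        rmse = {}
        for pat in ("AS", "AFS"):
            tr = ss.make_trajectory(ss.SpiralParams(pattern=pat))
            img = ss.reconstruct(ss.acquire(phantom, tr, wavelength=532), 256, phantom.pixel_size)
            rmse[pat] = np.sqrt(np.mean((img.pixels[edge] - truth[edge]) ** 2))
        assert rmse["AFS"] < rmse["AS"]

    def test_rmse_decreases_with_point_budget(self, phantom):
        truth = phantom.mu_a[532]
        rmses = []
        for n in (8192, 33332, 131072):
            tr = ss.make_trajectory(ss.SpiralParams(pattern="AFS", n_points=n))
            img = ss.reconstruct(ss.acquire(phantom, tr, wavelength=532), 256, phantom.pixel_size)
            rmses.append(np.sqrt(np.mean((img.pixels - truth) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]


class TestRigid:
    def test_identity_for_aligned_landmarks(self, rng):
        pts = rng.uniform(-1, 1, (5, 2))
        tr = ss.fit_rigid(pts, pts)
        assert tr.rotation == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.translation, 0.0, atol=1e-12)
        assert tr.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self, rng):
        alpha, dx, dy = 0.3, 0.5, -0.2
        m = rng.uniform(-1, 1, (4, 2))
        R = np.array([[np.cos(alpha), -np.sin(alpha)], [np.sin(alpha), np.cos(alpha)]])
        f = m @ R.T + [dx, dy]
        tr = ss.fit_rigid(m, f)
        assert tr.rotation == pytest.approx(alpha, abs=1e-12)
        assert tr.translation[0] == pytest.approx(dx, abs=1e-12)
        assert tr.translation[1] == pytest.approx(dy, abs=1e-12)
        assert np.allclose(tr.apply(m), f, atol=1e-12)

    def test_residual_tracks_jitter(self, rng):
        m = rng.uniform(-1, 1, (20, 2))
        res = []
        for sigma in (0.01, 0.05):
            f = m + rng.normal(0, sigma, m.shape)
            res.append(ss.fit_rigid(m, f).residual_rms)
        assert 0.2 * 0.01 < res[0] < 3 * 0.01
        assert 0.2 * 0.05 < res[1] < 3 * 0.05
        assert res[1] > res[0]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.fit_rigid([[0, 0]], [[1, 1]])
        with pytest.raises(ValueError):
            ss.fit_rigid([[1, 1], [1, 1]], [[0, 0], [0, 0]])

    def test_pure_rotation_no_scale(self, rng):
        m = rng.uniform(-1, 1, (6, 2))
        f = 2.0 * m  # scaled: best rigid fit must still have det(R)=+1, no scale
        tr = ss.fit_rigid(m, f)
        assert np.linalg.det(tr.matrix) == pytest.approx(1.0)


class TestStitch:
    def test_identity_mosaic_equals_input(self, phantom):
        img = ss.ReconstructedImage(
            phantom.mu_a[532].copy(), np.ones(phantom.shape, bool), phantom.pixel_size
        )
        mosaic = ss.stitch([img], [ss.RigidTransform2D(0.0, (0.0, 0.0))])
        assert mosaic.shape == img.shape
        assert np.allclose(mosaic.pixels, img.pixels)

    def test_overlapping_crops_rebuild_scene(self, phantom):
        scene = phantom.mu_a[532]
        d = phantom.pixel_size
        a, b = scene[:, :160], scene[:, 96:]
        ims = [
            ss.ReconstructedImage(a.copy(), np.ones_like(a, bool), d),
            ss.ReconstructedImage(b.copy(), np.ones_like(b, bool), d),
        ]
        trs = [
            ss.RigidTransform2D(0.0, ((79.5 - 127.5) * d, 0.0)),
            ss.RigidTransform2D(0.0, (((96 + 255) / 2 - 127.5) * d, 0.0)),
        ]
        mosaic = ss.stitch(ims, trs, blend="feather_mean")
        assert mosaic.shape == scene.shape
        assert np.allclose(mosaic.pixels, scene, atol=1e-9)

    def test_disjoint_tiles_union(self):
        d = 0.01
        a = ss.ReconstructedImage(np.ones((20, 20)), np.ones((20, 20), bool), d)
        b = ss.ReconstructedImage(np.full((20, 20), 2.0), np.ones((20, 20), bool), d)
        mosaic = ss.stitch(
            [a, b],
            [ss.RigidTransform2D(0.0, (0.0, 0.0)), ss.RigidTransform2D(0.0, (40 * d, 0.0))],
        )
        assert mosaic.fill_mask.sum() == 800

    def test_bad_blend_mode(self):
        a = ss.ReconstructedImage(np.ones((4, 4)), np.ones((4, 4), bool), 0.1)
        with pytest.raises(ValueError):
            ss.stitch([a], [ss.RigidTransform2D(0.0, (0.0, 0.0))], blend="nope")
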