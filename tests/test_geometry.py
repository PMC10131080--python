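"""Projection, CTF, reconstruction and FSC primitives."""

import numpy as np
import pytest
from scipy.optimize import brentq

from scorevar.geometry import (CTFParams, Image2D, Pose, Volume, apply_ctf,
                               ctf_1d, fsc, fsc_resolution, lowpass_volume,
                               project, reconstruct, rotate_volume)

from conftest import make_blob_volume, make_sphere_volume, random_poses


def rel_rms(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2)))


class TestProject:
    def test_spherical_volume_projects_identically_at_any_pose(self, sphere_volume):
        # tolerance reflects the linear-interpolation budget of the
        # projector; the residual is rotation-variant interpolation error
        p1 = project(sphere_volume, Pose(10, 20, 30))
        p2 = project(sphere_volume, Pose(185, 77, 301))
        assert rel_rms(p1.grid, p2.grid) < 3e-3

    def test_intensity_conserved_over_pose_battery(self, blob_volume, rng):
        total = blob_volume.grid.sum()
        for pose in random_poses(50, rng, shift=2.0):
            proj = project(blob_volume, pose)
            assert abs(proj.grid.sum() / total - 1.0) < 1e-3

    def test_single_voxel_peak_matches_ray_summation_oracle(self):
        # brute-force oracle: rotate each voxel position actively and splat
        # its mass onto the xy plane with bilinear weights
        box, c = 32, 16
        vox = (21, 14, 19)  # (z, y, x)
        vol = np.zeros((box, box, box))
        vol[vox] = 1.0
        volume = Volume(vol, 2.0)
        pose = Pose(25, 40, 70)
        r = pose.matrix()

        oracle = np.zeros((box, box))
        pos = np.array([vox[2] - c, vox[1] - c, vox[0] - c], float)  # (x,y,z)
        x, y, _ = r @ pos
        ix, iy = int(np.floor(x + c)), int(np.floor(y + c))
        fx, fy = x + c - ix, y + c - iy
        for dy in (0, 1):
            for dx in (0, 1):
                w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                oracle[iy + dy, ix + dx] += w

        proj = project(volume, pose)
        iy0, ix0 = np.unravel_index(np.argmax(proj.grid), proj.grid.shape)
        iy1, ix1 = np.unravel_index(np.argmax(oracle), oracle.shape)
        assert abs(iy0 - iy1) <= 1 and abs(ix0 - ix1) <= 1
        # center of mass agrees sub-pixel
        yy, xx = np.mgrid[0:box, 0:box]
        com = lambda g: (np.sum(xx * g) / g.sum(), np.sum(yy * g) / g.sum())
        cx0, cy0 = com(np.clip(proj.grid, 0, None))
        cx1, cy1 = com(oracle)
        assert abs(cx0 - cx1) < 0.6 and abs(cy0 - cy1) < 0.6

    def test_rotation_composition(self, blob_volume):
        pose1 = Pose(40, 30, 10)
        pose2 = Pose(15, 60, 80)
        combined = Pose.from_matrix(pose1.matrix() @ pose2.matrix())
        a = project(blob_volume, combined)
        b = project(rotate_volume(blob_volume, pose2), pose1)
        assert rel_rms(a.grid, b.grid) < 0.02

    def test_mismatched_grid_raises(self, blob_volume):
        with pytest.raises(ValueError):
            Image2D(np.zeros((16, 24)), 2.0)


class TestCTF:
    def test_zero_frequency_equals_minus_amplitude_contrast(self):
        assert ctf_1d(np.array([0.0]), CTFParams(15000, amplitude_contrast=1.0))[0] == pytest.approx(-1.0)
        assert ctf_1d(np.array([0.0]), CTFParams(15000, amplitude_contrast=0.0))[0] == pytest.approx(0.0)
        assert ctf_1d(np.array([0.0]), CTFParams(15000, amplitude_contrast=0.07))[0] == pytest.approx(-0.07)

    def test_first_zero_matches_bisection_oracle(self, ctf_typical):
        ct = ctf_typical
        lam = ct.wavelength
        cs = ct.spherical_aberration * 1e7
        a = ct.amplitude_contrast

        def raw(k):
            chi = np.pi * lam * ct.defocus * k**2 - 0.5 * np.pi * lam**3 * cs * k**4
            return -(np.sqrt(1 - a * a) * np.sin(chi) + a * np.cos(chi))

        # oracle: first sign change of the closed-form expression
        ks = np.linspace(1e-5, 0.1, 20000)
        vals = raw(ks)
        i = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0][0]
        k_zero = brentq(raw, ks[i], ks[i + 1])

        implemented = ctf_1d(ks, ct)
        j = np.nonzero(np.sign(implemented[:-1]) != np.sign(implemented[1:]))[0][0]
        assert ks[j] <= k_zero <= ks[j + 1]

    def test_apply_ctf_acts_in_fourier_space(self, blob_volume, ctf_typical):
        img = project(blob_volume, Pose(10, 40, 5))
        out = apply_ctf(img, ctf_typical)
        f_in = np.fft.rfft2(img.grid.astype(float))
        f_out = np.fft.rfft2(out.grid)
        # DC ratio equals CTF(0) = -A
        assert f_out[0, 0] / f_in[0, 0] == pytest.approx(-0.07, abs=1e-6)


class TestReconstruct:
    def test_round_trip_error_below_ten_percent(self, rng):
        vol = make_blob_volume()
        poses = random_poses(200, rng)
        images = [project(vol, p) for p in poses]
        rec = reconstruct(images, poses)
        assert rel_rms(rec.grid, vol.grid) < 0.1

    def test_single_identity_image_gives_consistent_central_slab(self, blob_volume):
        img = project(blob_volume, Pose())
        rec = reconstruct([img], [Pose()], wiener=1e-3)
        # z-average of the reconstruction reproduces the projection shape
        slab = rec.grid.sum(axis=0)
        corr = np.corrcoef(slab.ravel(), img.grid.ravel())[0, 1]
        assert corr > 0.99

    def test_linearity(self, blob_volume, rng):
        poses = random_poses(20, rng)
        images = [project(blob_volume, p) for p in poses]
        rec1 = reconstruct(images, poses)
        scaled = [Image2D(i.grid * 3.0, i.pixel_size) for i in images]
        rec3 = reconstruct(scaled, poses)
        assert np.allclose(rec3.grid, 3.0 * rec1.grid, atol=1e-5 * np.abs(rec1.grid).max())

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct([], [])


class TestFSC:
    def test_identical_volumes_correlate_fully(self, blob_volume):
        _, corr = fsc(blob_volume, blob_volume)
        assert np.allclose(corr, 1.0, atol=1e-6)

    def test_independent_noise_has_near_zero_shells(self):
        rng = np.random.default_rng(7)
        a = Volume(rng.normal(size=(32, 32, 32)), 2.0)
        b = Volume(rng.normal(size=(32, 32, 32)), 2.0)
        freq, corr = fsc(a, b)
        # shells with >= 100 Fourier samples: radius >= ~3
        assert np.abs(corr[3:]).mean() < 0.1

    def test_constructed_crossing_location(self, blob_volume):
        rng = np.random.default_rng(3)
        cutoff_shell = 6
        box = blob_volume.box
        cutoff = box * blob_volume.voxel_size / cutoff_shell
        low = lowpass_volume(blob_volume, cutoff, edge_width=0.05)
        noise = rng.normal(size=low.grid.shape) * blob_volume.grid.std() * 5
        high_noise = noise - lowpass_volume(Volume(noise, 2.0), cutoff).grid
        b = Volume(low.grid + high_noise, 2.0)
        freq, corr = fsc(blob_volume, b)
        res = fsc_resolution(freq, corr)
        crossing_shell = box * blob_volume.voxel_size / res
        assert abs(crossing_shell - cutoff_shell) <= 1.0

    def test_mismatched_grids_raise(self, blob_volume):
        other = Volume(np.zeros((16, 16, 16)), 2.0)
        with pytest.raises(ValueError):
            fsc(blob_volume, other)


class TestVolumeInvariants:
    @pytest.mark.parametrize("bad", [
        np.zeros((15, 15, 15)), np.zeros((14, 14, 14)), np.zeros((16, 16, 18)),
    ])
    def test_rejects_bad_grids(self, bad):
        with pytest.raises(ValueError):
            Volume(bad, 2.0)

    def test_rejects_nonfinite(self):
        g = np.zeros((16, 16, 16))
        g[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume(g, 2.0)

    def test_pose_validation(self):
        with pytest.raises(ValueError):
            Pose(0, 200, 0)
        p = Pose(370, 90, -10)
        assert p.rot == pytest.approx(10) and p.psi == pytest.approx(350)
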