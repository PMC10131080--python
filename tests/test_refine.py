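"""Consensus refinement: global and local projection matching."""

import numpy as np
import pytest

from scorevar import _engine as engine
from scorevar.geometry import Pose, angular_distance
from scorevar.refine import (consensus_refine, global_align, local_align,
                             rotvec_ball, rotvec_star)
from scorevar.simulate import ctf_params_from_table, simulate_stack

from scorevar.simulate import builtin_scenario


def ang_errors(euler, table):
    ge = table.euler
    return np.array([
        angular_distance(engine.euler_matrices(euler[i])[0],
                         engine.euler_matrices(ge[i])[0])
        for i in range(len(euler))])


@pytest.fixture(scope="module")
def clean_stack():
    sc = builtin_scenario("HOMO1", n_particles=60, snr=float("inf"),
                          snr_spread=0.0, shift_sigma=1.0)
    stack, table = simulate_stack(sc)
    return sc, stack, table, ctf_params_from_table(table, sc)


class TestGlobalAlign:
    def test_recovers_known_orientations_on_clean_data(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        # low-pass cutoff scaled to the small test box (the 40 A default
        # assumes a production-size box)
        res = global_align(stack, sc.mean_phantom(), ctfs, angular_step=15.0,
                           iterations=4)
        errs = ang_errors(res.euler, table)
        assert np.mean(errs <= 15.0) >= 0.95

    def test_centered_spherical_images_recover_zero_shifts(self, sphere_volume):
        from scorevar.geometry import CTFParams, apply_ctf, project
        from scorevar.io import ParticleStack

        ctf = CTFParams(12000)
        img = apply_ctf(project(sphere_volume, Pose()), ctf).grid
        stack = ParticleStack(np.repeat(img[None], 16, axis=0),
                              sphere_volume.voxel_size)
        res = global_align(stack, sphere_volume, [ctf] * 16, iterations=2)
        assert np.all(np.abs(res.shifts) <= 0.5)

    def test_mean_score_trace_non_decreasing_on_clean_data(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        res = global_align(stack, sc.mean_phantom(), ctfs, iterations=4,
                           lowpass_init=24.0)
        diffs = np.diff(res.trace)
        assert np.all(diffs >= -1e-6)

    def test_empty_stack_rejected(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        from scorevar.io import ParticleStack
        with pytest.raises(ValueError):
            empty = ParticleStack(np.zeros((0, 48, 48), np.float32), 3.0)
            global_align(empty, sc.mean_phantom(), [])

    def test_angular_step_bounds(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        with pytest.raises(ValueError, match="angular_step"):
            global_align(stack, sc.mean_phantom(), ctfs, angular_step=2.0)


class TestLocalAlign:
    def test_vanishing_window_returns_input_poses(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        init = [Pose(r.rot, r.tilt, r.psi, round(r.shift_x), round(r.shift_y))
                for _, r in table.df.iterrows()]
        res = local_align(stack, sc.mean_phantom(), init, ctfs,
                          angle_window=1e-4, shift_window=0.0)
        for got, want in zip(res.poses, init):
            assert angular_distance(got, want) < 1e-3
            assert (got.shift_x, got.shift_y) == (want.shift_x, want.shift_y)

    def test_perturbed_poses_recover_truth_within_grid_spacing(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        rng = np.random.default_rng(0)
        window = 8.0
        init = []
        for _, r in table.df.iterrows():
            axis = rng.normal(size=3)
            axis *= rng.uniform(0, window / 2) / np.linalg.norm(axis)
            from scipy.spatial.transform import Rotation
            m = Pose(r.rot, r.tilt, r.psi).matrix() @ Rotation.from_rotvec(
                axis, degrees=True).as_matrix()
            p = Pose.from_matrix(m, round(r.shift_x), round(r.shift_y))
            init.append(p)
        res = local_align(stack, sc.mean_phantom(), init, ctfs,
                          angle_window=window, shift_window=2.0)
        errs = ang_errors(res.euler, table)
        # recovery within the grid spacing (step = window/4, so the nearest
        # node is within ~step*sqrt(3)/2), with a band-limit noise budget
        assert np.mean(errs <= window / 2) >= 0.98

    def test_refined_score_never_below_initial(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        init = [Pose(r.rot, r.tilt, r.psi, round(r.shift_x), round(r.shift_y))
                for _, r in table.df.iterrows()]
        base = local_align(stack, sc.mean_phantom(), init, ctfs,
                           angle_window=1e-4, shift_window=0.0)
        refined = local_align(stack, sc.mean_phantom(), init, ctfs,
                              angle_window=6.0, shift_window=2.0)
        # single-precision correlation sums differ at the 1e-2 level
        # between batch shapes; the inequality holds to that budget
        assert np.all(refined.scores >= base.scores - 0.01)

    def test_invalid_window_rejected(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        with pytest.raises(ValueError):
            local_align(stack, sc.mean_phantom(), [Pose()] * stack.n, ctfs,
                        angle_window=-1.0)


class TestConsensusRefine:
    def test_clean_consensus_converges(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        res = consensus_refine(stack, sc.mean_phantom(), ctfs,
                               global_iterations=3, local_iterations=3,
                               lowpass_init=24.0)
        errs = ang_errors(res.euler, table)
        assert np.median(errs) < 6.0
        assert np.mean(errs > 30.0) <= 0.05
        # consensus map correlates with the phantom (band-limited compare)
        from scorevar.geometry import fsc
        from scorevar import _engine as eng
        ws = res.working_stack
        truth = eng.reconstruct_working(ws, table.euler, table.shifts)
        _, corr = fsc(res.consensus, truth)
        assert corr[1:6].mean() > 0.95

    def test_determinism(self, clean_stack):
        sc, stack, table, ctfs = clean_stack
        r1 = consensus_refine(stack, sc.mean_phantom(), ctfs,
                              global_iterations=2, local_iterations=1,
                              lowpass_init=24.0)
        r2 = consensus_refine(stack, sc.mean_phantom(), ctfs,
                              global_iterations=2, local_iterations=1,
                              lowpass_init=24.0)
        np.testing.assert_array_equal(r1.euler, r2.euler)
        np.testing.assert_array_equal(r1.shifts, r2.shifts)


class TestOffsetGrids:
    def test_ball_contains_identity_and_respects_radius(self):
        g = rotvec_ball(8.0, 4.0)
        assert (np.all(g == 0, axis=1)).any()
        assert np.linalg.norm(g, axis=1).max() <= 8.0 + 1e-9

    def test_star_has_expected_size(self):
        assert rotvec_star([5.0, 2.5]).shape == (13, 3)

    def test_orientation_grid_covers_the_sphere(self):
        grid = engine.orientation_grid(15.0)
        mats = engine.euler_matrices(grid)
        rng = np.random.default_rng(2)
        for _ in range(25):
            target = engine.euler_matrices(
                [rng.uniform(0, 360),
                 np.degrees(np.arccos(rng.uniform(-1, 1))),
                 rng.uniform(0, 360)])[0]
            tr = np.einsum("cij,ij->c", mats, target)
            best = np.degrees(np.arccos(np.clip((tr.max() - 1) / 2, -1, 1)))
            assert best <= 13.0  # worst-case quantization of a 15-degree grid
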