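"""The restrained-correlation score and bimodal-score cleaning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scorevar.geometry import Image2D, Pose, apply_ctf, project
from scorevar.io import ParticleTable
from scorevar.scoring import (BimodalFit, clean_particles, fit_bimodal,
                              score)

# reference two-component mixture used throughout (clean mode on the right):
# 0.3 N(40, 5^2) + 0.7 N(70, 5^2); equal sds give the closed-form threshold
#   (40+70)/2 + 5^2 ln(0.3/0.7) / (70-40) = 54.29
MIX = dict(w=(0.3, 0.7), mu=(40.0, 70.0), sd=(5.0, 5.0))
MIX_THRESHOLD = (40 + 70) / 2 + 25 * np.log(0.3 / 0.7) / 30


def draw_mix(n, rng):
    comp = rng.random(n) < MIX["w"][1]
    return np.where(comp, rng.normal(MIX["mu"][1], MIX["sd"][1], n),
                    rng.normal(MIX["mu"][0], MIX["sd"][0], n))


class TestScore:
    @pytest.fixture()
    def matched(self, blob_volume, ctf_typical):
        pose = Pose(40, 70, 10, 2, -1)
        image = apply_ctf(project(blob_volume, pose), ctf_typical)
        return pose, image

    def test_exact_self_match_scores_the_full_scale(self, blob_volume,
                                                    ctf_typical, matched):
        pose, image = matched
        s = score(blob_volume, image, pose, pose, ctf_typical)
        assert s == pytest.approx(100.0, abs=1e-3)

    def test_white_noise_scores_near_zero(self, blob_volume, ctf_typical, rng):
        pose = Pose(10, 50, 5)
        vals = []
        for _ in range(100):
            img = Image2D(rng.normal(size=(32, 32)), blob_volume.voxel_size)
            vals.append(score(blob_volume, img, pose, pose, ctf_typical))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-9

    def test_score_decreases_with_noise_level(self, blob_volume, ctf_typical,
                                              matched, rng):
        pose, image = matched
        sig = image.grid.std()
        means = []
        for noise_sd in (0.5 * sig, 1.5 * sig, 4.0 * sig):
            vals = [score(blob_volume,
                          Image2D(image.grid + rng.normal(0, noise_sd,
                                                          image.grid.shape),
                                  image.pixel_size),
                          pose, pose, ctf_typical) for _ in range(12)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_invariant_to_affine_intensity_rescaling(self, blob_volume,
                                                     ctf_typical, matched):
        pose, image = matched
        s0 = score(blob_volume, image, pose, pose, ctf_typical)
        rescaled = Image2D(3.7 * image.grid + 11.0, image.pixel_size)
        s1 = score(blob_volume, rescaled, pose, pose, ctf_typical)
        assert s1 == pytest.approx(s0, abs=1e-4)

    def test_penalty_zero_iff_pose_equals_prior_and_grows(self, blob_volume,
                                                          ctf_typical, matched):
        pose, image = matched
        s0 = score(blob_volume, image, pose, pose, ctf_typical)
        shifted_prior = Pose(pose.rot, pose.tilt, pose.psi,
                             pose.shift_x + 3, pose.shift_y)
        s_shift = score(blob_volume, image, pose, shifted_prior, ctf_typical)
        assert s_shift == pytest.approx(s0 - 1.0, abs=1e-6)  # (3/3)^2
        rotated_prior = Pose(pose.rot, pose.tilt, pose.psi + 20,
                             pose.shift_x, pose.shift_y)
        s_rot = score(blob_volume, image, pose, rotated_prior, ctf_typical)
        assert s_rot == pytest.approx(s0 - 4.0, abs=1e-3)  # (20/10)^2

    def test_zero_variance_image_is_penalty_only(self, blob_volume, ctf_typical):
        flat = Image2D(np.full((32, 32), 7.0), blob_volume.voxel_size)
        pose = Pose(0, 30, 0)
        prior = Pose(0, 30, 0, 3, 0)
        assert score(blob_volume, flat, pose, prior, ctf_typical) == \
            pytest.approx(-1.0, abs=1e-9)


class TestFitBimodal:
    def test_threshold_matches_closed_form_intersection(self, rng):
        x = draw_mix(20000, rng)
        fit = fit_bimodal(x)
        assert not fit.degenerate
        assert fit.threshold == pytest.approx(MIX_THRESHOLD, abs=1.0)

    def test_parameter_recovery(self, rng):
        fit = fit_bimodal(draw_mix(20000, rng))
        assert fit.means[0] == pytest.approx(40.0, abs=1.0)
        assert fit.means[1] == pytest.approx(70.0, abs=1.0)
        assert fit.weights[0] == pytest.approx(0.3, abs=0.05)

    def test_unimodal_sample_is_degenerate(self, rng):
        fit = fit_bimodal(rng.normal(60, 5, 5000))
        assert fit.degenerate

    def test_component_order_never_changes_threshold(self, rng):
        # mirroring the sample swaps which mode is "clean"; the intersection
        # must mirror exactly with it
        x = draw_mix(20000, rng)
        fit_a = fit_bimodal(x)
        fit_b = fit_bimodal(-x)
        assert fit_b.threshold == pytest.approx(-fit_a.threshold, abs=1e-6)

    def test_too_few_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="50"):
            fit_bimodal(rng.normal(size=49))

    def test_agrees_with_sklearn_mixture_oracle(self, rng):
        from sklearn.mixture import GaussianMixture

        x = draw_mix(20000, rng)
        fit = fit_bimodal(x)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(np.sort(gm.means_.ravel()), fit.means,
                                   atol=0.5)
        np.testing.assert_allclose(gm.weights_[order], fit.weights, atol=0.02)


def make_table(scores):
    n = len(scores)
    return ParticleTable(pd.DataFrame({
        "particle_id": np.arange(n), "image_index": np.arange(n),
        "rot": 0.0, "tilt": 0.0, "psi": 0.0, "shift_x": 0.0, "shift_y": 0.0,
        "defocus": 10000.0, "score": scores,
    }))


class TestCleanParticles:
    def test_all_above_threshold_is_identity(self, rng):
        fit = fit_bimodal(draw_mix(20000, rng))
        table = make_table(rng.normal(80, 2, 100))
        out = clean_particles(table, fit)
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_kept_fraction_matches_analytic_tail_masses(self, rng):
        x = draw_mix(20000, rng)
        fit = fit_bimodal(x)
        out = clean_particles(make_table(x), fit)
        expected = sum(w * norm.sf(MIX_THRESHOLD, m, s) for w, m, s in
                       zip(MIX["w"], MIX["mu"], MIX["sd"]))
        assert len(out) / len(x) == pytest.approx(expected, abs=0.03)

    def test_kept_count_equals_brute_force_filter(self, rng):
        x = draw_mix(5000, rng)
        fit = fit_bimodal(x)
        out = clean_particles(make_table(x), fit)
        assert len(out) == int(np.sum(x >= fit.threshold))

    def test_degenerate_fit_refuses_to_clean(self, rng, caplog):
        fit = BimodalFit((59.0, 60.0), (5.0, 5.0), (0.5, 0.5), 59.5,
                         degenerate=True)
        table = make_table(rng.normal(60, 5, 200))
        with caplog.at_level("WARNING"):
            out = clean_particles(table, fit)
        assert len(out) == len(table)
        assert any("degenerate" in r.message for r in caplog.records)
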