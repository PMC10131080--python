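"""Consensus refinement: align every particle to a single reference.

The pipeline mirrors standard single-particle practice: a few iterations of
exhaustive (global) projection matching against a deliberately low-passed
initial reference, followed by iterations of local refinement around each
particle's current pose, re-reconstructing the consensus map after every
pass. The resulting per-particle poses and consensus scores initialize the
multi-reference classification stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine as engine
from .geometry import CTFParams, Pose, Volume, lowpass_volume
from .io import ParticleStack
from .scoring import ScoreParams

logger = logging.getLogger(__name__)

DEFAULT_LOWPASS_INIT = 40.0   # Angstrom; initial reference filter
DEFAULT_ANGULAR_STEP = 15.0   # degrees; global search grid
DEFAULT_MAX_SHIFT = 4.0       # pixels; global translational search
DEFAULT_ANGLE_WINDOW = 10.0   # degrees; local search window
DEFAULT_SHIFT_WINDOW = 3.0    # pixels; local translational window


@dataclass
class AlignmentResult:
    """Per-particle alignment against a single (consensus) reference."""

    euler: np.ndarray            # (N, 3) ZYZ degrees
    shifts: np.ndarray           # (N, 2) pixels
    scores: np.ndarray           # (N,) restrained-correlation scores
    consensus: Volume            # reference reconstructed from the poses
    trace: list = field(default_factory=list)  # mean score per iteration
    working_stack: object = None  # engine WorkingStack, reused downstream

    @property
    def n(self) -> int:
        return self.euler.shape[0]

    @property
    def poses(self) -> list[Pose]:
        return [Pose(*self.euler[i], self.shifts[i, 0], self.shifts[i, 1])
                for i in range(self.n)]


def rotvec_ball(window: float, step: float) -> np.ndarray:
    """Rotation-vector offsets (degrees) on a cubic grid inside a ball.

    Includes the identity; covers geodesic deviations up to ``window``.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    vals = np.arange(-window, window + step / 2, step)
    g = np.array(np.meshgrid(vals, vals, vals, indexing="ij")).reshape(3, -1).T
    g = g[np.linalg.norm(g, axis=1) <= window + 1e-9]
    if not (np.all(g == 0, axis=1)).any():
        g = np.vstack([[0.0, 0.0, 0.0], g])
    return g


def rotvec_star(radii) -> np.ndarray:
    """Identity plus +/- offsets about each axis at the given radii."""
    out = [[0.0, 0.0, 0.0]]
    for r in np.atleast_1d(radii):
        for ax in range(3):
            for s in (+1.0, -1.0):
                v = [0.0, 0.0, 0.0]
                v[ax] = s * r
                out.append(v)
    return np.asarray(out)


def _euler_shift_arrays(init_poses) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(init_poses, AlignmentResult):
        return init_poses.euler.copy(), init_poses.shifts.copy()
    poses = list(init_poses)
    euler = np.array([[p.rot, p.tilt, p.psi] for p in poses])
    shifts = np.array([[p.shift_x, p.shift_y] for p in poses])
    return euler, shifts


def global_align(
    stack: ParticleStack,
    reference: Volume,
    ctfs: list[CTFParams],
    angular_step: float = DEFAULT_ANGULAR_STEP,
    max_shift: float = DEFAULT_MAX_SHIFT,
    iterations: int = 4,
    score_params: ScoreParams | None = None,
    lowpass_init: float = DEFAULT_LOWPASS_INIT,
    work_box: int = 16,
) -> AlignmentResult:
    """Exhaustive projection matching of a stack against one reference.

    The reference is low-pass filtered (default 40 A) before the first
    iteration to avoid reference bias; after each pass a new consensus map
    is reconstructed from the current poses and the search repeats against
    it. Global search carries no pose prior, so scores here are pure scaled
    correlations.
    """
    if stack.n == 0:
        raise ValueError("empty particle stack")
    if not 5.0 <= angular_step <= 30.0:
        raise ValueError("angular_step must lie in [5, 30] degrees")
    sp = score_params or ScoreParams()
    ws = engine.prepare_stack(stack.images, stack.pixel_size, ctfs,
                              work_box=work_box,
                              mask_radius_fraction=sp.mask_radius_fraction)
    ref = lowpass_volume(reference, lowpass_init)
    ref_ft = engine.reference_ft(ref)
    shifts = None
    trace: list[float] = []
    for it in range(iterations):
        final = it == iterations - 1
        if not final:
            euler, shifts, ncc = engine.global_search(
                ws, ref_ft, angular_step, max_shift, shifts0=shifts, top=24)
            scores = sp.scale * ncc
        else:
            # last pass: keep several candidate orientation basins per
            # particle and pick the winner after local polish — slice
            # interpolation noise otherwise mis-ranks near-degenerate basins
            c_euler, c_shifts, _ = engine.global_search(
                ws, ref_ft, angular_step, max_shift, shifts0=shifts, top=24,
                n_candidates=4)
            polish = rotvec_ball(angular_step / 2.0, angular_step / 4.0)
            best_scores = np.full(ws.n, -np.inf)
            euler = np.zeros((ws.n, 3))
            shifts = np.zeros((ws.n, 2))
            for j in range(c_euler.shape[1]):
                e, s, sc, _ = engine.local_search(
                    ws, ref_ft, c_euler[:, j], c_shifts[:, j], polish,
                    2, sp, prior_euler=c_euler[:, j],
                    prior_shifts=c_shifts[:, j])
                better = sc > best_scores
                best_scores[better] = sc[better]
                euler[better] = e[better]
                shifts[better] = s[better]
            scores = best_scores
        trace.append(float(scores.mean()))
        logger.info("global iteration %d/%d: mean score %.2f",
                    it + 1, iterations, trace[-1])
        if it < iterations - 1:
            new_ref = engine.class_reference_halves(
                ws, euler, shifts, np.arange(ws.n))[2]
            ref_ft = engine.reference_ft(new_ref)
    consensus = engine.class_reference_halves(ws, euler, shifts,
                                              np.arange(ws.n))[2]
    return AlignmentResult(euler, shifts, scores, consensus, trace, ws)


def local_align(
    stack: ParticleStack,
    reference: Volume,
    init_poses,
    ctfs: list[CTFParams],
    angle_window: float = DEFAULT_ANGLE_WINDOW,
    shift_window: float = DEFAULT_SHIFT_WINDOW,
    score_params: ScoreParams | None = None,
    step: float | None = None,
    work_box: int = 24,
    working_stack=None,
) -> AlignmentResult:
    """One pass of restricted search around per-particle initial poses.

    Orientations are sampled on a rotation-vector grid of radius
    ``angle_window`` at spacing ``step`` (default ``angle_window / 4``);
    shifts on the integer pixel grid within ``shift_window``. The initial
    pose is always a candidate, so the refined score never drops below the
    score at the initial pose.
    """
    if angle_window <= 0 or shift_window < 0:
        raise ValueError("search windows must be positive")
    sp = score_params or ScoreParams()
    ws = working_stack
    if ws is None:
        ws = engine.prepare_stack(stack.images, stack.pixel_size, ctfs,
                                  work_box=work_box,
                                  mask_radius_fraction=sp.mask_radius_fraction)
    euler, shifts = _euler_shift_arrays(init_poses)
    if euler.shape[0] != ws.n:
        raise ValueError("need one initial pose per particle")
    offsets = rotvec_ball(angle_window, step or angle_window / 4.0)
    ref_ft = engine.reference_ft(reference)
    out_euler, out_shifts, out_scores, _ = engine.local_search(
        ws, ref_ft, euler, shifts, offsets, shift_window, sp,
        prior_euler=euler, prior_shifts=shifts)
    consensus = engine.reconstruct_working(ws, out_euler, out_shifts)
    return AlignmentResult(out_euler, out_shifts, out_scores, consensus,
                           [float(out_scores.mean())], ws)


def consensus_refine(
    stack: ParticleStack,
    reference: Volume,
    ctfs: list[CTFParams],
    global_iterations: int = 4,
    local_iterations: int = 4,
    angular_step: float = DEFAULT_ANGULAR_STEP,
    max_shift: float = DEFAULT_MAX_SHIFT,
    angle_window: float = DEFAULT_ANGLE_WINDOW,
    shift_window: float = DEFAULT_SHIFT_WINDOW,
    score_params: ScoreParams | None = None,
    lowpass_init: float = DEFAULT_LOWPASS_INIT,
    work_box: int = 24,
) -> AlignmentResult:
    """Full consensus pipeline: global search then coarse-to-fine local
    refinement, reconstructing the consensus map after every pass.

    The global stage runs on a tighter frequency band (the initial reference
    is heavily low-passed anyway); local refinement and the final consensus
    use the standard working band.
    """
    sp = score_params or ScoreParams()
    res = global_align(stack, reference, ctfs, angular_step, max_shift,
                       global_iterations, sp, lowpass_init,
                       work_box=min(16, work_box))
    ws = engine.prepare_stack(stack.images, stack.pixel_size, ctfs,
                              work_box=work_box,
                              mask_radius_fraction=sp.mask_radius_fraction)
    euler, shifts = res.euler, res.shifts
    trace = list(res.trace)
    everyone = np.arange(ws.n)
    ref = engine.class_reference_halves(ws, euler, shifts, everyone)[2]
    scores = res.scores
    for it in range(local_iterations):
        # shrink the search window geometrically; the grid stays coarse
        # enough (window/2) that each pass is cheap
        window = max(angle_window / (2.0 ** it), 0.75)
        offsets = rotvec_ball(window, window / 2.0)
        ref_ft = engine.reference_ft(ref)
        euler, shifts, scores, _ = engine.local_search(
            ws, ref_ft, euler, shifts, offsets, shift_window, sp,
            prior_euler=euler, prior_shifts=shifts)
        trace.append(float(scores.mean()))
        logger.info("local iteration %d/%d: mean score %.2f",
                    it + 1, local_iterations, trace[-1])
        ref = engine.class_reference_halves(ws, euler, shifts, everyone)[2]
    return AlignmentResult(euler, shifts, scores, ref, trace, ws)


def reconstruct_full(
    stack: ParticleStack,
    ctfs: list[CTFParams],
    euler: np.ndarray,
    shifts: np.ndarray,
    subset: np.ndarray | None = None,
    mask_radius_fraction: float = 0.9,
) -> Volume:
    """Full-resolution reconstruction from aligned stack images."""
    ws = engine.prepare_stack(stack.images, stack.pixel_size, ctfs,
                              work_box=stack.box,
                              mask_radius_fraction=mask_radius_fraction)
    return engine.reconstruct_working(ws, euler, shifts, subset=subset)
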