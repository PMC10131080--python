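"""Multi-reference 3D classification with per-class local alignment.

For a given class count K, particles start from a random partition into K
seed groups whose references are reconstructed with the consensus poses.
Each iteration then locally re-aligns every particle against every class
reference (starting from the particle's current pose), assigns each
particle to the class with the highest restrained-correlation score (hard
argmax, ties to the lowest class id), and rebuilds the class references.

Three standard numerical devices make this robust at realistic noise:

* Gold-standard cross-half scoring. Each class keeps two half-set
  reconstructions (split by particle parity), filtered by their mutual FSC,
  and every particle is scored against the half-map it did not contribute
  to. Without this, each particle correlates slightly better with the
  reference containing its own noise, which freezes the initial random
  partition.
* Deterministic annealing. Reconstruction (not assignment) weights are a
  softmax of the scores at a temperature cooled geometrically to zero, so
  the partition bifurcates smoothly out of the random initialization
  instead of locking into a shallow local optimum.
* Pseudo-symmetry relaxation. The consensus map's significant rotational
  self-correlations define discrete alternative orientation basins; the
  per-class search includes those rotations as candidates (with the
  angular restraint measured to the nearest symmetry-equivalent of the
  prior), so a particle consensus-aligned in a wrong basin can still land
  correctly in its class.

Classes that empty out are reseeded with the worst-scoring particles of the
largest class, so K live classes survive; surplus classes act as sinks that
collect particles fitting none of the structured classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine as engine
from .geometry import Volume, fsc
from .refine import AlignmentResult, rotvec_ball, rotvec_star
from .scoring import ScoreMatrix, ScoreParams

logger = logging.getLogger(__name__)


@dataclass
class ClassifyOptions:
    """Knobs of one classification run."""

    max_iterations: int = 12      # annealing iterations (post-anneal extra
                                  # iterations run until assignments settle)
    tol: float = 0.01             # stop when < tol of assignments change
    angle_step: float = 5.0       # degrees; local search star radius
    shift_window: float = 2.0     # pixels
    seed: int = 0
    wiener: float = 0.01
    work_box: int = 20            # band used during iterations
    score_box: int = 32           # band used for the final score matrix
    anneal_t0: float = 1.7        # initial temperature, as a multiple of the
                                  # median cross-class score range at iter 1
    anneal_decay: float = 0.8
    anneal_floor_rel: float = 0.1   # hard assignment below this fraction of T0
    momentum: float = 0.55        # running-average weight on half-maps
    sym_relax: bool = True        # include pseudo-symmetry basin candidates
    quality_weight: bool = True   # down-weight low-scoring particles in maps
    wide_realign: int = 1         # wide-window re-alignment passes at the end
    score_params: ScoreParams = field(default_factory=ScoreParams)


@dataclass
class ClassificationRun:
    """Result of one K-class classification."""

    k: int
    references: list[Volume]
    assignments: np.ndarray       # (N,) class ids in [1, K]
    score_matrix: ScoreMatrix     # (N, K) restrained scores s_{k,i}
    class_stats: pd.DataFrame     # class_id, n_k, score_mean, score_var
    euler: np.ndarray             # (N, 3) pose of the assigned class
    shifts: np.ndarray            # (N, 2)
    iterations_run: int = 0
    seed: int = 0
    reseed_events: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.assignments.size


def _class_stats(scores: np.ndarray, assignments: np.ndarray, k: int) -> pd.DataFrame:
    """Per-class counts, score means and population variances, computed from
    the scores of the particles assigned to each class only."""
    rows = []
    for c in range(1, k + 1):
        members = np.nonzero(assignments == c)[0]
        s = scores[members, c - 1]
        rows.append({
            "class_id": c,
            "n_k": int(members.size),
            "score_mean": float(s.mean()) if members.size else float("nan"),
            "score_var": float(s.var()) if members.size else float("nan"),
        })
    return pd.DataFrame(rows)


class _ClassMaps:
    """Running half-set reconstructions of one class with FSC filtering."""

    def __init__(self, momentum: float):
        self.momentum = momentum
        self.h0 = None
        self.h1 = None

    def update(self, ws, euler, shifts, weights, parity, wiener):
        maps = []
        for par in (0, 1):
            sel = np.nonzero((weights > 0.02) & (parity == par))[0]
            if sel.size < 2:
                sel = np.nonzero(weights > 0.02)[0]
            maps.append(engine.reconstruct_working(
                ws, euler, shifts, subset=sel, wiener=wiener,
                weights=weights[sel]))
        if self.h0 is not None and self.momentum > 0:
            a = self.momentum
            self.h0 = a * self.h0 + (1 - a) * maps[0].grid
            self.h1 = a * self.h1 + (1 - a) * maps[1].grid
        else:
            self.h0, self.h1 = maps[0].grid, maps[1].grid
        v0 = Volume(self.h0, maps[0].voxel_size)
        v1 = Volume(self.h1, maps[1].voxel_size)
        _, cc = fsc(v0, v1)
        w = np.clip(2.0 * cc / (1.0 + np.abs(cc)), 0.0, 1.0)
        w[0] = 1.0
        full = Volume(0.5 * (self.h0 + self.h1), v0.voxel_size)
        return (engine._shell_filter(v1, w), engine._shell_filter(v0, w),
                engine._shell_filter(full, w))


def classify(
    stack,
    consensus: AlignmentResult,
    k: int,
    opts: ClassifyOptions | None = None,
) -> ClassificationRun:
    """One K-class multi-reference classification run.

    ``stack`` may be None when the consensus result carries its prepared
    working stack (the normal case). K = 1 reduces to a local refinement of
    the consensus reference.
    """
    opts = opts or ClassifyOptions()
    sp = opts.score_params
    if k < 1:
        raise ValueError("K must be >= 1")
    ws_full = consensus.working_stack
    if ws_full is None:
        raise ValueError("consensus result carries no working stack; "
                         "run consensus refinement first")
    n = ws_full.n
    if n < k:
        raise ValueError(f"cannot split {n} particles into {k} classes")

    # iterate on a compact band; score finally on a wider band where
    # reference quality is resolution-limited
    cache = getattr(ws_full, "_band_cache", None)
    if cache is None:
        cache = {ws_full.work_box: ws_full}
        ws_full._band_cache = cache

    def _band(box: int):
        if box not in cache:
            cache[box] = engine.prepare_stack(
                ws_full.images, ws_full.pixel_size, ws_full.ctfs,
                work_box=box,
                mask_radius_fraction=ws_full.mask_radius_fraction)
        return cache[box]

    ws = _band(min(opts.work_box, ws_full.work_box))
    ws_score = _band(opts.score_box)

    cons_euler = consensus.euler
    cons_shifts = consensus.shifts

    offsets = rotvec_star([opts.angle_step])
    n_star = len(offsets)
    sym_mats = None
    if opts.sym_relax and k > 1:
        sym_rv = getattr(consensus, "_pseudo_sym_cache", None)
        if sym_rv is None:
            sym_rv = engine.pseudo_symmetry_rotations(consensus.consensus)
            consensus._pseudo_sym_cache = sym_rv
        if len(sym_rv):
            offsets = np.vstack([offsets, sym_rv])
            from scipy.spatial.transform import Rotation
            sym_mats = Rotation.from_rotvec(sym_rv, degrees=True).as_matrix()
            logger.info("K=%d: %d pseudo-symmetry basin candidates", k,
                        len(sym_rv))

    rng = np.random.default_rng(opts.seed)
    soft = rng.dirichlet(np.full(k, 5.0), size=n)  # (n, k) anneal weights

    # score-based reconstruction weighting: poor particles contribute less
    # to the class maps (their assignments are still computed and reported)
    if opts.quality_weight and consensus.scores is not None:
        p10, p70 = np.percentile(consensus.scores, [10, 70])
        wq = np.clip((consensus.scores - p10) / max(p70 - p10, 1e-9),
                     0.05, 1.0)
    else:
        wq = np.ones(n)

    euler = cons_euler.copy()
    shifts = cons_shifts.copy()
    assignments = np.zeros(n, dtype=np.int64)
    parity = np.arange(n) % 2
    halves = [np.nonzero(parity == p)[0] for p in (0, 1)]
    maps = [_ClassMaps(opts.momentum) for _ in range(k)]
    refs: list[Volume] = [None] * k
    scores = np.empty((n, k))
    reseed_events: list = []

    temp = None if k > 1 else 0.0  # set from the iteration-1 score spread
    floor = 0.0
    it = 0
    max_it = opts.max_iterations if k > 1 else 2
    while True:
        it += 1
        cand_euler = np.empty((k, n, 3))
        cand_shifts = np.empty((k, n, 2))
        # once annealing has cooled, poses are converged: the remaining
        # settle iterations only rescore (plus basin jumps); the wide
        # re-alignment pass below still re-searches at the end
        if temp is not None and temp <= floor and it > 1:
            it_offsets = np.vstack([offsets[:1], offsets[n_star:]])
        else:
            it_offsets = offsets
        for c in range(k):
            m0, m1, full = maps[c].update(ws, euler, shifts,
                                          soft[:, c] * wq,
                                          parity, opts.wiener)
            refs[c] = full
            for p, ref in enumerate((m0, m1)):
                ref_ft = engine.reference_ft(ref)
                e, s, sc, _ = engine.local_search(
                    ws, ref_ft, euler, shifts, it_offsets, opts.shift_window,
                    sp, prior_euler=cons_euler, prior_shifts=cons_shifts,
                    subset=halves[p], prior_sym_mats=sym_mats)
                cand_euler[c, halves[p]] = e
                cand_shifts[c, halves[p]] = s
                scores[halves[p], c] = sc
        new_assign = np.argmax(scores, axis=1) + 1  # ties -> lowest class id
        if temp is None:
            spread = float(np.median(scores.max(axis=1) - scores.min(axis=1)))
            temp = max(opts.anneal_t0 * spread, 1e-6)
            floor = opts.anneal_floor_rel * temp
            logger.info("K=%d: annealing T0=%.2f (score spread %.2f)",
                        k, temp, spread)

        # reseed classes that emptied out
        counts = np.bincount(new_assign, minlength=k + 1)[1:]
        for c in np.nonzero(counts == 0)[0]:
            largest = int(np.argmax(counts))
            m = min(int(round(n / k)), max(1, counts[largest] // 2))
            members = np.nonzero(new_assign == largest + 1)[0]
            worst = members[np.argsort(scores[members, largest])[:m]]
            new_assign[worst] = c + 1
            counts = np.bincount(new_assign, minlength=k + 1)[1:]
            reseed_events.append({"iteration": it, "class": int(c + 1),
                                  "from": int(largest + 1), "n": int(m)})
            logger.info("iteration %d: reseeded empty class %d with %d "
                        "worst particles of class %d", it, c + 1, m,
                        largest + 1)

        idx = np.arange(n)
        euler = cand_euler[new_assign - 1, idx]
        shifts = cand_shifts[new_assign - 1, idx]
        changed = float(np.mean(new_assign != assignments))
        assignments = new_assign
        if temp > floor:
            z = (scores - scores.max(axis=1, keepdims=True)) / temp
            soft = np.exp(z)
            soft /= soft.sum(axis=1, keepdims=True)
        else:
            soft = np.eye(k)[assignments - 1]
        logger.info("K=%d iteration %d: T=%.2f %.1f%% changed, mean "
                    "assigned score %.2f", k, it, temp, 100 * changed,
                    float(scores[idx, assignments - 1].mean()))
        annealed = temp <= floor
        temp *= opts.anneal_decay
        if (annealed and changed < opts.tol) or it >= max_it + 4:
            break
        if it >= max_it and changed < opts.tol:
            break

    # wide re-alignment: consensus misaligns exactly the particles whose
    # mobile feature disagrees with the majority, and the +-angle_step
    # search cannot recover them; a couple of wide-window passes against
    # the now-separated class references can
    if k > 1 and opts.wide_realign > 0:
        wide = rotvec_ball(4.0 * opts.angle_step, 2.0 * opts.angle_step)
        if sym_mats is not None:
            from scipy.spatial.transform import Rotation
            wide = np.vstack([wide, Rotation.from_matrix(sym_mats)
                              .as_rotvec(degrees=True)])
        for _ in range(opts.wide_realign):
            it += 1
            for c in range(k):
                m0, m1, full = maps[c].update(ws, euler, shifts,
                                              soft[:, c] * wq,
                                              parity, opts.wiener)
                refs[c] = full
                for p, ref in enumerate((m0, m1)):
                    ref_ft = engine.reference_ft(ref)
                    e, s, sc, _ = engine.local_search(
                        ws, ref_ft, euler, shifts, wide, opts.shift_window,
                        sp, prior_euler=cons_euler, prior_shifts=cons_shifts,
                        subset=halves[p], prior_sym_mats=sym_mats)
                    cand_euler[c, halves[p]] = e
                    cand_shifts[c, halves[p]] = s
                    scores[halves[p], c] = sc
            assignments = np.argmax(scores, axis=1) + 1
            euler = cand_euler[assignments - 1, idx]
            shifts = cand_shifts[assignments - 1, idx]
            soft = np.eye(k)[assignments - 1]
            logger.info("K=%d wide re-alignment: mean assigned score %.2f",
                        k, float(scores[idx, assignments - 1].mean()))

    # final pass on the standard band: rebuild filtered cross-half maps from
    # the final assignment and recompute the full score matrix and poses,
    # still allowing basin jumps and a small polish so particles that the
    # consensus aligned into a wrong pseudo-symmetry basin are scored fairly
    # against every class
    members = [np.nonzero(assignments == c + 1)[0] for c in range(k)]
    final_offsets = rotvec_star([opts.angle_step / 2.0])
    if sym_mats is not None:
        from scipy.spatial.transform import Rotation
        final_offsets = np.vstack([
            final_offsets,
            Rotation.from_matrix(sym_mats).as_rotvec(degrees=True)])
    final_maps = []
    for c in range(k):
        sub = members[c] if members[c].size >= 2 else np.arange(n)
        m0, m1, full = engine.class_reference_halves(
            ws_score, euler, shifts, sub, wiener=opts.wiener)
        final_maps.append((m0, m1))
        refs[c] = full
    for c in range(k):
        m0, m1 = final_maps[c]
        for p, ref in enumerate((m0, m1)):
            ref_ft = engine.reference_ft(ref)
            e, s, sc, _ = engine.local_search(
                ws_score, ref_ft, euler, shifts, final_offsets,
                1, sp, prior_euler=cons_euler, prior_shifts=cons_shifts,
                subset=halves[p], prior_sym_mats=sym_mats)
            cand_euler[c, halves[p]] = e
            cand_shifts[c, halves[p]] = s
            scores[halves[p], c] = sc
    final_assign = np.argmax(scores, axis=1) + 1
    idx = np.arange(n)
    euler = cand_euler[final_assign - 1, idx]
    shifts = cand_shifts[final_assign - 1, idx]

    stats = _class_stats(scores, final_assign, k)
    return ClassificationRun(
        k=k,
        references=refs,
        assignments=final_assign,
        score_matrix=ScoreMatrix(scores.copy()),
        class_stats=stats,
        euler=euler,
        shifts=shifts,
        iterations_run=it,
        seed=opts.seed,
        reseed_events=reseed_events,
    )


def sweep(
    stack,
    consensus: AlignmentResult,
    k_min: int = 1,
    k_max: int = 6,
    opts: ClassifyOptions | None = None,
) -> list[ClassificationRun]:
    """Independent classification runs for K = k_min .. k_max.

    Each run is seeded as ``seed + K``; runs share nothing beyond the
    consensus initialization.
    """
    if not 1 <= k_min <= k_max <= 10:
        raise ValueError("need 1 <= k_min <= k_max <= 10")
    opts = opts or ClassifyOptions()
    runs = []
    for k in range(k_min, k_max + 1):
        runs.append(classify(stack, consensus, k,
                             replace(opts, seed=opts.seed + k)))
    return runs
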