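"""Class-number selection by maximizing the mean per-class score variance.

For each classification run with K classes the criterion is

    V(K) = mean over classes k of Var_k,
    Var_k = (1 / N_k) * sum over particles i assigned to k of
            (s_{k,i} - mean_k)^2

i.e. the population variance of the scores of the particles assigned to
each class, averaged over classes. The selected class count K_best is the
K whose run maximizes V(K). The partition with the broadest spread of
scores is the one that best captures the variability in the data: with too
few classes, mixed references are blurred and compress the score spread;
with too many, populations split and low-scoring "noisy" sink classes with
narrow distributions appear, both of which shrink the average variance.

The criterion is invariant to adding a constant to every score and scales
quadratically under score rescaling, so K_best does not depend on the
(arbitrary) affine scale of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassificationRun
from .geometry import Volume

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Per-K criterion values and the selected class count."""

    k_values: list[int]
    mean_variance: list[float]
    k_best: int
    noisy_flags: dict = field(default_factory=dict)  # K -> set of class ids

    def as_table(self) -> list[dict]:
        return [
            {"k": k, "mean_score_variance": v,
             "noisy_classes": sorted(self.noisy_flags.get(k, set())),
             "selected": k == self.k_best}
            for k, v in zip(self.k_values, self.mean_variance)
        ]

    @property
    def flatness(self) -> float:
        """Max-to-median ratio of the per-K criterion; values near 1 hint
        that no discrete partition stands out (possibly continuous
        heterogeneity)."""
        med = float(np.median(self.mean_variance))
        return float(max(self.mean_variance) / med) if med > 0 else float("inf")


def mean_score_variance(run: ClassificationRun, sample: bool = False) -> float:
    """Average over classes of the per-class score variance.

    Uses the population variance (divisor N_k) by default; ``sample=True``
    switches to the N_k - 1 divisor. Classes with a single particle
    contribute zero; empty classes are excluded from the average (loudly).
    """
    assignments = run.assignments
    scores = run.score_matrix.values
    if assignments.size == 0:
        raise ValueError("run has no assigned particles")
    variances = []
    for k in range(1, run.k + 1):
        members = np.nonzero(assignments == k)[0]
        if members.size == 0:
            logger.warning("K=%d run: class %d is empty and is excluded "
                           "from the mean score variance", run.k, k)
            continue
        s = scores[members, k - 1]
        if members.size == 1:
            variances.append(0.0)
        else:
            variances.append(float(s.var(ddof=1 if sample else 0)))
    if not variances:
        raise ValueError("run has no non-empty classes")
    return float(np.mean(variances))


def flag_noisy(run: ClassificationRun) -> set[int]:
    """Class ids whose mean assigned score is an outlier on the low side.

    Sink classes that collect poorly fitting particles show up with a
    depressed score mean. Because the within-class score spread (particle
    quality) is much wider than between-class mean differences, the test
    is an outlier test on the *class means*: class k is flagged when its
    mean falls below the mean of the other classes by more than
    ``max(2.5 * std(other means), 1.0)`` score units. Diagnostic only:
    never feeds back into :func:`select_k`.
    """
    means = {}
    for k in range(1, run.k + 1):
        s = run.score_matrix.values[run.assignments == k, k - 1]
        if s.size:
            means[k] = float(s.mean())
    flags = set()
    for k, m in means.items():
        others = [v for kk, v in means.items() if kk != k]
        if not others:
            continue
        gap = float(np.mean(others)) - m
        spread = float(np.std(others)) if len(others) > 1 else 0.0
        if gap > max(2.5 * spread, 1.0):
            flags.add(k)
    return flags


def select_k(runs: list[ClassificationRun], sample: bool = False) -> SelectionResult:
    """Select K_best = argmax_K of the mean per-class score variance.

    Requires at least two runs with distinct K; ties break toward the
    smallest K (parsimony).
    """
    ks = [r.k for r in runs]
    if len(set(ks)) < 2:
        raise ValueError("need >= 2 runs with distinct K to compare")
    order = np.argsort(ks)
    runs = [runs[i] for i in order]
    ks = [r.k for r in runs]
    mv = [mean_score_variance(r, sample=sample) for r in runs]
    best = int(np.argmax(mv))  # first max: ties toward the smallest K
    flags = {r.k: flag_noisy(r) if r.k >= 2 else set() for r in runs}
    return SelectionResult(k_values=ks, mean_variance=mv,
                           k_best=ks[best], noisy_flags=flags)


def pick_refinement_maps(
    runs: list[ClassificationRun],
    result: SelectionResult,
) -> tuple[list[Volume], list[int]]:
    """Maps of the K_best + 1 run with its noisy sink class(es) dropped.

    Running with one extra class lets the sink drain low-quality particles,
    typically improving the remaining reconstructions; this helper returns
    those remaining maps. If no class of the K_best + 1 run is flagged, all
    its maps are returned (with a notice).
    """
    target = result.k_best + 1
    by_k = {r.k: r for r in runs}
    if target not in by_k:
        raise ValueError(
            f"no K={target} run available; extend the sweep to K >= {target}")
    run = by_k[target]
    flagged = result.noisy_flags.get(target)
    if flagged is None:
        flagged = flag_noisy(run)
    if not flagged:
        logger.info("no noisy class flagged in the K=%d run; returning all "
                    "%d maps", target, target)
    keep = [k for k in range(1, target + 1) if k not in flagged]
    return [run.references[k - 1] for k in keep], keep
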