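"""End-to-end convenience pipeline: simulate -> refine -> sweep -> select."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .classify import ClassificationRun, ClassifyOptions, sweep
from .io import ParticleStack, ParticleTable
from .refine import AlignmentResult, consensus_refine
from .scoring import ScoreParams
from .selection import SelectionResult, select_k
from .simulate import Scenario, builtin_scenario, ctf_params_from_table, simulate_stack

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    scenario: Scenario
    stack: ParticleStack
    table: ParticleTable
    consensus: AlignmentResult
    runs: list[ClassificationRun]
    selection: SelectionResult | None


def run_scenario(
    scenario: Scenario | str,
    k_min: int = 1,
    k_max: int = 6,
    seed: int = 0,
    classify_opts: ClassifyOptions | None = None,
    score_params: ScoreParams | None = None,
    scenario_overrides: dict | None = None,
) -> PipelineResult:
    """Simulate a scenario and run the full class-number-selection pipeline.

    The initial consensus reference is the proportion-weighted mean of the
    scenario's phantoms — the analog of refining against a low-pass filtered
    deposited map — and is low-pass filtered to 40 A by the refinement
    stage before first use.
    """
    if isinstance(scenario, str):
        scenario = builtin_scenario(scenario, **(scenario_overrides or {}))
    sp = score_params or ScoreParams()
    logger.info("simulating scenario %s (n=%d, K_true=%d)",
                scenario.name, scenario.n_particles, scenario.k_true)
    stack, table = simulate_stack(scenario)
    ctfs = ctf_params_from_table(table, scenario)
    logger.info("consensus refinement")
    consensus = consensus_refine(stack, scenario.mean_phantom(), ctfs,
                                 score_params=sp)
    opts = classify_opts or ClassifyOptions(score_params=sp)
    opts.seed = seed
    logger.info("classification sweep K=%d..%d", k_min, k_max)
    runs = sweep(stack, consensus, k_min, k_max, opts)
    selection = select_k(runs) if len(runs) > 1 else None
    if selection is not None:
        logger.info("selected K_best=%d", selection.k_best)
    return PipelineResult(scenario, stack, table, consensus, runs, selection)
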