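"""scorevar: how many discrete conformations are in a cryo-EM dataset?

Runs multi-reference 3D classification for a range of class counts K with
local projection-matching alignment, scores every particle against every
class reference, and selects the best K by maximizing the mean per-class
score variance. Ships a ground-truth synthetic particle generator so the
whole pipeline is testable end to end without external data.
"""

from .classify import ClassificationRun, ClassifyOptions, classify, sweep
from .geometry import (CTFParams, Image2D, Pose, Volume, angular_distance,
                       apply_ctf, fsc, fsc_resolution, lowpass_volume, project,
                       reconstruct)
from .io import (ParticleStack, ParticleTable, RunConfig, read_stack,
                 read_table, read_volume, write_stack, write_table,
                 write_volume)
from .refine import (AlignmentResult, consensus_refine, global_align,
                     local_align, reconstruct_full)
from .scoring import (BimodalFit, ScoreMatrix, ScoreParams, clean_particles,
                      fit_bimodal, score)
from .selection import (SelectionResult, flag_noisy, mean_score_variance,
                        pick_refinement_maps, select_k)
from .simulate import (BUILTIN_NAMES, BlobSpec, Scenario, build_phantom,
                       builtin_scenario, ctf_params_from_table, simulate_stack)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
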