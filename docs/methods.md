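# Methods

`scorevar` estimates the number of discrete conformations K present in a
single-particle cryo-EM dataset. It runs multi-reference 3D classification
for a range of class counts, computes a per-particle quality-of-fit score
against every class reference, and selects

    K_best = argmax_K  (1/K) * sum_k Var_k,
    Var_k  = population variance of the scores of the particles
             assigned to class k

— the partition with the broadest average spread of scores. This note
documents the model, the numerical machinery, the synthetic data the
package is validated on, and the limits of both.

## The score

The score of particle image `I_i` against reference `R_k` at pose `p` is

    s_{k,i} = 100 * NCC(CTF_i(project(R_k, p)), I_i)
              - (|shift(p) - shift(prior)| / 3 px)^2
              - min((geodesic(p, prior) / 10 deg)^2, 4)

where NCC is the masked, mean-subtracted, unit-normalized cross-correlation
and the prior pose is the consensus alignment. Constants (scale 100, prior
sigmas 3 px / 10 degrees, unit penalty weights) are readability choices: a
perfect self-match scores 100, and the selection criterion is invariant to
affine transformations of the score (tested), so the absolute scale cannot
change `K_best`. The angular penalty is capped at 4 score units so that a
pose far from the prior can still win when the data clearly demand it — a
robust-loss restraint rather than a hard one. The angular distance is the
geodesic angle of the relative rotation, which behaves correctly near the
Euler poles.

## Geometry and numerics

* Orientations are intrinsic ZYZ Euler triplets `(rot, tilt, psi)` applied
  to the volume, projected along +z, then shifted in-plane; the rotation
  and phase origin is voxel `B//2`. Real-space projection uses linear
  interpolation; its rotation-variant error (~1e-3 relative RMS on a
  32-voxel box) sets several test tolerances.
* The matching engine works on Fourier-cropped particle transforms
  ("working bands"). Frequencies are integer cycles per box, so a band is
  comparable across grid sizes and shifts stay in original pixels. Central
  slices of references are gathered with trilinear interpolation from a
  2x zero-padded 3D transform; reconstruction inserts slices into the
  same oversampled grid (Wiener constant: 0.01 of the mean filled
  interpolation weight, with a sinc^2 gridding correction). The 2x
  oversampling keeps the projection/reconstruction round-trip error below
  10% at 150-200 projections of a 32-voxel phantom.
* Translational search is a phase-matrix product evaluating the
  correlation on an integer pixel grid (window +-2..4 px); orientation
  search candidates are rotation-vector offsets composed onto the current
  orientation (well conditioned at all tilts, unlike raw Euler steps).
* Global (exhaustive) search uses a quasi-uniform grid (tilt rings spaced
  by the angular step, rot spacing widened by 1/sin tilt, psi exhaustive)
  and two stages: a zero-shift GEMM prescreen over the full grid — taking
  the maximum over a 3x3 grid of trial recenterings when no shift
  estimates exist yet, because an uncompensated shift of a few pixels
  silently mis-ranks orientations — followed by a full shift search over
  the best 24 grid points. On the last pass the best four orientation
  basins are polished locally before choosing, because slice-interpolation
  noise (~5%) can mis-rank nearly degenerate basins of pseudo-symmetric
  particles.

## Consensus refinement

Four global iterations against the initial reference (low-passed to 40 A,
as one would low-pass a deposited map to avoid reference bias) followed by
four local passes with a geometrically shrinking rotation-vector ball
(10 -> 0.75 degrees), re-reconstructing the consensus after every pass.
The global stage runs on a 16-frequency band, local refinement on 24.
All consensus reconstructions are gold-standard filtered (below). C1
symmetry is always assumed.

## Classification

For each K, particles are randomly partitioned into K seed groups (seeded;
runs in a sweep use `seed + K`), initial references reconstructed with
consensus poses, and the following loop runs until fewer than 1% of
assignments change (at most ~20 iterations): locally re-align every
particle against every class reference, assign each particle to its
highest-scoring class (hard argmax, ties to the lowest id), rebuild the
references. Empty classes are reseeded with the worst-scoring particles of
the largest class. Four numerical devices make this work at realistic
noise; all four are standard ideas in the field, combined here:

1. **Gold-standard cross-half scoring.** Each class keeps two half-set
   reconstructions (split by particle parity) filtered by their mutual FSC
   (`2*FSC/(1+FSC)` per shell), and every particle is scored against the
   half-map it did not contribute to. Without this, each particle
   correlates a little better with the reference that contains its own
   noise — measured at ~6 score units for 1500-particle classes, enough to
   freeze the initial random partition permanently.
2. **Deterministic annealing.** Reconstruction weights (never the reported
   assignments) are a softmax of the scores at a temperature that starts
   at 1.7x the median cross-class score range and decays by 0.8 per
   iteration to zero (up to 12 annealing iterations, then until
   assignments settle). The partition bifurcates smoothly out of the
   random initialization instead of locking into a shallow optimum;
   half-maps also carry a 0.55 running-average momentum to quench
   iteration-to-iteration reference noise.
3. **Score-weighted reconstruction.** Particles are weighted in the class
   maps by their consensus score percentile (clipped to [0.05, 1]), so the
   poorest particles — which cannot be aligned or classified at this
   SNR — do not erode the references. Their assignments and scores are
   still computed and reported.
4. **Pseudo-symmetry relaxation.** Rotations under which the consensus map
   nearly maps onto itself (self-correlation >= 0.7 on an 18-degree grid)
   are added as explicit search candidates, with the angular restraint
   measured to the nearest symmetry-equivalent of the prior. A particle
   that the consensus aligned into a wrong basin can then still land
   correctly in its class.

Per-class search candidates are a star of rotation-vector offsets
(+-5 degrees about each axis) plus the pseudo-symmetry jumps, with a
+-2 px shift window. Iterations run on a 20-frequency band — wide enough
to resolve the localized class differences, small enough to iterate
quickly; after convergence one wide re-alignment pass (+-20 degrees)
runs, and the final score matrix, class statistics and output maps are
recomputed on a 32-frequency band, where reference quality is
resolution-limited and therefore informative.

## Selection

`mean_score_variance` averages the per-class population variance (divisor
N_k, exactly as the estimator is defined; a sample-variance switch exists
but defaults off) over non-empty classes; single-member classes contribute
zero, empty classes are excluded loudly. Ties break toward the smallest K.
Classes whose mean assigned score is a low-side outlier among the class
means (gap to the other classes' mean above max(2.5 x their spread, 1.0
score units)) are flagged "noisy" — a diagnostic that never feeds back
into the selection. An outlier test on class means is used because the
within-class score spread (particle quality) is an order of magnitude
wider than any between-class mean difference, so a threshold phrased in
units of the score spread would never fire. `pick_refinement_maps` returns the
maps of the `K_best + 1` run with flagged sink classes dropped, since an
extra sink class drains low-quality particles and improves the remaining
reconstructions. The report also states the max-to-median ratio of the
per-K values: a ratio near 1 (flat bars) suggests that no discrete
partition stands out, as expected under continuous heterogeneity.

## What the synthetic data emulates — and what it does not

Each built-in scenario is a discrete mixture of Gaussian-blob phantoms in
a 48-voxel box at 3 A/voxel, 3000 particles, uniform orientations,
2 px Gaussian picking error, per-particle defocus in 8000-20000 A, and
white Gaussian noise at a stack-mean signal-to-noise power ratio of 0.1
(measured inside the particle mask of radius 0.45*box). Two design
choices are essential and deliberate:

* **Per-particle quality spread.** Individual particle SNRs are lognormal
  (log-sigma 0.6) around the stack mean, emulating ice thickness,
  radiation damage and picking quality. Per-particle scores *measure*
  quality; with uniform quality the score distributions carry no
  structure and the mean score variance is provably flat in K (we
  verified this: with a constant-SNR generator even ground-truth
  partitions do not move the criterion). Real stacks — including the
  in-silico mixtures the method was first demonstrated on, which kept
  real experimental noise — always carry this spread.
* **Fine structure.** Phantom lobes carry small satellite blobs
  (sigma ~1.5 voxels), so maps have signal at high shells and class
  references are resolution-limited the way real maps are: a class with
  fewer or worse particles loses its fine shells first, which is what
  couples reference quality to N_k and score spread.

The scenario geometries are irregular C1 clusters (distinct lobe
amplitudes, radii and heights). This too is deliberate: per-particle
alignment at SNR 0.1 in a small box is only feasible when nearly all
signal power carries orientation information; a dominant spherical core
or an exactly symmetric ring makes the orientation ill-determined and the
whole pipeline fails for reasons unrelated to the method under study.
Residual pseudo-symmetries are handled by the basin machinery above.

What passing on these data does **not** show: behavior with structured
(colored) noise, solvent background or radiation-damage envelopes; box
sizes and particle counts of real datasets (two orders of magnitude
larger); CTF estimation errors; or classes whose differences are at
near-atomic resolution. The built-in scenarios are frozen (geometry,
proportions, seeds) so all end-to-end numbers are reproducible.

## Known limitations

* Hard argmax assignment is the literal reading of the per-class
  statistics the criterion needs; likelihood-marginalized classification
  would use the data more efficiently at very low SNR.
* Shifts are searched on an integer pixel grid; sub-pixel refinement is
  not implemented.
* For strongly unbalanced mixtures the desk-scale criterion landscape
  becomes flat: in the rotary-state scenario (54/34/12 at n=3000), the
  K=2 and K=3 values differ by under 1%, because the ~40% lowest-quality
  particles cannot be aligned at this scale and their compression of the
  minority-class score spread offsets the purity gain. With true poses
  K=3 wins, and at real dataset sizes the effect vanishes; at desk scale
  the reported `K_best` for that scenario can land on 2. The same
  flat-bar behavior is what the method reports for genuinely continuous
  heterogeneity.
* The mean-variance criterion is compared only within a sweep; scores are
  never compared across runs with different K, so no cross-run
  normalization is applied (or needed).
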