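"""Per-particle quality-of-fit scores and bimodal score-based cleaning.

The score of particle image I against reference R at pose p is

    s = scale * NCC(CTF(project(R, p)), I)
        - lambda_shift * (|shift - prior_shift| / shift_sigma_prior)^2
        - min(lambda_angle * (geodesic(p, prior) / angle_sigma_prior)^2,
              angle_penalty_max)

where NCC is the masked, mean-subtracted, unit-normalized cross-correlation
(in [-1, 1]) between the CTF-modulated reference projection and the raw
image, inside a soft circular mask. A perfect self-match with pose equal to
the prior therefore scores ``scale`` (100 by default). The absolute scale is
arbitrary: the class-number selection criterion is invariant to affine score
transformations, so these constants only set readability.

Cleaning fits a two-component 1D Gaussian mixture to consensus scores and
keeps the particles to the right of the intersection between the modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import CTFParams, Image2D, Pose, Volume, angular_distance, apply_ctf, project, soft_circular_mask

logger = logging.getLogger(__name__)


@dataclass
class ScoreParams:
    """Constants of the restrained-correlation score."""

    scale: float = 100.0
    shift_sigma_prior: float = 3.0    # pixels
    angle_sigma_prior: float = 10.0   # degrees
    lambda_shift: float = 1.0
    lambda_angle: float = 1.0
    angle_penalty_max: float = 4.0  # cap: lets a much better distant pose win
    mask_radius_fraction: float = 0.9  # of box/2
    lowpass: float | None = None       # Angstrom; band limit of the NCC

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.shift_sigma_prior <= 0 or self.angle_sigma_prior <= 0:
            raise ValueError("prior sigmas must be positive")
        if self.lambda_shift < 0 or self.lambda_angle < 0:
            raise ValueError("penalty weights must be >= 0")


@dataclass
class ScoreMatrix:
    """N x K matrix of scores s_{k,i} from one classification run."""

    values: np.ndarray                 # (N, K)
    particle_ids: np.ndarray = None
    class_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-D (particles x classes)")
        n, k = self.values.shape
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite values")
        if n < k or k < 1:
            raise ValueError(f"need N >= K >= 1, got N={n}, K={k}")
        if self.particle_ids is None:
            self.particle_ids = np.arange(n)
        if self.class_ids is None:
            self.class_ids = np.arange(1, k + 1)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _lowpass2d(grid: np.ndarray, pixel_size: float, cutoff: float) -> np.ndarray:
    f = np.fft.fftfreq(grid.shape[0], d=pixel_size)
    ky, kx = np.meshgrid(f, f[: grid.shape[0] // 2 + 1], indexing="ij")
    keep = np.sqrt(kx**2 + ky**2) <= 1.0 / cutoff
    return np.fft.irfft2(np.fft.rfft2(grid) * keep, s=grid.shape)


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean-subtracted, unit-normalized correlation under a soft mask."""
    msum = mask.sum()
    am = (a - (a * mask).sum() / msum) * mask
    bm = (b - (b * mask).sum() / msum) * mask
    na = np.sqrt((am * am).sum())
    nb = np.sqrt((bm * bm).sum())
    if na == 0 or nb == 0:
        raise ZeroDivisionError("zero variance inside mask")
    return float((am * bm).sum() / (na * nb))


def score(
    reference: Volume,
    image: Image2D,
    pose: Pose,
    pose_prior: Pose,
    ctf: CTFParams,
    params: ScoreParams | None = None,
) -> float:
    """Restrained-correlation score of one image against one reference."""
    params = params or ScoreParams()
    if reference.box != image.box:
        raise ValueError(
            f"reference box {reference.box} does not match image box {image.box}")
    proj = apply_ctf(project(reference, pose), ctf)
    a, b = proj.grid, image.grid.astype(np.float64)
    if params.lowpass is not None:
        a = _lowpass2d(a, image.pixel_size, params.lowpass)
        b = _lowpass2d(b, image.pixel_size, params.lowpass)
    mask = soft_circular_mask(image.box, params.mask_radius_fraction * image.box / 2)

    ds = np.hypot(pose.shift_x - pose_prior.shift_x, pose.shift_y - pose_prior.shift_y)
    da = angular_distance(pose, pose_prior)
    penalty = (params.lambda_shift * (ds / params.shift_sigma_prior) ** 2
               + min(params.lambda_angle * (da / params.angle_sigma_prior) ** 2,
                     params.angle_penalty_max))
    try:
        ncc = masked_ncc(a, b, mask)
    except ZeroDivisionError:
        logger.warning("zero-variance image inside mask; score is penalty-only")
        return -penalty
    return params.scale * ncc - penalty


# --------------------------------------------------------------------------- #
# Bimodal score cleaning
# --------------------------------------------------------------------------- #


@dataclass
class BimodalFit:
    """Two-component 1D Gaussian mixture fitted to consensus scores."""

    means: tuple[float, float]    # sorted ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float              # equal-density point between the means
    degenerate: bool
    log_likelihood: float = float("nan")
    n_iter: int = 0


def _gmm2_em(x: np.ndarray, max_iter: int, tol: float):
    """Deterministic 2-component EM: components seeded at the 25th/75th
    percentiles with the pooled standard deviation."""
    q25, q75 = np.percentile(x, [25, 75])
    sd = max(float(np.std(x)), 1e-8)
    mu = np.array([q25, q75], dtype=np.float64)
    sig = np.array([sd, sd])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = (np.log(w)[None, :]
                - 0.5 * np.log(2 * np.pi * sig[None, :] ** 2)
                - 0.5 * ((x[:, None] - mu[None, :]) / sig[None, :]) ** 2)
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot[:, 0]) + m[:, 0]).sum())
        # M step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sig = np.sqrt((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk)
        sig = np.maximum(sig, 1e-8)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return mu, sig, w, ll, it


def _equal_density_point(mu, sig, w) -> float:
    """Score where the two weighted component densities are equal,
    restricted to the interval between the means."""
    (m1, m2), (s1, s2), (w1, w2) = mu, sig, w
    if np.isclose(s1, s2):
        s2_ = s1 * s1
        return float((m1 + m2) / 2.0 + s2_ * np.log(w1 / w2) / (m2 - m1))
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log((w1 * s2) / (w2 * s1)))
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots >= min(m1, m2)) & (roots <= max(m1, m2))]
    if inside.size:
        return float(inside[0])
    return float((m1 + m2) / 2.0)


def fit_bimodal(scores, max_iter: int = 500, tol: float = 1e-8) -> BimodalFit:
    """Fit a bimodal Gaussian mixture to a score distribution.

    The threshold is the score between the two component means where the
    weighted component densities intersect. The fit is flagged degenerate
    when the means are separated by less than half the pooled standard
    deviation, in which case the threshold is unreliable and cleaning should
    not be applied.
    """
    x = np.asarray(scores, dtype=np.float64).ravel()
    if x.size < 50:
        raise ValueError(f"need at least 50 scores for a stable fit, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores contain non-finite values")
    mu, sig, w, ll, it = _gmm2_em(x, max_iter, tol)
    order = np.argsort(mu)
    mu, sig, w = mu[order], sig[order], w[order]
    pooled = np.sqrt(w[0] * sig[0] ** 2 + w[1] * sig[1] ** 2)
    degenerate = abs(mu[1] - mu[0]) < 0.5 * pooled
    thr = _equal_density_point(mu, sig, w)
    return BimodalFit(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sig[0]), float(sig[1])),
        weights=(float(w[0]), float(w[1])),
        threshold=float(thr),
        degenerate=bool(degenerate),
        log_likelihood=ll,
        n_iter=it,
    )


def clean_particles(table, fit: BimodalFit, score_column: str = "score"):
    """Keep the particles whose consensus score falls at or above the
    intersection threshold (the clean mode). Record order is preserved.

    A degenerate fit refuses to clean and returns the table unchanged.
    """
    if fit.degenerate:
        logger.warning("degenerate bimodal fit: refusing to clean, "
                       "returning the table unchanged")
        return table
    return table.filter(table.df[score_column] >= fit.threshold)
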