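"""Batched band-limited projection-matching engine.

All heavy per-particle work (orientation search, scoring, per-class
reconstruction during classification) runs here on Fourier-cropped particle
transforms. Conventions:

* Particle images are soft-masked, mean-subtracted, transformed, and cropped
  to a working band of ``work_box`` frequencies (integer cycles per box). The
  physical box is unchanged, so frequency indices are comparable between the
  original and working grids; shifts stay in original-pixel units.
* Reference volumes are zero-padded 2x before transforming, and central
  slices are gathered at doubled coordinates (oversampled trilinear
  interpolation).
* The normalized cross-correlation (NCC) is computed within the working
  band; per-particle CTFs are applied to the image side of the correlation,
  which is equivalent to modulating the reference projection.
* Translational search is an FFT correlation evaluated on the original
  1-pixel grid (band transforms are re-embedded into a full-size grid).

Scores follow the same definition as :func:`scorevar.scoring.score`:
``scale * NCC - lambda_shift * (|shift - prior| / sigma_s)^2
- lambda_angle * (geodesic(pose, prior) / sigma_a)^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._kernels import gather_slices, scatter_slices
from .geometry import CTFParams, Volume, ctf_1d, soft_circular_mask

_CHUNK = 192  # particles per correlation chunk (bounds peak memory)


# --------------------------------------------------------------------------- #
# Stack preparation
# --------------------------------------------------------------------------- #


@dataclass
class WorkingStack:
    """Preprocessed particle stack at the engine's working band."""

    box: int                 # original box size (pixels)
    work_box: int            # retained band (frequencies per axis)
    pixel_size: float
    fimgs: np.ndarray        # (N, Bw, Bw) complex64, fft order, DC zeroed
    kimgs: np.ndarray        # (N, Bw*Bw) complex64, CTF * conj(fimgs)
    ctf_band: np.ndarray     # (N, Bw*Bw) float32 signed CTF values
    ctf2: np.ndarray         # (N, Bw*Bw) float32
    inorm: np.ndarray        # (N,) float32 band norms of masked images
    ctfs: list[CTFParams]
    images: np.ndarray       # (N, B, B) float32 raw images
    mask_radius_fraction: float

    @property
    def n(self) -> int:
        return self.fimgs.shape[0]

    @property
    def band_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        f = np.fft.fftfreq(self.work_box) * self.work_box
        ky, kx = np.meshgrid(f, f, indexing="ij")
        return kx.ravel(), ky.ravel()


def _fourier_crop(farr: np.ndarray, out: int) -> np.ndarray:
    """Crop fft-ordered 2D transforms (last two axes) to an ``out`` band."""
    h = out // 2
    idx = np.concatenate([np.arange(h), np.arange(-h, 0)])
    return farr[..., idx, :][..., :, idx]


def prepare_stack(
    images: np.ndarray,
    pixel_size: float,
    ctfs: list[CTFParams],
    work_box: int = 24,
    mask_radius_fraction: float = 0.9,
) -> WorkingStack:
    """Mask, transform and band-crop a particle stack for matching."""
    images = np.ascontiguousarray(images, dtype=np.float32)
    n, box, _ = images.shape
    if work_box > box:
        work_box = box
    mask = soft_circular_mask(box, mask_radius_fraction * box / 2).astype(np.float32)
    msum = mask.sum()
    means = (images * mask).sum(axis=(1, 2)) / msum
    masked = (images - means[:, None, None]) * mask

    # phase origin at the box center, matching the reference slice convention
    fimgs = np.fft.fft2(np.fft.ifftshift(masked, axes=(-2, -1))).astype(np.complex64)
    fimgs = np.ascontiguousarray(_fourier_crop(fimgs, work_box))
    fimgs[:, 0, 0] = 0.0

    f = np.fft.fftfreq(work_box) * work_box
    ky, kx = np.meshgrid(f, f, indexing="ij")
    kk = np.sqrt(kx**2 + ky**2) / (box * pixel_size)  # 1/Angstrom
    ctf_band = np.stack([ctf_1d(kk, c) for c in ctfs]).astype(np.float32)

    flat = fimgs.reshape(n, -1)
    cflat = ctf_band.reshape(n, -1)
    inorm = np.sqrt((np.abs(flat) ** 2).sum(axis=1)).astype(np.float32)
    inorm[inorm == 0] = 1.0
    return WorkingStack(
        box=box,
        work_box=work_box,
        pixel_size=pixel_size,
        fimgs=fimgs,
        kimgs=np.ascontiguousarray(cflat * np.conj(flat)),
        ctf_band=np.ascontiguousarray(cflat),
        ctf2=np.ascontiguousarray(cflat * cflat),
        inorm=inorm,
        ctfs=list(ctfs),
        images=images,
        mask_radius_fraction=mask_radius_fraction,
    )


# --------------------------------------------------------------------------- #
# Reference transforms and slices
# --------------------------------------------------------------------------- #


@dataclass
class ReferenceFT:
    """2x zero-padded centered Fourier transform of a reference map."""

    fvol: np.ndarray  # (2b, 2b, 2b) complex64, centered
    box: int          # reference grid size b


def reference_ft(vol: Volume) -> ReferenceFT:
    b = vol.box
    p = 2 * b
    c = p // 2 - b // 2
    padded = np.zeros((p, p, p), dtype=np.float64)
    padded[c:c + b, c:c + b, c:c + b] = vol.grid
    fvol = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
    return ReferenceFT(fvol.astype(np.complex64), b)


def slice_band(ref: ReferenceFT, rotations: np.ndarray, ws: WorkingStack) -> np.ndarray:
    """Projection transforms (C, Bw*Bw) of the reference at many orientations."""
    kx, ky = ws.band_freqs
    out = np.empty((rotations.shape[0], kx.size), dtype=np.complex64)
    gather_slices(ref.fvol, np.ascontiguousarray(rotations, dtype=np.float64),
                  2.0 * kx, 2.0 * ky, out)
    out[:, 0] = 0.0  # mean subtraction of the projection
    return out


def euler_matrices(euler: np.ndarray) -> np.ndarray:
    """(M, 3, 3) xyz rotation matrices from (M, 3) ZYZ Euler degrees."""
    return Rotation.from_euler("ZYZ", np.atleast_2d(euler), degrees=True).as_matrix()


def orientation_grid(angular_step: float) -> np.ndarray:
    """Quasi-uniform (rot, tilt, psi) grid at the given angular step.

    Tilt rings are spaced by ``angular_step`` with rot spacing widened by
    1/sin(tilt); psi is exhaustive at ``angular_step``.
    """
    if not 0 < angular_step <= 60:
        raise ValueError("angular_step must lie in (0, 60] degrees")
    psis = np.arange(0.0, 360.0, angular_step)
    out = []
    n_tilt = int(round(180.0 / angular_step))
    for tilt in np.linspace(0.0, 180.0, n_tilt + 1):
        s = np.sin(np.radians(tilt))
        n_rot = max(1, int(round(360.0 * s / angular_step)))
        for rot in np.arange(n_rot) * (360.0 / n_rot):
            for psi in psis:
                out.append((rot, tilt, psi))
    return np.array(out, dtype=np.float64)


# --------------------------------------------------------------------------- #
# Correlation search
# --------------------------------------------------------------------------- #


def _shift_phase(ws: WorkingStack, shifts: np.ndarray) -> np.ndarray:
    """Phase ramps e^{-2 pi i k.s / B} for (N, 2) pixel shifts.

    Integer shifts (the common case: the translational search works on the
    pixel grid) are served from per-axis lookup tables.
    """
    shifts = np.asarray(shifts, dtype=np.float64)
    ints = np.rint(shifts)
    smax = ws.box // 2
    if np.array_equal(ints, shifts) and np.all(np.abs(ints) <= smax):
        tab = getattr(ws, "_phase_tables", None)
        if tab is None:
            kx, ky = ws.band_freqs
            srange = np.arange(-smax, smax + 1)
            px = np.exp(-2j * np.pi * np.outer(srange, kx) / ws.box)
            py = np.exp(-2j * np.pi * np.outer(srange, ky) / ws.box)
            tab = (px.astype(np.complex64), py.astype(np.complex64), smax)
            ws._phase_tables = tab
        px, py, off = tab
        ix = ints[:, 0].astype(np.int64) + off
        iy = ints[:, 1].astype(np.int64) + off
        return px[ix] * py[iy]
    kx, ky = ws.band_freqs
    ph = -2j * np.pi * (np.outer(shifts[:, 0], kx) + np.outer(shifts[:, 1], ky)) / ws.box
    return np.exp(ph).astype(np.complex64)


def _shift_matrix(ws: WorkingStack, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase matrix evaluating the correlation on a (2w+1)^2 shift grid.

    Returns ``(E, dx, dy)`` where ``corr = Re[X @ E]`` gives the correlation
    at relative integer shifts ``(dx[j], dy[j])`` for band arrays X that
    already carry the base-shift phase.
    """
    kx, ky = ws.band_freqs
    offs = np.arange(-window, window + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dxf = dx.ravel().astype(np.float64)
    dyf = dy.ravel().astype(np.float64)
    ph = -2j * np.pi * (np.outer(kx, dxf) + np.outer(ky, dyf)) / ws.box
    return np.exp(ph).astype(np.complex64), dxf, dyf


def global_search(
    ws: WorkingStack,
    ref: ReferenceFT,
    angular_step: float,
    max_shift: float,
    shifts0: np.ndarray | None = None,
    top: int = 4,
    n_candidates: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive orientation search with FFT translational search.

    Two stages: a zero-shift NCC prescreen of the full orientation grid,
    then a full translational search over the ``top`` prescreen candidates.
    When per-particle shift estimates ``shifts0`` are available the
    prescreen recenters each particle by them; otherwise it takes the
    maximum over a coarse grid of trial recenterings, because an
    uncompensated shift of a few pixels decorrelates the upper band and
    silently mis-ranks orientations.

    Returns ``(euler (N,3), shifts (N,2), ncc (N,))``.
    """
    n = ws.n
    grid = orientation_grid(angular_step)
    mats = euler_matrices(grid)
    pref = slice_band(ref, mats, ws)                      # (C, F)
    p2 = (np.abs(pref) ** 2).astype(np.float32)

    if shifts0 is None:
        t = max_shift * 0.75
        trials = np.array([[0.0, 0.0], [t, 0.0], [-t, 0.0], [0.0, t],
                           [0.0, -t], [t, t], [t, -t], [-t, t], [-t, -t]])
    else:
        trials = None

    pnorm = np.sqrt(np.maximum(p2 @ ws.ctf2.T, 1e-30))    # (C, N)
    if trials is None:
        kimgs = ws.kimgs * _shift_phase(ws, np.asarray(shifts0, dtype=np.float64))
        ncc0 = np.real(pref @ kimgs.T) / (pnorm * ws.inorm[None, :])
    else:
        ncc0 = np.full((grid.shape[0], n), -np.inf, dtype=np.float32)
        for tr in trials:
            kimgs = ws.kimgs * _shift_phase(ws, np.tile(tr, (n, 1)))
            c = np.real(pref @ kimgs.T) / (pnorm * ws.inorm[None, :])
            np.maximum(ncc0, c, out=ncc0)
    top = min(top, grid.shape[0])
    cand = np.argpartition(-ncc0, top - 1, axis=0)[:top]  # (top, N)

    # stage 2: full shift search over the retained candidates
    nc = max(1, min(n_candidates, top))
    best_ncc = np.zeros((n, nc))
    best_orient = np.zeros((n, nc), dtype=np.int64)
    best_shift = np.zeros((n, nc, 2))
    w = int(round(max_shift))
    eph, dxf, dyf = _shift_matrix(ws, w)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        m = hi - lo
        sel = cand[:, lo:hi]                              # (top, m)
        x = pref[sel] * ws.kimgs[None, lo:hi]             # (top, m, F)
        corr = np.real(x.reshape(top * m, -1) @ eph).reshape(top, m, -1)
        pn = pnorm[sel, np.arange(lo, hi)[None, :]]       # (top, m)
        nccs = corr / (pn[..., None] * ws.inorm[lo:hi, None])
        # per-orientation best shift, then rank orientations per particle
        per_cand = nccs.max(axis=2)                       # (top, m)
        s_at = nccs.argmax(axis=2)
        order = np.argsort(-per_cand, axis=0)[:nc]        # (nc, m)
        mi = np.arange(m)[None, :]
        best_ncc[lo:hi] = per_cand[order, mi].T
        best_orient[lo:hi] = sel[order, mi].T
        si = s_at[order, mi]
        best_shift[lo:hi, :, 0] = dxf[si].T
        best_shift[lo:hi, :, 1] = dyf[si].T
    if n_candidates <= 1:
        return grid[best_orient[:, 0]], best_shift[:, 0], best_ncc[:, 0]
    return grid[best_orient], best_shift, best_ncc


def local_search(
    ws: WorkingStack,
    ref: ReferenceFT,
    euler: np.ndarray,
    shifts: np.ndarray,
    offsets: np.ndarray,
    shift_window: float,
    score_params,
    prior_euler: np.ndarray | None = None,
    prior_shifts: np.ndarray | None = None,
    subset: np.ndarray | None = None,
    prior_sym_mats: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Restricted orientation/translation search around per-particle poses.

    ``offsets`` is an (M, 3) array of rotation-vector offsets (degrees)
    composed onto each particle's current orientation; rotation vectors are
    used instead of raw Euler increments because they stay well conditioned
    near tilt 0/180. Translations are searched on the integer pixel grid
    within ``shift_window`` of the current shift. The returned best pose
    maximizes the restrained score (NCC scaled by ``score_params.scale``
    minus the quadratic pose-deviation penalties relative to the prior pose,
    which defaults to the current pose).

    Returns ``(euler (N,3), shifts (N,2), score (N,), ncc (N,))`` for the
    particles in ``subset`` (all by default).
    """
    sp = score_params
    if subset is None:
        subset = np.arange(ws.n)
    subset = np.asarray(subset)
    n = subset.size
    euler = np.asarray(euler, dtype=np.float64)[subset]
    shifts = np.asarray(shifts, dtype=np.float64)[subset]
    offsets = np.atleast_2d(np.asarray(offsets, dtype=np.float64))
    m = offsets.shape[0]

    if prior_euler is None:
        prior_euler = euler
    else:
        prior_euler = np.asarray(prior_euler, dtype=np.float64)[subset]
    if prior_shifts is None:
        prior_shifts = shifts
    else:
        prior_shifts = np.asarray(prior_shifts, dtype=np.float64)[subset]

    w = int(round(shift_window))
    eph, dxf, dyf = _shift_matrix(ws, w)
    ns = dxf.size
    smax = ws.box / 4

    prior_mats = euler_matrices(prior_euler)
    out_euler = np.empty((n, 3))
    out_shift = np.empty((n, 2))
    out_score = np.empty(n)
    out_ncc = np.empty(n)

    off_mats = Rotation.from_rotvec(offsets, degrees=True).as_matrix()  # (m,3,3)
    base_mats = euler_matrices(euler)
    base_shifts = np.rint(shifts).astype(np.int64)
    base_phase = _shift_phase(ws, base_shifts.astype(np.float64))

    chunk = max(1, _CHUNK * 8 // max(m, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        nb = hi - lo
        mats = np.einsum("bij,mjk->bmik", base_mats[lo:hi], off_mats)
        pref = slice_band(ref, mats.reshape(-1, 3, 3), ws).reshape(nb, m, -1)
        rows = subset[lo:hi]
        x = pref * (ws.kimgs[rows] * base_phase[lo:hi])[:, None, :]  # (nb, m, F)
        corr = np.real(x.reshape(nb * m, -1) @ eph).reshape(nb, m, ns)

        # absolute integer shift grid per particle, centered on current shift
        sx = base_shifts[lo:hi, 0, None] + dxf[None, :]              # (nb, ns)
        sy = base_shifts[lo:hi, 1, None] + dyf[None, :]

        p2 = (np.abs(pref) ** 2)
        pnorm = np.sqrt(np.maximum(
            np.einsum("bmf,bf->bm", p2, ws.ctf2[rows]), 1e-30))
        ncc = corr / (pnorm[:, :, None] * ws.inorm[rows, None, None])

        # restraint penalties; with pseudo-symmetry relaxation the angular
        # deviation is measured to the nearest symmetry-equivalent prior
        tr = np.einsum("bij,bmij->bm", prior_mats[lo:hi], mats)
        if prior_sym_mats is not None and len(prior_sym_mats):
            for sm in prior_sym_mats:
                pm = prior_mats[lo:hi] @ sm
                np.maximum(tr, np.einsum("bij,bmij->bm", pm, mats), out=tr)
        ang = np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))
        pen_a = np.minimum(sp.lambda_angle * (ang / sp.angle_sigma_prior) ** 2,
                           getattr(sp, "angle_penalty_max", 4.0))
        dsx = sx - prior_shifts[lo:hi, 0, None]
        dsy = sy - prior_shifts[lo:hi, 1, None]
        pen_s = sp.lambda_shift * ((dsx**2 + dsy**2) / sp.shift_sigma_prior**2)
        total = sp.scale * ncc - pen_a[:, :, None] - pen_s[:, None, :]
        # forbid shifts beyond the B/4 bound
        bad = (np.abs(sx) > smax) | (np.abs(sy) > smax)
        total = total - 1e9 * bad[:, None, :]

        v = total.reshape(nb, -1)
        arg = np.argmax(v, axis=1)
        mi, si = np.unravel_index(arg, (m, ns))
        out_score[lo:hi] = v[np.arange(nb), arg]
        out_ncc[lo:hi] = ncc[np.arange(nb), mi, si]
        best_mats = mats[np.arange(nb), mi]
        with warnings.catch_warnings():
            # ZYZ conversion at tilt ~ 0/180 is gimbal-degenerate; any of
            # the equivalent (rot, psi) pairs is fine here
            warnings.simplefilter("ignore", UserWarning)
            out_euler[lo:hi] = Rotation.from_matrix(best_mats).as_euler(
                "ZYZ", degrees=True) % np.array([360.0, 360.0, 360.0])
        out_shift[lo:hi, 0] = sx[np.arange(nb), si]
        out_shift[lo:hi, 1] = sy[np.arange(nb), si]
    return out_euler, out_shift, out_score, out_ncc


# --------------------------------------------------------------------------- #
# Working-size reconstruction
# --------------------------------------------------------------------------- #


def reconstruct_working(
    ws: WorkingStack,
    euler: np.ndarray,
    shifts: np.ndarray,
    subset: np.ndarray | None = None,
    wiener: float = 0.01,
    weights: np.ndarray | None = None,
) -> Volume:
    """Band-limited reconstruction from the working-stack transforms.

    ``weights`` are optional per-particle occupancies (for soft-weighted
    class averages). Returns a ``work_box`` cube whose voxel size is scaled
    so the physical box matches the original stack.
    """
    if subset is None:
        subset = np.arange(ws.n)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("cannot reconstruct from an empty class (no images)")
    bw = ws.work_box
    pad = 2 * bw
    kx, ky = ws.band_freqs
    plane = np.stack([kx, ky, np.zeros_like(kx)], axis=1)

    euler = np.asarray(euler, dtype=np.float64)[subset]
    shifts = np.asarray(shifts, dtype=np.float64)[subset]
    mats = euler_matrices(euler)
    phases = np.conj(_shift_phase(ws, shifts))  # undo shift: e^{+2 pi i k.s/B}

    num = np.zeros((pad, pad, pad), dtype=np.complex128)
    den = np.zeros((pad, pad, pad), dtype=np.float64)
    flat = ws.fimgs.reshape(ws.n, -1)
    for j, i in enumerate(subset):
        w = 1.0 if weights is None else float(weights[j])
        vals = flat[i] * phases[j] * (ws.ctf_band[i] * w)  # phase-corrected
        coords_xyz = 2.0 * (plane @ mats[j])
        coords = (coords_xyz[:, ::-1] + pad // 2).astype(np.float32)
        scatter_slices(num, den, coords, vals.astype(np.complex128),
                       (ws.ctf2[i] * w).astype(np.float64))
    filled = den[den > 0]
    fvol = num / (den + wiener * filled.mean())
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(fvol))).real
    ax = np.sinc((np.arange(pad) - pad // 2) / pad) ** 2
    vol = vol / (ax[:, None, None] * ax[None, :, None] * ax[None, None, :])
    c = pad // 2 - bw // 2
    voxel = ws.pixel_size * ws.box / bw
    return Volume(vol[c:c + bw, c:c + bw, c:c + bw], voxel)


def pseudo_symmetry_rotations(
    vol: Volume,
    threshold: float = 0.7,
    step: float = 18.0,
    separation: float = 30.0,
    max_rotations: int = 4,
) -> np.ndarray:
    """Rotation vectors (degrees) under which a map nearly maps onto itself.

    A pseudo-symmetric reference produces discrete alternative alignment
    basins; the returned rotations let a search jump between those basins
    explicitly. Rotations are detected by real-space rotational
    self-correlation on a coarse orientation grid, keeping peaks above
    ``threshold`` that are at least ``separation`` degrees apart.
    """
    from scipy.spatial.transform import Rotation

    from .geometry import Pose, rotate_volume

    grid = orientation_grid(step)
    mats = euler_matrices(grid)
    v0 = vol.grid - vol.grid.mean()
    n0 = np.sqrt((v0**2).sum())
    if n0 == 0:
        return np.zeros((0, 3))
    cands = []
    for g, m in zip(grid, mats):
        ang = np.degrees(np.arccos(np.clip((np.trace(m) - 1.0) / 2.0, -1, 1)))
        if ang < separation:
            continue
        w = rotate_volume(vol, Pose(*g)).grid
        w = w - w.mean()
        nw = np.sqrt((w**2).sum())
        if nw == 0:
            continue
        c = float((v0 * w).sum() / (n0 * nw))
        if c >= threshold:
            cands.append((c, m))
    cands.sort(key=lambda t: -t[0])
    kept: list[np.ndarray] = []
    for c, m in cands:
        far = all(
            np.degrees(np.arccos(np.clip((np.trace(m.T @ m2) - 1) / 2, -1, 1)))
            > separation for m2 in kept)
        if far:
            kept.append(m)
        if len(kept) >= max_rotations:
            break
    if not kept:
        return np.zeros((0, 3))
    return Rotation.from_matrix(np.stack(kept)).as_rotvec(degrees=True)


def _shell_filter(vol: Volume, weights: np.ndarray) -> Volume:
    """Multiply a map's Fourier shells by per-shell weights."""
    b = vol.box
    f = np.fft.fftfreq(b) * b
    kz, ky, kx = np.meshgrid(f, f, f, indexing="ij")
    sh = np.minimum(np.rint(np.sqrt(kz**2 + ky**2 + kx**2)).astype(int),
                    weights.size - 1)
    out = np.fft.ifftn(np.fft.fftn(vol.grid.astype(np.float64)) * weights[sh]).real
    return Volume(out, vol.voxel_size)


def class_reference_halves(
    ws: WorkingStack,
    euler: np.ndarray,
    shifts: np.ndarray,
    subset: np.ndarray,
    wiener: float = 0.01,
) -> tuple[Volume, Volume, Volume]:
    """Gold-standard class references for cross-half scoring.

    The class members are split by global particle parity into two
    half-set reconstructions; their shell-wise FSC yields a Cref-style
    weight ``2 FSC / (1 + FSC)`` that filters reference noise away. Scoring
    each particle against the half-map it did not contribute to removes the
    self-noise bias that would otherwise freeze the initial random
    partition (a particle always correlates a little better with a
    reference that contains its own noise).

    Returns ``(map_for_even_particles, map_for_odd_particles, full_map)``:
    the first is built from the odd half, the second from the even half,
    and the third from the average (for reporting and output).
    """
    from .geometry import fsc as _fsc

    subset = np.asarray(subset)
    h0 = subset[subset % 2 == 0]
    h1 = subset[subset % 2 == 1]
    if h0.size < 2 or h1.size < 2:
        full = reconstruct_working(ws, euler, shifts, subset=subset,
                                   wiener=wiener)
        return full, full, full
    rec0 = reconstruct_working(ws, euler, shifts, subset=h0, wiener=wiener)
    rec1 = reconstruct_working(ws, euler, shifts, subset=h1, wiener=wiener)
    _, cc = _fsc(rec0, rec1)
    w = np.clip(2.0 * cc / (1.0 + np.abs(cc)), 0.0, 1.0)
    w[0] = 1.0
    full = Volume(0.5 * (rec0.grid + rec1.grid), rec0.voxel_size)
    return (_shell_filter(rec1, w), _shell_filter(rec0, w),
            _shell_filter(full, w))
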