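"""Projection geometry for single-particle analysis.

Conventions
-----------
* A :class:`Volume` stores a cubic density grid indexed ``[z, y, x]`` (MRC
  section/row/column order) with a physical voxel size in Angstrom.
* A :class:`Pose` is an intrinsic ZYZ Euler rotation ``(rot, tilt, psi)`` in
  degrees applied to the volume, followed by projection along +z and a 2D
  shift ``(shift_x, shift_y)`` in pixels applied to the projected image.
* The rotation/phase origin sits at voxel ``B // 2`` on every axis (B even).
* The contrast transfer function uses the convention ``CTF(0) = -A`` (dark
  protein on a bright background); the simulator and the matching engine use
  the same convention, so the global sign cancels internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #


@dataclass
class Volume:
    """Cubic real-valued density map with a physical voxel size."""

    grid: np.ndarray  # shape (B, B, B), indexed [z, y, x]
    voxel_size: float  # Angstrom per voxel

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError(f"volume grid must be cubic, got shape {self.grid.shape}")
        b = self.grid.shape[0]
        if b < 16 or b % 2:
            raise ValueError(f"box size must be even and >= 16, got {b}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def box(self) -> int:
        return self.grid.shape[0]


@dataclass
class Image2D:
    """Square real-valued image with a physical pixel size."""

    grid: np.ndarray  # shape (B, B), indexed [y, x]
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError(f"image must be square, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def box(self) -> int:
        return self.grid.shape[0]


@dataclass
class Pose:
    """Intrinsic ZYZ Euler angles (degrees) plus an in-plane shift (pixels)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self) -> None:
        self.rot = float(self.rot) % 360.0
        self.psi = float(self.psi) % 360.0
        self.tilt = float(self.tilt)
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt must lie in [0, 180], got {self.tilt}")

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, shift_x: float = 0.0, shift_y: float = 0.0
    ) -> "Pose":
        rot, tilt, psi = Rotation.from_matrix(m).as_euler("ZYZ", degrees=True)
        return cls(rot % 360.0, float(np.clip(tilt, 0.0, 180.0)), psi % 360.0,
                   shift_x, shift_y)


def angular_distance(a: Pose | np.ndarray, b: Pose | np.ndarray) -> float:
    """Geodesic distance (degrees) between two orientations.

    Computed as the rotation angle of the relative rotation matrix, which is
    free of Euler-gimbal artifacts near tilt 0/180.
    """
    ma = a.matrix() if isinstance(a, Pose) else np.asarray(a)
    mb = b.matrix() if isinstance(b, Pose) else np.asarray(b)
    tr = np.trace(ma.T @ mb)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


@dataclass
class CTFParams:
    """Contrast transfer function parameters (no astigmatism)."""

    defocus: float  # Angstrom, > 0 means underfocus
    voltage: float = 300.0  # kV
    spherical_aberration: float = 2.7  # mm
    amplitude_contrast: float = 0.07  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.defocus <= 0:
            raise ValueError("defocus must be positive (underfocus)")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1]")
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        v = self.voltage * 1e3
        return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


def ctf_1d(k: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """CTF(k) for spatial frequency k in 1/Angstrom.

    CTF(k) = -[sqrt(1 - A^2) sin(chi) + A cos(chi)],
    chi(k) = pi * lambda * z * k^2 - (pi/2) * lambda^3 * Cs * k^4.
    """
    k = np.asarray(k, dtype=np.float64)
    lam = ctf.wavelength
    cs = ctf.spherical_aberration * 1e7  # mm -> Angstrom
    chi = np.pi * lam * ctf.defocus * k**2 - 0.5 * np.pi * lam**3 * cs * k**4
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_grid(box: int, pixel_size: float, ctf: CTFParams, rfft: bool = False) -> np.ndarray:
    """CTF sampled on the 2D FFT frequency grid of a box x box image."""
    ky = np.fft.fftfreq(box, d=pixel_size)
    kx = np.fft.rfftfreq(box, d=pixel_size) if rfft else np.fft.fftfreq(box, d=pixel_size)
    kk = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    return ctf_1d(kk, ctf)


# --------------------------------------------------------------------------- #
# Core operations
# --------------------------------------------------------------------------- #


def rotate_volume(volume: Volume, pose: Pose) -> Volume:
    """Actively rotate a volume by the pose's rotation about the box center.

    A density feature at position p (relative to the center) moves to R p.
    Linear interpolation.
    """
    b = volume.box
    c = b // 2
    r = pose.matrix()
    # index order is (z, y, x): conjugate the xyz matrix by the axis reversal
    p = np.eye(3)[::-1]
    a = p @ r.T @ p  # pulling map: input_index = a @ (output_index - c) + c
    center = np.full(3, c, dtype=np.float64)
    offset = center - a @ center
    out = ndimage.affine_transform(
        volume.grid.astype(np.float64), a, offset=offset, order=1,
        mode="constant", cval=0.0,
    )
    return Volume(out, volume.voxel_size)


def project(volume: Volume, pose: Pose) -> Image2D:
    """Line-integral projection along +z of the pose-rotated volume.

    The projected image is then translated by ``(shift_x, shift_y)`` pixels.
    Total intensity is conserved up to interpolation at the box edge.
    """
    rotated = rotate_volume(volume, pose)
    proj = rotated.grid.sum(axis=0)
    if pose.shift_x or pose.shift_y:
        proj = ndimage.shift(proj, (pose.shift_y, pose.shift_x), order=1,
                             mode="constant", cval=0.0)
    return Image2D(proj, volume.voxel_size)


def apply_ctf(image: Image2D, ctf: CTFParams) -> Image2D:
    """Multiply the image's Fourier transform by the CTF."""
    h = ctf_grid(image.box, image.pixel_size, ctf, rfft=True)
    out = np.fft.irfft2(np.fft.rfft2(image.grid.astype(np.float64)) * h,
                        s=image.grid.shape)
    return Image2D(out, image.pixel_size)


def reconstruct(
    images: list[Image2D],
    poses: list[Pose],
    ctfs: list[CTFParams] | None = None,
    wiener: float = 0.01,
) -> Volume:
    """Direct Fourier (slice-insertion) reconstruction with Wiener weights.

    Each image's centered 2D FFT is phase-shifted back to the origin and
    spread with trilinear weights into a 2x oversampled (zero-padded) 3D
    Fourier grid; the accumulated grid is divided by the accumulated
    (CTF^2-weighted) interpolation weight regularized by
    ``wiener * mean_weight``, inverse transformed, corrected for the
    interpolation kernel roll-off and cropped back to the original box.
    """
    if len(images) == 0:
        raise ValueError("cannot reconstruct from an empty class (no images)")
    if len(images) != len(poses) or (ctfs is not None and len(ctfs) != len(images)):
        raise ValueError("images, poses and ctfs must have equal length")
    box = images[0].box
    pixel = images[0].pixel_size
    pad = 2 * box  # oversampled grid; image DFT values land at doubled coords

    from ._kernels import scatter_slices  # deferred: numba compile on demand

    f = np.fft.fftshift(np.fft.fftfreq(box)) * box
    kx, ky = np.meshgrid(f, f, indexing="xy")
    plane = np.stack([kx.ravel(), ky.ravel(), np.zeros(box * box)], axis=1)

    num = np.zeros((pad, pad, pad), dtype=np.complex128)
    den = np.zeros((pad, pad, pad), dtype=np.float64)

    for i, (img, pose) in enumerate(zip(images, poses)):
        if img.box != box:
            raise ValueError("all images must share the same box size")
        fimg = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img.grid.astype(np.float64))))
        # undo the in-image shift before insertion
        phase = np.exp(2j * np.pi * (kx * pose.shift_x + ky * pose.shift_y) / box)
        fimg = fimg * phase
        if ctfs is not None:
            h = ctf_1d(np.sqrt(kx**2 + ky**2) / (box * pixel), ctfs[i])
            vals = (fimg * h).ravel()
            wts = (h * h).ravel()
        else:
            vals = fimg.ravel()
            wts = np.ones(box * box)
        coords_xyz = 2.0 * (plane @ poses[i].matrix())  # R^T k, oversampled
        coords = (coords_xyz[:, ::-1] + pad // 2).astype(np.float32)
        scatter_slices(num, den, coords, vals.astype(np.complex128),
                       wts.astype(np.float64))

    filled = den[den > 0]
    if filled.size == 0:
        raise ValueError("no Fourier samples inserted")
    fvol = num / (den + wiener * filled.mean())
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(fvol))).real
    # gridding correction for the trilinear kernel roll-off on the padded grid
    ax = np.sinc((np.arange(pad) - pad // 2) / pad) ** 2
    vol = vol / (ax[:, None, None] * ax[None, :, None] * ax[None, None, :])
    c = pad // 2 - box // 2
    return Volume(vol[c:c + box, c:c + box, c:c + box], pixel)


def fsc(vol_a: Volume, vol_b: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Fourier shell correlation between two maps.

    Returns ``(freq, corr)`` where freq is in 1/Angstrom (shell centers) and
    corr the per-shell normalized cross-correlation of the Fourier transforms.
    """
    if vol_a.box != vol_b.box or vol_a.voxel_size != vol_b.voxel_size:
        raise ValueError("volumes must share grid size and voxel size")
    b = vol_a.box
    fa = np.fft.fftshift(np.fft.fftn(vol_a.grid.astype(np.float64)))
    fb = np.fft.fftshift(np.fft.fftn(vol_b.grid.astype(np.float64)))
    f = np.fft.fftshift(np.fft.fftfreq(b)) * b
    kz, kyy, kxx = np.meshgrid(f, f, f, indexing="ij")
    shell = np.rint(np.sqrt(kz**2 + kyy**2 + kxx**2)).astype(int).ravel()
    nshell = b // 2
    cross = np.bincount(shell, weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=nshell)[:nshell]
    pa = np.bincount(shell, weights=np.abs(fa.ravel()) ** 2, minlength=nshell)[:nshell]
    pb = np.bincount(shell, weights=np.abs(fb.ravel()) ** 2, minlength=nshell)[:nshell]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cross / np.sqrt(pa * pb)
    corr = np.nan_to_num(corr, nan=0.0)
    freq = np.arange(nshell) / (b * vol_a.voxel_size)
    return freq, corr


def fsc_resolution(freq: np.ndarray, corr: np.ndarray, threshold: float = 0.143) -> float:
    """Resolution (Angstrom) at the first crossing of the FSC threshold."""
    below = np.nonzero(corr[1:] < threshold)[0]
    if below.size == 0:
        # never drops below threshold: resolution is at the band limit
        return float(1.0 / freq[-1]) if freq[-1] > 0 else np.inf
    i = below[0] + 1
    # linear interpolation between shells i-1 and i
    c0, c1 = corr[i - 1], corr[i]
    f0, f1 = freq[i - 1], freq[i]
    fx = f0 if c0 == c1 else f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return float(1.0 / fx) if fx > 0 else np.inf


def lowpass_volume(volume: Volume, cutoff: float, edge_width: float = 0.1) -> Volume:
    """Low-pass filter a map at ``cutoff`` Angstrom with a cosine edge.

    ``edge_width`` is the half-width of the cosine roll-off as a fraction of
    the cutoff frequency.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive (Angstrom)")
    b = volume.box
    f = np.fft.fftfreq(b, d=volume.voxel_size)
    fz, fy, fx = np.meshgrid(f, f, f, indexing="ij")
    k = np.sqrt(fz**2 + fy**2 + fx**2)
    kc = 1.0 / cutoff
    w = kc * edge_width
    filt = np.clip(0.5 * (1.0 + np.cos(np.pi * (k - kc) / max(w, 1e-9))), 0.0, 1.0)
    filt[k <= kc] = 1.0
    filt[k >= kc + w] = 0.0
    out = np.fft.ifftn(np.fft.fftn(volume.grid.astype(np.float64)) * filt).real
    return Volume(out, volume.voxel_size)


def soft_circular_mask(box: int, radius: float, edge: float = 3.0) -> np.ndarray:
    """2D soft-edged circular mask centered at the phase origin (B//2)."""
    c = box // 2
    y, x = np.mgrid[0:box, 0:box]
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    m = np.clip((radius - r) / edge + 0.5, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * m))
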