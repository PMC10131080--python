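"""Numba kernels for central-slice gather/scatter in Fourier space.

These are the two memory-bound inner loops of the projection-matching engine:
extracting central slices of a 3D transform at arbitrary orientations
(projection) and spreading 2D transforms back into the 3D grid
(back-projection). Trilinear interpolation in both directions.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(fastmath=True)
def gather_slices(fvol, rotations, kx, ky, out):
    """Extract central slices of a centered 3D FFT at many orientations.

    fvol      : (B, B, B) complex64, centered (DC at index B//2 on each axis)
    rotations : (C, 3, 3) float64 xyz rotation matrices (active volume rotation)
    kx, ky    : (Nf,) float64 slice-plane frequencies in index units
    out       : (C, Nf) complex64, filled with \\hat{V}(R^T (kx, ky, 0))
    """
    b = fvol.shape[0]
    c0 = b // 2
    nc = rotations.shape[0]
    nf = kx.shape[0]
    for c in range(nc):
        r = rotations[c]
        for f in range(nf):
            x = r[0, 0] * kx[f] + r[1, 0] * ky[f]
            y = r[0, 1] * kx[f] + r[1, 1] * ky[f]
            z = r[0, 2] * kx[f] + r[1, 2] * ky[f]
            gz = z + c0
            gy = y + c0
            gx = x + c0
            iz = int(np.floor(gz))
            iy = int(np.floor(gy))
            ix = int(np.floor(gx))
            if iz < 0 or iy < 0 or ix < 0 or iz >= b - 1 or iy >= b - 1 or ix >= b - 1:
                out[c, f] = 0.0
                continue
            fz = gz - iz
            fy = gy - iy
            fx = gx - ix
            v000 = fvol[iz, iy, ix]
            v001 = fvol[iz, iy, ix + 1]
            v010 = fvol[iz, iy + 1, ix]
            v011 = fvol[iz, iy + 1, ix + 1]
            v100 = fvol[iz + 1, iy, ix]
            v101 = fvol[iz + 1, iy, ix + 1]
            v110 = fvol[iz + 1, iy + 1, ix]
            v111 = fvol[iz + 1, iy + 1, ix + 1]
            w00 = v000 * (1.0 - fx) + v001 * fx
            w01 = v010 * (1.0 - fx) + v011 * fx
            w10 = v100 * (1.0 - fx) + v101 * fx
            w11 = v110 * (1.0 - fx) + v111 * fx
            w0 = w00 * (1.0 - fy) + w01 * fy
            w1 = w10 * (1.0 - fy) + w11 * fy
            out[c, f] = w0 * (1.0 - fz) + w1 * fz


@numba.njit(fastmath=True)
def scatter_slices(num, den, coords, vals, wts):
    """Spread one slice's Fourier samples into the 3D accumulation grids.

    num    : (B, B, B) complex128 accumulated data
    den    : (B, B, B) float64 accumulated interpolation weight
    coords : (Nf, 3) float32 fractional [z, y, x] sample coordinates
    vals   : (Nf,) complex128 sample values (already CTF-multiplied if used)
    wts    : (Nf,) float64 sample weights (CTF^2 or 1)
    """
    b = num.shape[0]
    nf = coords.shape[0]
    for f in range(nf):
        gz = coords[f, 0]
        gy = coords[f, 1]
        gx = coords[f, 2]
        iz = int(np.floor(gz))
        iy = int(np.floor(gy))
        ix = int(np.floor(gx))
        if iz < 0 or iy < 0 or ix < 0 or iz >= b - 1 or iy >= b - 1 or ix >= b - 1:
            continue
        fz = gz - iz
        fy = gy - iy
        fx = gx - ix
        v = vals[f]
        w = wts[f]
        for dz in range(2):
            wz = fz if dz else 1.0 - fz
            for dy in range(2):
                wy = fy if dy else 1.0 - fy
                for dx in range(2):
                    wx = fx if dx else 1.0 - fx
                    ww = wz * wy * wx
                    num[iz + dz, iy + dy, ix + dx] += v * ww
                    den[iz + dz, iy + dy, ix + dx] += w * ww
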