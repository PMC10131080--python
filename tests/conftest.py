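"""Shared fixtures: small phantoms and stacks sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from scorevar.geometry import CTFParams, Pose, Volume
from scorevar.simulate import BlobSpec, Scenario


def make_blob_volume(box: int = 32, voxel: float = 2.0) -> Volume:
    """Asymmetric multi-blob phantom used across geometry tests."""
    c = box // 2
    z, y, x = np.mgrid[0:box, 0:box, 0:box].astype(np.float64)

    def gauss(cx, cy, cz, s):
        return np.exp(-((x - c - cx) ** 2 + (y - c - cy) ** 2
                        + (z - c - cz) ** 2) / (2 * s * s))

    # keep all support well inside the inscribed sphere so rotations and
    # modest shifts conserve intensity
    grid = (gauss(0, 0, 0, 3.0) + 0.8 * gauss(4, 2, -2, 2.0)
            + 0.9 * gauss(-3, 3, 2, 2.2) + 0.7 * gauss(2, -4, 3, 1.8))
    return Volume(grid, voxel)


def make_sphere_volume(box: int = 32, voxel: float = 2.0, sigma: float = 3.5) -> Volume:
    c = box // 2
    z, y, x = np.mgrid[0:box, 0:box, 0:box].astype(np.float64)
    r2 = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2
    return Volume(np.exp(-r2 / (2 * sigma * sigma)), voxel)


def random_poses(n: int, rng: np.random.Generator, shift: float = 0.0) -> list[Pose]:
    """Poses uniform over the sphere, optionally with integer shifts."""
    out = []
    for _ in range(n):
        sx = sy = 0.0
        if shift > 0:
            sx, sy = np.clip(np.round(rng.normal(0, shift, 2)), -4, 4)
        out.append(Pose(rng.uniform(0, 360),
                        np.degrees(np.arccos(rng.uniform(-1, 1))),
                        rng.uniform(0, 360), sx, sy))
    return out


def small_scenario(k: int = 1, n: int = 60, snr: float = float("inf"),
                   seed: int = 11, **kw) -> Scenario:
    """Compact two-lobe scenario in a 32-box for fast end-to-end tests."""
    # irregular C1 cluster: distinct amplitudes, radii and heights make the
    # orientation well determined even in a small box
    core = [BlobSpec((5, 0, -3), 2.8, 1.3), BlobSpec((-3, 4, -2), 2.6, 0.9),
            BlobSpec((-2, -4, 1), 2.4, 0.7), BlobSpec((0, 1, 3), 2.8, 1.1),
            BlobSpec((4, 4, 3), 2.0, 0.8)]
    extra = [BlobSpec((6, 5, 3), 2.2, 1.0), BlobSpec((-6, -5, 2), 2.2, 1.0),
             BlobSpec((0, 7, -4), 2.2, 1.0)]
    if k > 1:
        confs = [core] + [core + [e] for e in extra[:k - 1]]
    else:
        confs = [core]
    props = tuple(np.full(k, 1.0 / k))
    kw.setdefault("snr_spread", 0.0)
    return Scenario(name=f"TEST{k}", conformations=confs, proportions=props,
                    n_particles=n, snr=snr, box=32, voxel_size=3.0,
                    shift_sigma=kw.pop("shift_sigma", 1.0), seed=seed, **kw)


@pytest.fixture(scope="session")
def blob_volume() -> Volume:
    return make_blob_volume()


@pytest.fixture(scope="session")
def sphere_volume() -> Volume:
    return make_sphere_volume()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ctf_typical() -> CTFParams:
    return CTFParams(defocus=15000.0, voltage=300.0,
                     spherical_aberration=2.7, amplitude_contrast=0.07)
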