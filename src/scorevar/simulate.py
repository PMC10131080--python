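"""Ground-truth heterogeneous particle simulator.

Each scenario is a discrete mixture of Gaussian-blob phantoms sharing a
common core and differing by localized density — the kinds of discrete
heterogeneity seen in practice: extra bound domains (antibody arms), a small
peripheral lobe, ring stoichiometry (8-mer vs 9-mer), and a rotor stalk at
three azimuths. Particles are rendered with uniform random orientations,
Gaussian in-plane shift errors, a per-particle CTF drawn from a defocus
range, and additive white Gaussian noise calibrated to a requested
signal-to-noise power ratio inside the particle mask.

The built-in scenarios are frozen (geometry, mixing proportions, box, SNR
and seed) so that end-to-end class-number recovery is reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CTFParams, Pose, Volume, apply_ctf, project
from .io import ParticleStack, ParticleTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlobSpec:
    """Isotropic 3D Gaussian blob: center (x, y, z) voxels from box center."""

    center: tuple[float, float, float]
    sigma: float
    amplitude: float = 1.0

    def fits(self, box: int) -> bool:
        return float(np.linalg.norm(self.center)) + 3.0 * self.sigma < box / 2


@dataclass
class Scenario:
    """A frozen description of one simulated heterogeneous dataset."""

    name: str
    conformations: list[list[BlobSpec]]
    proportions: tuple[float, ...]
    n_particles: int = 3000
    snr: float = 0.1
    snr_spread: float = 0.6       # sigma of per-particle lognormal SNR
    defocus_range: tuple[float, float] = (8000.0, 20000.0)
    shift_sigma: float = 2.0
    box: int = 48
    voxel_size: float = 3.0
    seed: int = 0
    voltage: float = 300.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.07

    def __post_init__(self) -> None:
        if len(self.conformations) < 1:
            raise ValueError("need at least one conformation")
        if len(self.proportions) != len(self.conformations):
            raise ValueError("one mixing proportion per conformation")
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be positive and sum to 1")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (may be inf)")

    @property
    def k_true(self) -> int:
        return len(self.conformations)

    def phantoms(self) -> list[Volume]:
        return [build_phantom(blobs, self.box, self.voxel_size)
                for blobs in self.conformations]

    def mean_phantom(self) -> Volume:
        vols = self.phantoms()
        grid = sum(p * v.grid for p, v in zip(self.proportions, vols))
        return Volume(grid, self.voxel_size)


def build_phantom(blobs: list[BlobSpec], box: int, voxel_size: float) -> Volume:
    """Sum of isotropic 3D Gaussians on a cubic grid. Deterministic."""
    for b in blobs:
        if not b.fits(box):
            raise ValueError(
                f"blob at {b.center} with sigma {b.sigma} exceeds the box "
                f"(need |center| + 3 sigma < {box / 2})")
    c = box // 2
    z, y, x = np.mgrid[0:box, 0:box, 0:box].astype(np.float64)
    grid = np.zeros((box, box, box))
    for b in blobs:
        cx, cy, cz = b.center
        r2 = (x - c - cx) ** 2 + (y - c - cy) ** 2 + (z - c - cz) ** 2
        grid += b.amplitude * np.exp(-r2 / (2.0 * b.sigma**2))
    return Volume(grid, voxel_size)


def simulate_stack(scenario: Scenario) -> tuple[ParticleStack, ParticleTable]:
    """Render a heterogeneous particle stack with ground-truth metadata.

    Per particle: class drawn from the mixing proportions; rot and psi
    uniform on [0, 360), tilt sin-weighted on [0, 180] (uniform over the
    sphere); shifts from a centered Gaussian; defocus uniform in range.
    Images are CTF-modulated noise-free projections plus white Gaussian
    noise whose variance is the masked signal power divided by the
    particle's SNR.

    Per-particle SNR values are lognormal with stack mean equal to the
    scenario ``snr`` and log-sigma ``snr_spread``, emulating the broad
    quality variation of real particle stacks (ice thickness, radiation
    damage, picking quality). This quality spread is what per-particle
    quality-of-fit scores measure; without it every particle is equally
    good and score distributions carry no structure.
    Bit-reproducible from the scenario seed.
    """
    sc = scenario
    if sc.n_particles < 10 * sc.k_true:
        logger.warning("only %d particles for %d classes; classes will be thin",
                       sc.n_particles, sc.k_true)
    rng = np.random.default_rng(sc.seed)
    n = sc.n_particles
    labels = rng.choice(sc.k_true, size=n, p=np.asarray(sc.proportions)) + 1
    rot = rng.uniform(0.0, 360.0, n)
    tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    psi = rng.uniform(0.0, 360.0, n)
    shifts = rng.normal(0.0, sc.shift_sigma, (n, 2)) if sc.shift_sigma > 0 \
        else np.zeros((n, 2))
    defocus = rng.uniform(*sc.defocus_range, n)
    if math.isfinite(sc.snr) and sc.snr_spread > 0:
        # lognormal with E[snr_i] = snr
        mu = math.log(sc.snr) - 0.5 * sc.snr_spread**2
        snr_i = rng.lognormal(mu, sc.snr_spread, n)
    else:
        snr_i = np.full(n, sc.snr)

    phantoms = sc.phantoms()
    c = sc.box // 2
    yy, xx = np.mgrid[0:sc.box, 0:sc.box]
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= (0.45 * sc.box) ** 2

    projs = np.empty((n, sc.box, sc.box), dtype=np.float64)
    for i in range(n):
        pose = Pose(rot[i], tilt[i], psi[i], shifts[i, 0], shifts[i, 1])
        projs[i] = project(phantoms[labels[i] - 1], pose).grid
    # CTF modulation, batched over particles (identical to apply_ctf per image)
    from .geometry import ctf_grid
    images = np.empty((n, sc.box, sc.box), dtype=np.float64)
    chunk = 256
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        h = np.stack([ctf_grid(sc.box, sc.voxel_size,
                               CTFParams(defocus[i], sc.voltage,
                                         sc.spherical_aberration,
                                         sc.amplitude_contrast), rfft=True)
                      for i in range(lo, hi)])
        images[lo:hi] = np.fft.irfft2(np.fft.rfft2(projs[lo:hi]) * h,
                                      s=(sc.box, sc.box))
    if math.isfinite(sc.snr):
        for i in range(n):
            power = float(np.mean(images[i][mask] ** 2))
            images[i] = images[i] + rng.normal(
                0.0, math.sqrt(power / snr_i[i]), (sc.box, sc.box))

    table = ParticleTable(pd.DataFrame({
        "particle_id": np.arange(n),
        "image_index": np.arange(n),
        "rot": rot, "tilt": tilt, "psi": psi,
        "shift_x": shifts[:, 0], "shift_y": shifts[:, 1],
        "defocus": defocus,
        "true_class": labels.astype(np.int64),
        "true_snr": snr_i,
    }))
    return ParticleStack(images, sc.voxel_size), table


def ctf_params_from_table(table: ParticleTable, scenario: Scenario | None = None,
                          voltage: float = 300.0, cs: float = 2.7,
                          ac: float = 0.07) -> list[CTFParams]:
    """Per-particle CTF parameter objects from a table's defocus column."""
    if scenario is not None:
        voltage = scenario.voltage
        cs = scenario.spherical_aberration
        ac = scenario.amplitude_contrast
    return [CTFParams(d, voltage, cs, ac) for d in table.df["defocus"]]


# --------------------------------------------------------------------------- #
# Built-in scenarios
# --------------------------------------------------------------------------- #

def _ring(n: int, radius: float, sigma: float, amplitude: float = 1.0,
          z: float = 0.0, phase_deg: float = 0.0,
          amp_ramp: float = 0.0, z_ramp: float = 0.0) -> list[BlobSpec]:
    """Ring of blobs with optional monotone amplitude and height ramps.

    Real protomers are never perfectly equivalent; the ramps make the ring
    genuinely asymmetric (no rotation or flip maps it onto itself), which is
    what lets a consensus alignment lock a single orientation basin — the
    role ordered side features play for real complexes.
    """
    out = []
    for k in range(n):
        a = math.radians(phase_deg + 360.0 * k / n)
        frac = k / (n - 1) if n > 1 else 0.0
        amp = amplitude * (1.0 + amp_ramp * (frac - 0.5))
        zz = z + z_ramp * (frac - 0.5)
        out.append(BlobSpec((radius * math.cos(a), radius * math.sin(a), zz),
                            sigma, amp))
    return out


def _decorate(blobs: list[BlobSpec], seed: int) -> list[BlobSpec]:
    """Add fine-structure satellite blobs around each lobe.

    Real macromolecules have detail at every scale; pure large Gaussians do
    not. The satellites (sigma ~1.5 voxels) put genuine signal into the
    higher-resolution shells, so reconstruction quality — and therefore the
    quality-of-fit score — becomes resolution-limited the way real maps
    are: classes with fewer or worse particles lose their fine shells
    first. Deterministic for a given seed; the satellites are part of the
    frozen scenario geometry.
    """
    rng = np.random.default_rng(seed)
    out = list(blobs)
    for b in blobs:
        if b.sigma < 2.5:
            continue
        for _ in range(3):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            r = 0.9 * b.sigma
            c = (b.center[0] + r * d[0], b.center[1] + r * d[1],
                 b.center[2] + r * d[2])
            sat = BlobSpec(c, 1.5, 0.55 * b.amplitude)
            if sat.fits(48):
                out.append(sat)
    return out


def _cluster_core() -> list[BlobSpec]:
    # irregular C1 cluster of distinct lobes at distinct radii and heights;
    # nearly all signal power carries orientation information, which is what
    # makes per-particle alignment feasible at low SNR in a small box
    return [BlobSpec((9, 0, -4), 4.0, 1.2), BlobSpec((-5, 8, -4), 4.0, 0.9),
            BlobSpec((-5, -8, -4), 4.0, 0.7), BlobSpec((0, 2, 4), 4.5, 1.1),
            BlobSpec((6, 6, 5), 3.0, 0.8), BlobSpec((-8, 1, 6), 3.0, 0.6)]


# off-ring "tag" lobe shared by both ring stoichiometries (breaks the
# residual ring pseudo-symmetry the way an asymmetric subunit would)
_FLAG = BlobSpec((3.0, 2.0, 8.0), 3.5, 1.0)


def _env3() -> Scenario:
    # trimer-like core (amplitude-graded, so the monomers are inequivalent);
    # two prominent "antibody arm" additions define the classes
    core = _decorate(_cluster_core(), seed=421)
    arm_a = _decorate([BlobSpec((13.0, -2.0, 2.0), 3.5, 1.4)], seed=422)
    arm_b = _decorate([BlobSpec((-6.0, -10.0, 3.0), 3.5, 1.4)], seed=423)
    return Scenario(
        name="ENV3",
        conformations=[core + arm_a, core + arm_b, core + arm_a + arm_b],
        proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=1107,
    )


def _trpv2() -> Scenario:
    # four-fold channel-like ring (graded protomers) topped by an off-axis
    # domain; the classes differ only by one small peripheral lobe
    core = _decorate(_ring(4, 9.0, 4.5, 1.0, amp_ramp=0.7, z_ramp=4.0)
                     + [BlobSpec((3.0, -2.0, 7.0), 3.5, 0.9)], seed=431)
    lobe = _decorate([BlobSpec((9.5, 9.5, 4.0), 3.0, 1.0)], seed=432)
    return Scenario(
        name="TRPV2",
        conformations=[core + lobe, core],
        proportions=(0.66, 0.34),
        seed=1209,
    )


def _ring89() -> Scenario:
    # 8-mer vs 9-mer rings of equal radius (mildly graded protomers)
    return Scenario(
        name="RING89",
        conformations=[
            _decorate(_ring(8, 10.5, 3.0, amp_ramp=0.7, z_ramp=5.0) + [_FLAG],
                      seed=441),
            _decorate(_ring(9, 12.5, 3.0, amp_ramp=0.7, z_ramp=5.0) + [_FLAG],
                      seed=442)],
        proportions=(0.5, 0.5),
        seed=1303,
    )


def _rotor3() -> Scenario:
    # stator core with a fixed peripheral stalk (breaks the 3-fold, as the
    # real peripheral stalk does) plus a rotor blob at one of three azimuths
    core = ([BlobSpec((2.0, -2.0, 6.0), 4.0, 1.1)]
            + _ring(3, 7.0, 4.0, 1.0, z=-5.0, phase_deg=60.0, amp_ramp=0.8)
            + [BlobSpec((0.0, 13.0, 0.0), 3.5, 1.4)])  # peripheral stalk
    rotors = [_decorate([BlobSpec((11.0 * math.cos(math.radians(a)),
                                   11.0 * math.sin(math.radians(a)), 2.0),
                                  3.5, 1.2)], seed=451 + i)
              for i, a in enumerate((0.0, 120.0, 240.0))]
    core = _decorate(core, seed=450)
    return Scenario(
        name="ROTOR3",
        conformations=[core + r for r in rotors],
        proportions=(0.54, 0.34, 0.12),
        seed=1401,
    )


def _homo1() -> Scenario:
    core = _decorate(_cluster_core(), seed=421)
    return Scenario(name="HOMO1", conformations=[core], proportions=(1.0,),
                    seed=1005)


_BUILTINS = {"ENV3": _env3, "TRPV2": _trpv2, "RING89": _ring89,
             "ROTOR3": _rotor3, "HOMO1": _homo1}

BUILTIN_NAMES = tuple(sorted(_BUILTINS))


def builtin_scenario(name: str, **overrides) -> Scenario:
    """Return a frozen built-in scenario by name (ENV3, TRPV2, RING89,
    ROTOR3, HOMO1), optionally overriding non-structural fields."""
    key = name.upper()
    if key not in _BUILTINS:
        raise ValueError(f"unknown scenario {name!r}; valid names: "
                         f"{', '.join(BUILTIN_NAMES)}")
    sc = _BUILTINS[key]()
    return replace(sc, **overrides) if overrides else sc
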