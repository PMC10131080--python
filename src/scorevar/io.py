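"""File formats and on-disk run layout.

Maps and particle stacks are MRC2014 (32-bit float, mode 2) with the voxel
size recorded in the header. Particle metadata travels as a single-loop STAR
block using the common single-particle tag names, with a TSV mirror written
alongside for spreadsheet users. Configs, per-class statistics and selection
reports are YAML.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Volume


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# --------------------------------------------------------------------------- #
# MRC2014
# --------------------------------------------------------------------------- #

_MRC_HEADER_SIZE = 1024


def _mrc_header(nx: int, ny: int, nz: int, voxel: float, is_volume: bool,
                data: np.ndarray) -> bytes:
    mz = nz if is_volume else 1
    h = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<3i", h, 0, nx, ny, nz)
    struct.pack_into("<i", h, 12, 2)  # mode 2: float32
    struct.pack_into("<3i", h, 28, nx, ny, mz)  # mx, my, mz
    struct.pack_into("<3f", h, 40, nx * voxel, ny * voxel, mz * voxel)  # cella
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", h, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", h, 88, 1 if is_volume else 0)  # ispg
    h[208:212] = b"MAP "
    h[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))
    return bytes(h)


def write_mrc(path, data: np.ndarray, voxel_size: float, is_volume: bool) -> None:
    """Write a float32 MRC2014 file (mode 2). ``data`` is [z, y, x]-ordered
    (sections, rows, columns); for stacks, z indexes the images."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    nz, ny, nx = data.shape
    with open(path, "wb") as fh:
        fh.write(_mrc_header(nx, ny, nz, voxel_size, is_volume, data))
        fh.write(np.ascontiguousarray(data, dtype="<f4").tobytes())


def read_mrc(path) -> tuple[np.ndarray, float, bool]:
    """Read an MRC2014 mode-2 file; returns (data [z,y,x], voxel_size, is_volume)."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise FormatError(f"{path}: truncated header "
                          f"({len(raw)} < {_MRC_HEADER_SIZE} bytes)")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode, = struct.unpack_from("<i", raw, 12)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: bad MAP magic in header word 53")
    if mode != 2:
        raise FormatError(f"{path}: unsupported mode {mode} (need mode 2, float32)")
    if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 1 << 16:
        raise FormatError(f"{path}: implausible dimensions nx={nx} ny={ny} nz={nz}")
    nsymbt, = struct.unpack_from("<i", raw, 92)
    mz, = struct.unpack_from("<i", raw, 36)
    cellz, = struct.unpack_from("<f", raw, 48)
    cellx, = struct.unpack_from("<f", raw, 40)
    voxel = cellx / nx if nx else 1.0
    ispg, = struct.unpack_from("<i", raw, 88)
    start = _MRC_HEADER_SIZE + nsymbt
    need = start + nx * ny * nz * 4
    if len(raw) < need:
        raise FormatError(f"{path}: truncated data section "
                          f"({len(raw)} < {need} bytes)")
    data = np.frombuffer(raw[start:need], dtype="<f4").reshape(nz, ny, nx)
    return data.copy(), float(voxel), ispg != 0


def write_volume(path, volume: Volume) -> None:
    write_mrc(path, volume.grid, volume.voxel_size, is_volume=True)


def read_volume(path) -> Volume:
    data, voxel, _ = read_mrc(path)
    return Volume(data, voxel)


# --------------------------------------------------------------------------- #
# Particle stack and table
# --------------------------------------------------------------------------- #


@dataclass
class ParticleStack:
    """A stack of square particle images with a shared pixel size."""

    images: np.ndarray  # (N, B, B) float32
    pixel_size: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError(f"stack must be (N, B, B), got {self.images.shape}")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def box(self) -> int:
        return self.images.shape[1]


def write_stack(path, stack: ParticleStack) -> None:
    write_mrc(path, stack.images, stack.pixel_size, is_volume=False)


def read_stack(path) -> ParticleStack:
    data, voxel, _ = read_mrc(path)
    return ParticleStack(data, voxel)


# STAR tag <-> column mapping (common single-particle naming)
_STAR_TAGS = {
    "particle_id": "_rlnImageId",
    "image_index": "_rlnImageName",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "shift_x": "_rlnOriginX",
    "shift_y": "_rlnOriginY",
    "defocus": "_rlnDefocusU",
    "class_id": "_rlnClassNumber",
    "score": "_rlnParticleScore",
    "true_class": "_rlnGroupNumber",
}
_TAG_COLS = {v: k for k, v in _STAR_TAGS.items()}

POSE_COLUMNS = ("rot", "tilt", "psi", "shift_x", "shift_y")
REQUIRED_COLUMNS = ("particle_id", "image_index") + POSE_COLUMNS + ("defocus",)
_INT_COLUMNS = ("particle_id", "image_index", "class_id", "true_class")


@dataclass
class ParticleTable:
    """Per-particle metadata records backing one stack.

    Required columns: particle_id, image_index, rot, tilt, psi, shift_x,
    shift_y, defocus. Optional: score, class_id, true_class and any
    run-specific score columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"particle table missing required column(s): "
                              f"{', '.join(missing)}")
        if self.df["particle_id"].duplicated().any():
            raise ValueError("particle ids must be unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def filter(self, keep) -> "ParticleTable":
        """Row subset preserving order and ids."""
        return ParticleTable(self.df.loc[np.asarray(keep)].copy())

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    @property
    def euler(self) -> np.ndarray:
        return self.df[["rot", "tilt", "psi"]].to_numpy(float)

    @property
    def shifts(self) -> np.ndarray:
        return self.df[["shift_x", "shift_y"]].to_numpy(float)


def write_table(path, table: ParticleTable, dialect: str = "star") -> None:
    """Write a particle table as a single-loop STAR block or as TSV."""
    df = table.df
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect != "star":
        raise ValueError(f"unknown dialect {dialect!r} (use 'star' or 'tsv')")
    lines = ["data_particles", "", "loop_"]
    tags = [_STAR_TAGS.get(c, f"_sv{c}") for c in df.columns]
    lines += [f"{t} #{i + 1}" for i, t in enumerate(tags)]
    body = df.to_csv(sep=" ", index=False, header=False,
                     float_format="%.6f").splitlines()
    lines += body + [""]
    path.write_text("\n".join(lines))


def read_table(path, dialect: str | None = None, strict: bool = False) -> ParticleTable:
    """Read a particle table (STAR single-loop or TSV).

    Unknown STAR tags are preserved as opaque columns in lenient mode and
    rejected in strict mode.
    """
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix == ".star" else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "star":
        tags: list[str] = []
        rows: list[list[str]] = []
        in_loop = False
        for line in path.read_text().splitlines():
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("data_"):
                continue
            if s == "loop_":
                in_loop = True
                continue
            if s.startswith("_"):
                if not in_loop:
                    raise FormatError(f"{path}: tag outside a loop block: {s}")
                tags.append(s.split()[0])
                continue
            if in_loop:
                rows.append(s.split())
        if not tags:
            raise FormatError(f"{path}: no STAR loop block found")
        cols = []
        for t in tags:
            if t in _TAG_COLS:
                cols.append(_TAG_COLS[t])
            elif t.startswith("_sv"):
                cols.append(t[3:])
            elif strict:
                raise FormatError(f"{path}: unknown STAR tag {t} (strict mode)")
            else:
                cols.append(t)
        df = pd.DataFrame(rows, columns=cols)
        for c in df.columns:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                pass
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for c in _INT_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    return ParticleTable(df)


# --------------------------------------------------------------------------- #
# Run configuration and reports
# --------------------------------------------------------------------------- #


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    scenario: str | None = None
    stack_path: str | None = None
    table_path: str | None = None
    reference_path: str | None = None
    k_min: int = 1
    k_max: int = 6
    seed: int = 0
    angular_step: float = 15.0
    max_shift: float = 4.0
    angle_window: float = 10.0
    shift_window: float = 3.0
    global_iterations: int = 4
    local_iterations: int = 4
    classify_iterations: int = 8
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
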