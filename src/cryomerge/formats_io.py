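"""MRC volume/stack and STAR metadata I/O.

Containers
----------
:class:`DensityMap`
    A 3D voxel grid with a physical pixel size (Å/px) and an origin (Å).
    The array is indexed ``(z, y, x)``; the physical coordinate of voxel
    ``(iz, iy, ix)`` is ``origin + index * apix`` per axis.
:class:`ImageStack`
    A stack of 2D images (micrographs, movie frames or particle images),
    indexed ``(n, y, x)`` with one shared in-plane pixel size.
:class:`StarTable`
    One ``data_``/``loop_`` block of a RELION-dialect STAR file, backed by a
    :class:`pandas.DataFrame` with the column (tag) order preserved.

MRC files are read and written through :mod:`gemmi` (MRC2014, mode 2 float).
STAR files are parsed with :mod:`gemmi.cif`; writing uses a small emitter so
the loop layout and numeric formatting match RELION conventions (floats at six
decimal places, integers kept integral).

Only the RELION <= 3.0 single-block dialect is supported; optics-group files
(RELION >= 3.1) are rejected with a clear message.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .exceptions import (
    CryomergeError,
    FormatError,
    MergeError,
    StarDialectError,
    StarParseError,
    UnsupportedModeError,
)

__all__ = [
    "DensityMap",
    "ImageStack",
    "StarTable",
    "CtfRecord",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
    "join_star",
]

#: MRC data modes that hold real scalar values (int8, int16, float32, uint16,
#: float16).  Complex modes (3, 4) are rejected.
_REAL_MODES = {0, 1, 2, 6, 12}


@dataclass
class DensityMap:
    """A 3D density map on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values (arbitrary units).  Stored as float32.
    apix : float or None
        Pixel (voxel) size in Å per pixel. ``None`` means "unset" — e.g. a
        header that carried a zero cell — and must be supplied by the caller
        before the map can be written or rescaled.
    origin : ndarray, shape (3,)
        Physical position (Å) of voxel ``(0, 0, 0)``, in ``(z, y, x)`` order.
    """

    data: np.ndarray
    apix: float | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("DensityMap data must be 3-dimensional")
        if any(n < 2 for n in self.data.shape):
            raise ValueError("DensityMap box lengths must be >= 2")
        if self.apix is not None:
            self.apix = float(self.apix)
            if not np.isfinite(self.apix) or self.apix <= 0:
                raise ValueError(f"apix must be finite and > 0, got {self.apix}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def box(self) -> tuple[int, int, int]:
        """Edge lengths in pixels, ``(nz, ny, nx)``."""
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        return len(set(self.data.shape)) == 1

    def require_apix(self) -> float:
        if self.apix is None:
            raise CryomergeError(
                "pixel size is unset (header carried none); supply apix explicitly"
            )
        return self.apix

    def center_physical(self) -> np.ndarray:
        """Physical coordinate (Å) of the center voxel ``box // 2`` per axis."""
        apix = self.require_apix()
        return self.origin + np.array([n // 2 for n in self.box]) * apix

    def with_apix(self, new_apix: float) -> "DensityMap":
        """Re-declare the pixel size, keeping the center voxel in place.

        The grid values are untouched; only the physical interpretation
        changes.  The origin is moved so the center voxel ``box // 2`` stays at
        the same physical coordinate — the natural convention for comparing
        reconstructions of a centered particle at candidate pixel sizes.
        """
        new_apix = float(new_apix)
        if new_apix <= 0:
            raise ValueError("apix must be > 0")
        if self.apix is None:
            new_origin = -np.array([n // 2 for n in self.box]) * new_apix
        else:
            center = self.center_physical()
            new_origin = center - np.array([n // 2 for n in self.box]) * new_apix
        return DensityMap(self.data.copy(), new_apix, new_origin)


@dataclass
class ImageStack:
    """A stack of 2D real-valued images sharing one pixel size.

    ``data`` is indexed ``(n, y, x)``; ``is_movie`` distinguishes movie frames
    (one exposure, many frames) from independent images such as extracted
    particles or micrographs.
    """

    data: np.ndarray
    apix: float | None = None
    is_movie: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (N, Y, X)")
        n, y, x = self.data.shape
        if n < 1 or y < 2 or x < 2:
            raise ValueError("ImageStack needs N >= 1 and Y, X >= 2")
        if self.apix is not None:
            self.apix = float(self.apix)
            if not np.isfinite(self.apix) or self.apix <= 0:
                raise ValueError(f"apix must be finite and > 0, got {self.apix}")

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    def require_apix(self) -> float:
        if self.apix is None:
            raise CryomergeError(
                "pixel size is unset (header carried none); supply apix explicitly"
            )
        return self.apix


class StarTable:
    """One ``data_`` block of a STAR file: ordered named columns plus rows.

    Thin wrapper around a :class:`pandas.DataFrame` that preserves the tag
    order and the block label.  Numeric columns are stored as int64/float64;
    everything else stays as strings.
    """

    def __init__(self, df: pd.DataFrame, name: str = "") -> None:
        self.df = df.reset_index(drop=True)
        self.name = name

    @classmethod
    def from_columns(cls, columns: dict[str, Sequence], name: str = "") -> "StarTable":
        return cls(pd.DataFrame(dict(columns)), name=name)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, tag: str) -> pd.Series:
        return self.df[tag]

    def copy(self) -> "StarTable":
        return StarTable(self.df.copy(), self.name)

    def implied_apix(self) -> float | None:
        """Pixel size (Å) implied by magnification and detector pixel size.

        RELION <= 3.0 stores the scale as ``_rlnDetectorPixelSize`` (µm) and
        ``_rlnMagnification``; the implied pixel size is
        ``detector_pixel * 1e4 / magnification`` Å.  Returns ``None`` when the
        columns are absent, and raises :class:`MergeError` when rows disagree.
        """
        if "_rlnMagnification" not in self.df or "_rlnDetectorPixelSize" not in self.df:
            return None
        mag = pd.to_numeric(self.df["_rlnMagnification"])
        dpx = pd.to_numeric(self.df["_rlnDetectorPixelSize"])
        apix = dpx * 1.0e4 / mag
        if len(apix) == 0:
            return None
        if float(apix.max() - apix.min()) > 1e-6:
            raise MergeError(
                "table implies more than one pixel size "
                f"({apix.min():.6f}..{apix.max():.6f} Å)"
            )
        return float(apix.iloc[0])

    def __eq__(self, other) -> bool:  # mostly for tests
        if not isinstance(other, StarTable):
            return NotImplemented
        return self.columns == other.columns and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"StarTable(name={self.name!r}, rows={len(self)}, columns={self.columns})"


@dataclass
class CtfRecord:
    """Per-micrograph CTF metadata, units as stored internally.

    Defocus in Å, astigmatism angle in degrees, voltage in kV, spherical
    aberration in Å (1 mm = 1e7 Å; RELION STAR files store mm), amplitude
    contrast as a fraction, detector pixel in µm.
    """

    micrograph_name: str
    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7e7
    amplitude_contrast: float = 0.1
    magnification: float = 10000.0
    detector_pixel: float = 1.0

    MM_TO_A = 1.0e7

    @property
    def implied_apix(self) -> float:
        """Pixel size in Å: detector pixel (µm) × 1e4 / magnification."""
        return self.detector_pixel * 1.0e4 / self.magnification

    @property
    def cs_mm(self) -> float:
        return self.cs / self.MM_TO_A

    @classmethod
    def from_star_row(cls, row: dict) -> "CtfRecord":
        return cls(
            micrograph_name=str(row.get("_rlnMicrographName", "")),
            defocus_u=float(row["_rlnDefocusU"]),
            defocus_v=float(row["_rlnDefocusV"]),
            astig_angle=float(row.get("_rlnDefocusAngle", 0.0)),
            voltage=float(row.get("_rlnVoltage", 300.0)),
            cs=float(row.get("_rlnSphericalAberration", 2.7)) * cls.MM_TO_A,
            amplitude_contrast=float(row.get("_rlnAmplitudeContrast", 0.1)),
            magnification=float(row.get("_rlnMagnification", 10000.0)),
            detector_pixel=float(row.get("_rlnDetectorPixelSize", 1.0)),
        )


# ---------------------------------------------------------------------------
# MRC


def read_mrc(path: str | os.PathLike, apix: float | None = None) -> DensityMap | ImageStack:
    """Read an MRC2014 file as a :class:`DensityMap` or :class:`ImageStack`.

    Volumes (``ISPG >= 1``) load as :class:`DensityMap`; image stacks
    (``ISPG == 0``) as :class:`ImageStack`.  The pixel size is taken from the
    header cell/grid fields; an exactly zero cell loads as *unset* (``None``)
    and is never silently used.  ``apix`` overrides the header value.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC file {path}: {exc}") from None
    mode = m.header_i32(4)
    if mode not in _REAL_MODES:
        raise UnsupportedModeError(
            f"{path}: MRC mode {mode} is not a supported real-valued mode"
        )
    if m.axis_positions() != [0, 1, 2]:
        m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    # gemmi's grid array is indexed (x, y, z); we use (z, y, x)
    data = np.asarray(m.grid, dtype=np.float32).transpose(2, 1, 0).copy()
    header_apix = None
    cell_x = m.grid.unit_cell.a
    mx = m.header_i32(8)  # word 8 = MX
    if cell_x > 0 and mx > 0:
        header_apix = cell_x / mx
    if apix is None:
        apix = header_apix
    origin = np.array(
        [m.header_float(52), m.header_float(51), m.header_float(50)], dtype=float
    )
    ispg = m.header_i32(23)
    if ispg == 0:
        return ImageStack(data, apix=apix)
    return DensityMap(data, apix=apix, origin=origin)


def write_mrc(obj: DensityMap | ImageStack, path: str | os.PathLike) -> None:
    """Write a map or stack as MRC2014 mode 2 (32-bit float).

    The header cell is ``box * apix`` per axis so any downstream tool reads
    back the same pixel size; volumes carry their origin in the MRC ORIGIN
    fields, stacks are written with ``ISPG = 0``.
    """
    apix = obj.require_apix()
    data = obj.data
    m = gemmi.Ccp4Map()
    nz, ny, nx = data.shape
    m.grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(m.grid)[...] = data.transpose(2, 1, 0)
    m.grid.unit_cell = gemmi.UnitCell(nx * apix, ny * apix, nz * apix, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    m.update_ccp4_header()
    if isinstance(obj, ImageStack):
        m.set_header_i32(23, 0)  # ISPG 0 marks an image/stack
    else:
        ox, oy, oz = obj.origin[2], obj.origin[1], obj.origin[0]
        m.set_header_float(50, ox)
        m.set_header_float(51, oy)
        m.set_header_float(52, oz)
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# STAR


def _coerce_numeric(series: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(series)
    except (ValueError, TypeError):
        return series


def read_star(path: str | os.PathLike) -> list[StarTable]:
    """Parse a RELION-dialect STAR file into a list of :class:`StarTable`.

    All ``data_`` blocks are returned in file order; unknown columns are
    preserved verbatim; ``#`` comment lines are ignored by the parser.
    Optics-group files (RELION >= 3.1) are rejected.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StarParseError(f"cannot parse STAR file {path}: {exc}") from None
    tables: list[StarTable] = []
    for block in doc:
        name = block.name.strip()
        if name in ("optics", "data_optics"):
            raise StarDialectError(
                f"{path}: optics-group STAR files (RELION >= 3.1) are not supported; "
                "convert to the single-block RELION <= 3.0 dialect first"
            )
        loop = None
        for item in block:
            if item.loop is not None:
                loop = item.loop
                break
        if loop is None:
            continue
        tags = list(loop.tags)
        if "_rlnOpticsGroup" in tags:
            raise StarDialectError(
                f"{path}: optics-group STAR files (RELION >= 3.1) are not supported"
            )
        table = block.find(tags)
        rows = [list(row) for row in table]
        df = pd.DataFrame(rows, columns=tags)
        for col in df.columns:
            df[col] = _coerce_numeric(df[col])
        tables.append(StarTable(df, name=name))
    return tables


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.6f}"
    return str(v)


def write_star(tables: StarTable | Iterable[StarTable], path: str | os.PathLike) -> None:
    """Write one or more tables as a RELION-dialect STAR file.

    Floats are written with six decimal places and integer columns stay
    integral, so column-wise text edits remain reproducible.
    """
    if isinstance(tables, StarTable):
        tables = [tables]
    lines: list[str] = []
    for t in tables:
        lines.append(f"data_{t.name}")
        lines.append("")
        lines.append("loop_")
        for i, tag in enumerate(t.columns, start=1):
            lines.append(f"{tag} #{i}")
        for row in t.df.itertuples(index=False):
            lines.append(" ".join(_format_value(v) for v in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def join_star(
    tables: Sequence[StarTable],
    required: Sequence[str] = (),
) -> StarTable:
    """Row-wise concatenation of tables over the intersection of their columns.

    The column order follows the first table; row counts add and no row
    content is altered.  Any tag listed in ``required`` must be present in
    every input, otherwise a :class:`MergeError` names the missing column.
    """
    if len(tables) < 2:
        raise MergeError("join_star needs at least two tables")
    for t in tables:
        for tag in required:
            if tag not in t.columns:
                raise MergeError(f"required column {tag} missing from input table")
    shared = [c for c in tables[0].columns if all(c in t.columns for t in tables[1:])]
    if not shared:
        raise MergeError("input tables share no columns")
    df = pd.concat([t.df[shared] for t in tables], ignore_index=True)
    return StarTable(df, name=tables[0].name)
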