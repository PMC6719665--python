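"""Particle-level merging mechanics: coordinate rescaling, even-box-pair
search, extraction with rescale and background normalization, guarded joins.

The even-box-pair search solves the practical problem of scaling straight to
a desired pixel-size ratio when only even box sizes are allowed: to bring
0.880 Å/px particles into a 1.120 Å/px frame one would ideally extract at
``420 * 1.120 / 0.880 = 534.5`` pixels, which is impossible; the search
instead enumerates even (extract, scaled) pairs whose ratio best matches
``start_apix / target_apix`` — here 560 -> 440 hits the ratio 11/14 exactly.
Both boxes are constrained to the requested range: the scaled box must stay
at least as large as the final crop, otherwise the workflow cannot window
down to the common box size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import CryomergeError, MergeError
from .formats_io import ImageStack, StarTable, join_star
from .grid_rescale import fourier_rescale_to_box

__all__ = [
    "BoxPair",
    "ParticleRescaleSpec",
    "rescale_particle_table",
    "find_box_pairs",
    "ideal_extract_box",
    "background_diameter",
    "extract_particles",
    "merge_datasets",
]

logger = logging.getLogger(__name__)

COORDINATE_COLUMNS = ("_rlnCoordinateX", "_rlnCoordinateY")
ORIGIN_COLUMNS = ("_rlnOriginX", "_rlnOriginY")


@dataclass
class BoxPair:
    """An (extraction box, scaled box) pair and how well it hits the desired ratio."""

    extract_box: int
    scaled_box: int
    desired_ratio: float

    @property
    def achieved_ratio(self) -> float:
        return self.scaled_box / self.extract_box

    @property
    def error_percent(self) -> float:
        return 100.0 * abs(self.achieved_ratio - self.desired_ratio) / self.desired_ratio

    def achieved_apix(self, extract_apix: float) -> float:
        return extract_apix * self.extract_box / self.scaled_box


@dataclass
class ParticleRescaleSpec:
    """Pixel sizes steering a coordinate-table rescale.

    ``pix_nominal`` is the value the original processing assumed,
    ``pix_relative`` the calibrated true value, ``pix_target`` the frame the
    micrographs were rescaled into.  Coordinates follow the micrograph's
    dimensional change, i.e. they scale by ``pix_relative / pix_target``.
    """

    pix_nominal: float
    pix_relative: float
    pix_target: float
    new_micrograph_path: str | None = None

    def __post_init__(self) -> None:
        for v in (self.pix_nominal, self.pix_relative, self.pix_target):
            if v <= 0:
                raise ValueError("pixel sizes must be > 0")

    @property
    def coordinate_factor(self) -> float:
        return self.pix_relative / self.pix_target


def rescale_particle_table(table: StarTable, spec: ParticleRescaleSpec) -> StarTable:
    """Correct picked-particle coordinates after micrograph rescaling.

    ``_rlnCoordinateX/Y`` (and ``_rlnOriginX/Y`` when present) are multiplied
    by ``pix_relative / pix_target``; magnification/detector-pixel columns
    are rewritten so the implied pixel size equals ``pix_target``; the
    micrograph path prefix is replaced when requested.  The output is ready
    for re-import.
    """
    for tag in COORDINATE_COLUMNS:
        if tag not in table.columns:
            raise MergeError(f"coordinate column {tag} missing from table")
    f = spec.coordinate_factor
    out = table.copy()
    for tag in COORDINATE_COLUMNS:
        out.df[tag] = out.df[tag] * f
    for tag in ORIGIN_COLUMNS:
        if tag in out.columns:
            out.df[tag] = out.df[tag] * f
    if "_rlnMagnification" in out.columns:
        out.df["_rlnMagnification"] = 10000.0
    if "_rlnDetectorPixelSize" in out.columns:
        out.df["_rlnDetectorPixelSize"] = float(spec.pix_target)
    if spec.new_micrograph_path is not None and "_rlnMicrographName" in out.columns:
        out.df["_rlnMicrographName"] = [
            spec.new_micrograph_path + str(name).rsplit("/", 1)[-1]
            for name in out.df["_rlnMicrographName"]
        ]
    return out


def ideal_extract_box(final_box: int, final_apix: float, start_apix: float) -> float:
    """Extraction box (possibly fractional) that would scale exactly to
    ``final_box`` at ``final_apix``: ``final_box * final_apix / start_apix``
    (420 px at 1.120 Å/px from 0.880 Å/px data -> 534.5 px)."""
    return final_box * final_apix / start_apix


def find_box_pairs(
    min_box: int,
    max_box: int,
    start_apix: float,
    target_apix: float,
    n_answers: int = 1,
) -> list[BoxPair]:
    """Exhaustive search for even box pairs closest to the desired scale ratio.

    Enumerates every even ``extract_box`` and even ``scaled_box`` in
    ``[min_box, max_box]`` (the scaled box must remain large enough for the
    final crop, hence the shared lower bound) and ranks pairs by percent
    error of ``scaled_box / extract_box`` against
    ``start_apix / target_apix``, ties broken by smaller extraction box.
    """
    if min_box > max_box:
        raise ValueError("min_box must be <= max_box")
    if n_answers < 1:
        raise ValueError("n_answers must be >= 1")
    desired = start_apix / target_apix
    lo = min_box + (min_box % 2)
    hi = max_box - (max_box % 2)
    if lo > hi:
        raise CryomergeError(f"no even box sizes in [{min_box}, {max_box}]")
    evens = range(lo, hi + 1, 2)
    pairs = [
        BoxPair(e, s, desired)
        for e in evens
        for s in evens
    ]
    pairs.sort(key=lambda p: (p.error_percent, p.extract_box, p.scaled_box))
    return pairs[:n_answers]


def background_diameter(
    target_box: int,
    final_apix: float,
    extract_apix: float,
    fraction: float = 0.75,
) -> int:
    """Diameter (px) of the background circle, in extraction-frame pixels.

    The normalization region should correspond to the *final* box: a fraction
    of ``target_box`` mapped back into the extraction frame,
    ``floor(fraction * target_box * final_apix / extract_apix)`` — e.g.
    ``0.75 * 420 * 1.120 / 0.880 -> 400`` px.
    """
    if target_box <= 0 or final_apix <= 0 or extract_apix <= 0 or fraction <= 0:
        raise ValueError("all arguments must be > 0")
    return math.floor(fraction * target_box * final_apix / extract_apix)


def _background_mask(box: int, bg_diameter: int) -> np.ndarray:
    radius = bg_diameter // 2
    ys = np.arange(box)[:, None] - box // 2
    xs = np.arange(box)[None, :] - box // 2
    return np.hypot(ys, xs) > radius


def extract_particles(
    micrograph: ImageStack,
    coords: list[tuple[float, float]],
    extract_box: int,
    scaled_box: int,
    bg_diameter: int,
    invert_contrast: bool = False,
) -> tuple[ImageStack, StarTable]:
    """Window, normalize and (optionally) rescale particles from a micrograph.

    For each ``(x, y)`` coordinate a window of ``extract_box`` pixels is cut
    centered on the nearest pixel (particles whose window would cross the
    micrograph edge are skipped and logged), then Fourier-rescaled to
    ``scaled_box``.  ``bg_diameter`` is specified in extraction-frame pixels
    (where ``0.75 * 420 * 1.120/0.880 -> 400`` holds) but normalization is
    applied to the *rescaled* particle with the correspondingly scaled
    circle: background mean 0, SD 1 outside it, then the optional contrast
    inversion.  Coordinates are kept continuous: the sub-pixel residual of
    each pick is stored in ``_rlnOriginX/Y``.
    """
    if extract_box % 2 or scaled_box % 2:
        raise ValueError("box sizes must be even-numbered")
    if bg_diameter > extract_box:
        raise ValueError("background diameter exceeds the extraction box")
    apix = micrograph.require_apix()
    img = micrograph.data[0]
    ny, nx = img.shape
    half = extract_box // 2
    scaled_diameter = int(bg_diameter * scaled_box / extract_box)
    mask = _background_mask(scaled_box, scaled_diameter)
    if not mask.any():
        raise CryomergeError("background region is empty; reduce bg_diameter")
    boxes, kept_rows, n_skipped = [], [], 0
    for x, y in coords:
        cx, cy = int(round(x)), int(round(y))
        x0, y0 = cx - half, cy - half
        if x0 < 0 or y0 < 0 or x0 + extract_box > nx or y0 + extract_box > ny:
            n_skipped += 1
            continue
        boxes.append(img[y0 : y0 + extract_box, x0 : x0 + extract_box])
        kept_rows.append((float(x), float(y), float(x - cx), float(y - cy)))
    if n_skipped:
        logger.info("skipped %d edge particle(s)", n_skipped)
    if not boxes:
        raise CryomergeError("no particles could be extracted")
    stack = ImageStack(np.stack(boxes), apix=apix)
    if scaled_box != extract_box:
        stack = fourier_rescale_to_box(stack, extract_box, scaled_box).object
    normalized = []
    for window in stack.data.astype(np.float64):
        bg = window[mask]
        bg_sd = bg.std()
        if bg_sd == 0:
            raise CryomergeError(
                "background has zero variance; cannot normalize particle"
            )
        window = (window - bg.mean()) / bg_sd
        if invert_contrast:
            window = -window
        normalized.append(window)
    stack = ImageStack(np.stack(normalized), apix=stack.apix)
    table = StarTable.from_columns(
        {
            "_rlnCoordinateX": [r[0] for r in kept_rows],
            "_rlnCoordinateY": [r[1] for r in kept_rows],
            "_rlnOriginX": [r[2] for r in kept_rows],
            "_rlnOriginY": [r[3] for r in kept_rows],
        }
    )
    return stack, table


def merge_datasets(
    table1: StarTable, table2: StarTable, tolerance: float = 1e-3
) -> StarTable:
    """Join two particle tables, refusing silently mismatched scales.

    The pixel size implied by each table's magnification/detector-pixel
    columns must agree within ``tolerance`` Å (and box sizes, when an
    ``_rlnImageSize`` column is present, must be equal); otherwise a
    :class:`MergeError` cites both values.
    """
    a1, a2 = table1.implied_apix(), table2.implied_apix()
    if a1 is not None and a2 is not None and abs(a1 - a2) > tolerance:
        raise MergeError(
            f"refusing to merge tables with mismatched pixel sizes: "
            f"{a1:.4f} vs {a2:.4f} Å/px (tolerance {tolerance})"
        )
    if "_rlnImageSize" in table1.columns and "_rlnImageSize" in table2.columns:
        b1 = set(table1["_rlnImageSize"].unique())
        b2 = set(table2["_rlnImageSize"].unique())
        if b1 != b2:
            raise MergeError(f"refusing to merge different box sizes: {b1} vs {b2}")
    return join_star(
        [table1, table2], required=("_rlnCoordinateX", "_rlnCoordinateY")
    )
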