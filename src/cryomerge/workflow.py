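"""End-to-end harmonization workflows tying the modules together.

Both workflows start from a calibrated relative pixel size (see
:mod:`cryomerge.scale_calibrate`) and end with one particle table on a
common scale ready to be joined:

* Method 1 (:func:`run_method1`) rescales the *micrographs* of every
  non-reference dataset to the target pixel size and rewrites the picked
  coordinates to match.  CTF parameters must then be re-estimated on the
  rescaled micrographs with an external tool; the emitted table carries a
  flag column saying so.
* Method 2 (:func:`run_method2`) leaves micrographs alone: it rescales the
  CTF metadata analytically, re-extracts particles with an even box pair
  that realizes the scale factor, crops to the common box and joins.

Every scale factor applied is recorded in an audit manifest so a run can be
replayed and checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctf_adjust import defocus_scale_factor, scale_ctf_table
from .exceptions import CryomergeError
from .formats_io import ImageStack, StarTable, join_star
from .grid_rescale import crop_window, fourier_rescale
from .particle_ops import (
    ParticleRescaleSpec,
    background_diameter,
    extract_particles,
    find_box_pairs,
    merge_datasets,
    rescale_particle_table,
)

__all__ = ["DatasetSpec", "WorkflowConfig", "run_method1", "run_method2"]


@dataclass
class DatasetSpec:
    """One dataset entering a merge.

    ``apix_nominal`` is what the facility reported and the initial processing
    assumed; ``apix_relative`` the calibrated value (equal to the nominal for
    the reference dataset).  ``micrographs`` maps name -> :class:`ImageStack`;
    ``particles`` is the picked/extracted metadata; ``ctf`` an optional
    per-micrograph CTF table.
    """

    label: str
    apix_nominal: float
    apix_relative: float | None = None
    micrographs: dict[str, ImageStack] = field(default_factory=dict)
    particles: StarTable | None = None
    ctf: StarTable | None = None

    @property
    def calibrated_apix(self) -> float:
        if self.apix_relative is None:
            raise CryomergeError(
                f"dataset {self.label!r} has no calibrated relative pixel size; "
                "run `cryomerge calibrate` first"
            )
        return self.apix_relative


@dataclass
class WorkflowConfig:
    """A merge job: one reference dataset plus the datasets to harmonize.

    The target pixel size always equals the reference dataset's pixel size —
    the convention of holding the larger pixel size constant.
    """

    reference: DatasetSpec
    others: list[DatasetSpec] = field(default_factory=list)
    final_box: int | None = None
    max_search_box: int | None = None
    apix_tolerance: float = 2e-3
    seed: int = 0

    @property
    def target_apix(self) -> float:
        return self.reference.apix_nominal


def run_method1(config: WorkflowConfig) -> dict:
    """Merge by rescaling micrographs and rewriting picked coordinates.

    Returns ``{"particles", "micrographs", "manifest"}``: the merged table,
    the rescaled micrographs per dataset, and the audit log of every factor
    applied.  CTF columns in the output are to be re-estimated externally on
    the rescaled micrographs (the table carries a flag column).
    """
    target = config.target_apix
    manifest: list[dict] = [
        {"step": "reference", "dataset": config.reference.label, "apix": target}
    ]
    if not config.others:
        return {
            "particles": config.reference.particles,
            "micrographs": {},
            "manifest": manifest,
        }
    tables = [config.reference.particles]
    all_mics: dict[str, dict[str, ImageStack]] = {}
    for ds in config.others:
        relative = ds.calibrated_apix
        mics: dict[str, ImageStack] = {}
        for name, mic in ds.micrographs.items():
            declared = ImageStack(mic.data, apix=relative, is_movie=mic.is_movie)
            result = fourier_rescale(declared, target)
            mics[name] = result.object
            manifest.append(
                {
                    "step": "rescale_micrograph",
                    "dataset": ds.label,
                    "micrograph": name,
                    "apix_from": relative,
                    "apix_to": result.achieved_apix,
                }
            )
        all_mics[ds.label] = mics
        if ds.particles is None:
            raise CryomergeError(f"dataset {ds.label!r} has no particle table")
        spec = ParticleRescaleSpec(
            pix_nominal=ds.apix_nominal,
            pix_relative=relative,
            pix_target=target,
        )
        table = rescale_particle_table(ds.particles, spec)
        manifest.append(
            {
                "step": "rescale_coordinates",
                "dataset": ds.label,
                "factor": spec.coordinate_factor,
            }
        )
        tables.append(table)
    merged = join_star(tables, required=("_rlnCoordinateX", "_rlnCoordinateY"))
    merged.df["_rlnCtfNeedsReestimation"] = 1
    manifest.append({"step": "join", "rows": len(merged)})
    return {"particles": merged, "micrographs": all_mics, "manifest": manifest}


def run_method2(config: WorkflowConfig) -> dict:
    """Merge by rescaling particles at extraction time.

    For each non-reference dataset: scale the CTF table analytically
    (defocus by the square of the pixel-size ratio), pick an even box pair
    realizing the scale factor, extract + normalize + rescale particles from
    the micrographs, crop to the final box and join with the reference.
    Returns ``{"particles", "stacks", "box_pair", "manifest"}``.
    """
    if config.final_box is None:
        raise CryomergeError("Method 2 needs the final (reference) box size")
    target = config.target_apix
    final_box = config.final_box
    manifest: list[dict] = [
        {"step": "reference", "dataset": config.reference.label, "apix": target}
    ]
    tables = (
        [config.reference.particles] if config.reference.particles is not None else []
    )
    stacks: dict[str, ImageStack] = {}
    box_pair = None
    for ds in config.others:
        relative = ds.calibrated_apix
        ctf_scaled = None
        if ds.ctf is not None:
            ctf_scaled = scale_ctf_table(ds.ctf, ds.apix_nominal, relative)
            manifest.append(
                {
                    "step": "scale_ctf",
                    "dataset": ds.label,
                    "factor": defocus_scale_factor(ds.apix_nominal, relative),
                }
            )
        max_box = config.max_search_box or int(final_box * 1.5)
        box_pair = find_box_pairs(final_box, max_box, relative, target, 1)[0]
        bg = background_diameter(final_box, target, relative)
        manifest.append(
            {
                "step": "box_pair",
                "dataset": ds.label,
                "extract_box": box_pair.extract_box,
                "scaled_box": box_pair.scaled_box,
                "error_percent": box_pair.error_percent,
                "bg_diameter": bg,
            }
        )
        if ds.particles is None:
            raise CryomergeError(f"dataset {ds.label!r} has no particle table")
        parts = []
        coord_rows = []
        for name, mic in ds.micrographs.items():
            sel = ds.particles.df["_rlnMicrographName"] == name
            coords = list(
                zip(
                    ds.particles.df.loc[sel, "_rlnCoordinateX"],
                    ds.particles.df.loc[sel, "_rlnCoordinateY"],
                )
            )
            if not coords:
                continue
            declared = ImageStack(mic.data, apix=relative, is_movie=mic.is_movie)
            stack, table = extract_particles(
                declared,
                coords,
                box_pair.extract_box,
                box_pair.scaled_box,
                bg,
            )
            cropped = crop_window(stack, final_box)
            if abs(cropped.apix - target) > config.apix_tolerance:
                raise CryomergeError(
                    f"achieved pixel size {cropped.apix} incompatible with "
                    f"target {target} (tolerance {config.apix_tolerance})"
                )
            parts.append(cropped)
            table.df["_rlnMicrographName"] = name
            coord_rows.append(table)
        if not parts:
            raise CryomergeError(f"dataset {ds.label!r} yielded no particles")
        stacks[ds.label] = ImageStack(
            np.concatenate([p.data for p in parts]), apix=parts[0].apix
        )
        ds_table = join_star(coord_rows) if len(coord_rows) > 1 else coord_rows[0]
        ds_table.df["_rlnMagnification"] = 10000.0
        ds_table.df["_rlnDetectorPixelSize"] = stacks[ds.label].apix
        tables.append(ds_table)
        manifest.append(
            {
                "step": "extract",
                "dataset": ds.label,
                "particles": stacks[ds.label].n_images,
                "apix": stacks[ds.label].apix,
            }
        )
    if len(tables) >= 2:
        merged = tables[0]
        for t in tables[1:]:
            merged = merge_datasets(merged, t, tolerance=config.apix_tolerance)
    else:
        merged = tables[0]
    manifest.append({"step": "join", "rows": len(merged)})
    return {
        "particles": merged,
        "stacks": stacks,
        "box_pair": box_pair,
        "manifest": manifest,
    }
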