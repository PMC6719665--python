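"""Rescaling CTF metadata when the pixel size of a dataset is corrected.

Fitted defocus depends on the *assumed* pixel size: the CTF is a function of
physical spatial frequency, but the fit sees digital frequencies, so
re-declaring the pixel size from ``old`` to ``new`` Å/px rescales every
frequency by ``old/new`` and, to leading order, the fitted defocus by

    (new / old)^2        (e.g. (0.880/0.900)^2 = 0.956049),

while the spherical-aberration term, quartic in frequency, would need

    Cs -> Cs * (old / new)^4   (e.g. 2.7 mm * (0.900/0.880)^4 = 2.954 mm).

:func:`scale_ctf_table` applies the defocus factor to a RELION micrograph
table and normalizes the magnification/detector-pixel columns so the implied
pixel size equals the corrected one.  By default only the quadratic factor is
applied (the defocus-dominated regime; Cs can instead be kept fixed and the
residual absorbed by later per-dataset CTF refinement).  Optionally a
constant defocus offset can be added that makes the CTF phase *exact* at one
chosen reference frequency, absorbing the quartic mismatch there — see
:func:`phase_match_constant` for the derivation and sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MergeError
from .formats_io import StarTable

__all__ = [
    "OpticalParams",
    "DefocusScaling",
    "electron_wavelength",
    "defocus_scale_factor",
    "scale_cs",
    "phase_match_constant",
    "ctf_phase",
    "scale_ctf_table",
]

MM_TO_A = 1.0e7


@dataclass
class OpticalParams:
    """Microscope optics: acceleration voltage (kV), wavelength (Å), Cs (Å)."""

    voltage: float
    cs: float = 2.7 * MM_TO_A

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)

    @property
    def cs_mm(self) -> float:
        return self.cs / MM_TO_A


@dataclass
class DefocusScaling:
    """A defocus correction: multiplicative factor plus additive constant (Å)."""

    old_apix: float
    new_apix: float
    constant: float = 0.0

    @property
    def factor(self) -> float:
        return defocus_scale_factor(self.old_apix, self.new_apix)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV.

    lambda = 12.2639 / sqrt(V * (1 + 0.97845e-6 * V)) with V in volts;
    12.2639 = h / sqrt(2 m0 e) in Å·V^1/2 and 0.97845e-6 = e / (2 m0 c^2)
    in 1/V.  300 kV -> 0.0197 Å.
    """
    if voltage_kv <= 0:
        raise ValueError("voltage must be > 0")
    v = voltage_kv * 1.0e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def defocus_scale_factor(old_apix: float, new_apix: float) -> float:
    """Multiplicative defocus correction ``(new_apix / old_apix)**2``."""
    if old_apix <= 0 or new_apix <= 0:
        raise ValueError("pixel sizes must be > 0")
    return (new_apix / old_apix) ** 2


def scale_cs(cs_mm: float, old_apix: float, new_apix: float) -> float:
    """Spherical-aberration correction ``cs * (old_apix / new_apix)**4`` (mm in, mm out)."""
    if cs_mm < 0:
        raise ValueError("Cs must be >= 0")
    if old_apix <= 0 or new_apix <= 0:
        raise ValueError("pixel sizes must be > 0")
    return cs_mm * (old_apix / new_apix) ** 4


def ctf_phase(k: float, defocus: float, cs: float, wavelength: float) -> float:
    """CTF phase chi(k) = pi*lambda*dz*k^2 - (pi/2)*Cs*lambda^3*k^4.

    ``k`` in 1/Å, ``defocus`` (underfocus positive) and ``cs`` in Å.  Serves
    as the oracle for the phase-matching constant.
    """
    return (
        np.pi * wavelength * defocus * k**2
        - 0.5 * np.pi * cs * wavelength**3 * k**4
    )


def phase_match_constant(
    cs_mm: float,
    voltage_kv: float,
    old_apix: float,
    new_apix: float,
    ref_resolution: float,
) -> float:
    """Additive defocus constant (Å) that makes the rescaled CTF phase exact
    at one reference frequency.

    The quadratic factor alone leaves a quartic phase residual when Cs is
    kept fixed.  Writing ``s = old_apix / new_apix`` (frequencies map as
    ``k -> s * k``) and requiring ``chi`` equality at the original-frame
    frequency ``k_ref = 1 / ref_resolution`` gives

        c = (Cs * lambda^2 / 2) * k_ref^2 * (s^4 - 1) / s^2 .

    With the :func:`ctf_phase` sign convention (underfocus positive, Cs term
    negative) the constant is positive when the pixel size shrinks; under the
    opposite Cs sign convention the same magnitude applies with opposite
    sign.
    """
    if ref_resolution <= 0:
        raise ValueError("reference resolution must be > 0 Å")
    lam = electron_wavelength(voltage_kv)
    cs = cs_mm * MM_TO_A
    s = old_apix / new_apix
    k_ref = 1.0 / ref_resolution
    return 0.5 * cs * lam**2 * k_ref**2 * (s**4 - 1.0) / s**2


def scale_ctf_table(
    table: StarTable,
    old_apix: float,
    new_apix: float,
    constant_mode: str = "off",
    ref_resolution: float | None = None,
) -> StarTable:
    """Rescale the defocus columns of a RELION micrograph/particle table.

    ``_rlnDefocusU`` and ``_rlnDefocusV`` are multiplied by
    ``(new/old)**2``; with ``constant_mode="phase_match"`` the additive
    constant from :func:`phase_match_constant` is applied on top (requires
    ``ref_resolution`` plus Cs and voltage columns).  ``_rlnMagnification``
    is set to 10000 and ``_rlnDetectorPixelSize`` to ``new_apix`` so the
    implied pixel size equals the corrected value.  The astigmatism angle is
    a pure rotation and is never rescaled; all other columns pass through
    untouched.
    """
    for tag in ("_rlnDefocusU", "_rlnDefocusV"):
        if tag not in table.columns:
            raise MergeError(f"defocus column {tag} missing from table")
    factor = defocus_scale_factor(old_apix, new_apix)
    constant = 0.0
    if constant_mode == "phase_match":
        if ref_resolution is None:
            raise ValueError("phase_match mode needs a reference resolution (Å)")
        for tag in ("_rlnSphericalAberration", "_rlnVoltage"):
            if tag not in table.columns:
                raise MergeError(f"phase_match mode needs column {tag}")
        cs_mm = float(table["_rlnSphericalAberration"].iloc[0])
        voltage = float(table["_rlnVoltage"].iloc[0])
        constant = phase_match_constant(
            cs_mm, voltage, old_apix, new_apix, ref_resolution
        )
    elif constant_mode != "off":
        raise ValueError(f"unknown constant_mode {constant_mode!r}")
    out = table.copy()
    out.df["_rlnDefocusU"] = out.df["_rlnDefocusU"] * factor + constant
    out.df["_rlnDefocusV"] = out.df["_rlnDefocusV"] * factor + constant
    if "_rlnMagnification" in out.columns:
        out.df["_rlnMagnification"] = 10000.0
    if "_rlnDetectorPixelSize" in out.columns:
        out.df["_rlnDetectorPixelSize"] = float(new_apix)
    return out
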