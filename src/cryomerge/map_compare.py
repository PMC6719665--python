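"""Map-agreement metrics: FSC curves, scalar scores, real-space correlation,
translational registration.

The Fourier shell correlation between maps with transforms ``F1``, ``F2`` is,
per shell ``s`` of integer Fourier radius,

    FSC(s) = Re( sum F1 · conj(F2) ) / sqrt( sum |F1|^2 · sum |F2|^2 ),

with shells one Fourier voxel wide up to Nyquist.  Both maps must already sit
on the same grid (box, pixel size, origin) — resample first; after rescaling
the origin shifts, so registration is part of every calibration loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import CryomergeError, GridMismatchError
from .formats_io import DensityMap, StarTable

__all__ = [
    "FscCurve",
    "fsc",
    "fsc_score",
    "real_space_cc",
    "register_translation",
    "apply_shift",
    "fsc_to_star",
]


@dataclass
class FscCurve:
    """Per-shell correlation between two maps on a common grid.

    ``shell_freq`` holds spatial frequencies (1/Å) at shell centers, ordered
    from DC up to Nyquist; ``shell_counts`` the number of Fourier voxels per
    shell.
    """

    shell_freq: np.ndarray
    fsc: np.ndarray
    shell_counts: np.ndarray

    def __len__(self) -> int:
        return len(self.fsc)


def _check_same_grid(map1: DensityMap, map2: DensityMap) -> None:
    if map1.box != map2.box:
        raise GridMismatchError(
            f"boxes differ ({map1.box} vs {map2.box}); resample onto a common "
            "grid before comparing"
        )
    a1, a2 = map1.require_apix(), map2.require_apix()
    if abs(a1 - a2) > 1e-6 * max(a1, a2):
        raise GridMismatchError(
            f"pixel sizes differ ({a1} vs {a2}); resample onto a common grid"
        )
    if np.max(np.abs(map1.origin - map2.origin)) > 1e-3 * a1:
        raise GridMismatchError(
            "origins differ; superpose/resample before comparing (rescaling "
            "shifts the origin)"
        )


def _shell_radii(shape) -> np.ndarray:
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * n for n in shape], indexing="ij", sparse=True
    )
    r = np.sqrt(sum(g.astype(np.float64) ** 2 for g in grids))
    return np.rint(r).astype(np.intp)


def fsc(map1: DensityMap, map2: DensityMap) -> FscCurve:
    """Fourier shell correlation between two maps on an identical grid."""
    _check_same_grid(map1, map2)
    if not map1.is_cubic:
        raise GridMismatchError("FSC requires cubic boxes")
    n = map1.box[0]
    apix = map1.require_apix()
    f1 = np.fft.fftn(map1.data.astype(np.float64))
    f2 = np.fft.fftn(map2.data.astype(np.float64))
    radii = _shell_radii(map1.box)
    nyq = n // 2
    mask = radii <= nyq
    r = radii[mask]
    num = np.bincount(r, weights=(f1 * np.conj(f2)).real[mask], minlength=nyq + 1)
    d1 = np.bincount(r, weights=(np.abs(f1) ** 2)[mask], minlength=nyq + 1)
    d2 = np.bincount(r, weights=(np.abs(f2) ** 2)[mask], minlength=nyq + 1)
    counts = np.bincount(r, minlength=nyq + 1)
    denom = np.sqrt(d1 * d2)
    curve = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    freqs = np.arange(nyq + 1) / (n * apix)
    return FscCurve(freqs, curve, counts)


def fsc_score(curve: FscCurve) -> float:
    """Scalar agreement score: mean FSC over all shells excluding DC.

    Monotone under uniform improvement and stable on low-resolution phantoms;
    used to rank candidate pixel sizes during calibration.
    """
    if len(curve) == 0:
        raise CryomergeError("empty FSC curve")
    if len(curve) == 1:
        return float(curve.fsc[0])
    return float(np.mean(curve.fsc[1:]))


def real_space_cc(
    map1: DensityMap, map2: DensityMap, mask: DensityMap | None = None
) -> float:
    """Pearson correlation between voxel values, optionally inside a mask.

    The mask is an ordinary map with values in [0, 1]; voxels with
    ``mask > 0.5`` contribute.  Affine-invariant: ``cc(m, 2m + 5) = 1``.
    """
    _check_same_grid(map1, map2)
    a = map1.data.astype(np.float64).ravel()
    b = map2.data.astype(np.float64).ravel()
    if mask is not None:
        if mask.box != map1.box:
            raise GridMismatchError("mask grid differs from map grid")
        sel = mask.data.ravel() > 0.5
        a, b = a[sel], b[sel]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise CryomergeError("correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def register_translation(ref: DensityMap, moving: DensityMap) -> np.ndarray:
    """Shift (voxels, z/y/x) that best superposes ``moving`` onto ``ref``.

    Finds the integer-voxel maximum of the circular cross-correlation, then
    refines each axis with a three-point parabola.  Applying the returned
    shift to ``moving`` (see :func:`apply_shift`) maximizes the real-space
    correlation with ``ref``.
    """
    _check_same_grid(ref, moving)
    fr = np.fft.fftn(ref.data.astype(np.float64))
    fm = np.fft.fftn(moving.data.astype(np.float64))
    cc = np.fft.ifftn(fr * np.conj(fm)).real
    peak = np.array(np.unravel_index(np.argmax(cc), cc.shape))
    shift = peak.astype(float)
    # sub-voxel refinement per axis on wrapped neighbors
    for ax in range(cc.ndim):
        n = cc.shape[ax]
        idx = list(peak)
        c0 = cc[tuple(idx)]
        idx[ax] = (peak[ax] - 1) % n
        cm = cc[tuple(idx)]
        idx[ax] = (peak[ax] + 1) % n
        cp = cc[tuple(idx)]
        denom = cm - 2.0 * c0 + cp
        if denom < 0:  # genuine local maximum
            shift[ax] += 0.5 * (cm - cp) / denom
    # wrap into (-n/2, n/2]
    for ax, n in enumerate(cc.shape):
        if shift[ax] > n / 2:
            shift[ax] -= n
    return shift


def apply_shift(map_: DensityMap, shift) -> DensityMap:
    """Circularly shift a map by a (possibly sub-voxel) shift via Fourier phase."""
    spec = np.fft.fftn(map_.data.astype(np.float64))
    out = np.fft.ifftn(ndimage.fourier_shift(spec, shift)).real
    return DensityMap(out, apix=map_.apix, origin=map_.origin.copy())


def plot_fsc(curves: dict[str, FscCurve], path: str | None = None):
    """Plot one or more FSC curves against spatial frequency (1/Å).

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve.shell_freq, curve.fsc, label=label)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("spatial frequency (1/Å)")
    ax.set_ylabel("FSC")
    ax.set_ylim(-0.1, 1.05)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def fsc_to_star(curve: FscCurve, name: str = "fsc") -> StarTable:
    """Export an FSC curve as a STAR-style table (frequency, FSC)."""
    return StarTable.from_columns(
        {
            "_rlnSpectralIndex": np.arange(len(curve)),
            "_rlnResolution": curve.shell_freq,
            "_rlnFourierShellCorrelation": curve.fsc,
        },
        name=name,
    )
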