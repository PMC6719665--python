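"""Pixel-size changes by reciprocal-space pad/crop, real-space resampling and windowing.

The workhorse is :func:`fourier_rescale`: forward FFT, symmetric crop (to a
larger pixel size) or zero-pad (to a smaller one) of the centered spectrum,
inverse FFT.  Because the box can only change in steps of 2 pixels (even boxes
throughout), the achievable pixel size is quantized; :func:`granularity`
returns the step, ``2 * apix / box`` — 2% of the pixel size for a 100-pixel
box, 1% for a 200-pixel box.

Spectrum convention: after an ``fftshift`` the DC term sits at index
``box // 2`` in every dimension, and pad/crop is symmetric about it.  This
makes the identity rescale exact and keeps the image center (pixel
``box // 2``) fixed, so a centered particle stays centered; any sub-pixel
origin shift that remains is handled downstream by translational
registration.  Grey values are preserved (the spectrum is renormalized so the
mean is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import CryomergeError, GridMismatchError
from .formats_io import DensityMap, ImageStack

__all__ = [
    "RescaleResult",
    "granularity",
    "fourier_rescale",
    "fourier_rescale_to_box",
    "crop_window",
    "pad_window",
    "resample_real_space",
]


@dataclass
class RescaleResult:
    """Outcome of a Fourier rescale.

    ``achieved_apix`` is ``old_box * old_apix / new_box`` — the pixel size the
    even-box constraint actually allowed, within half a granularity step of
    the request.
    """

    object: DensityMap | ImageStack
    requested_apix: float
    achieved_apix: float
    new_box: int


def granularity(box: int, apix: float) -> float:
    """Smallest nonzero pixel-size step achievable by even-box pad/crop.

    Changing an even box by one even step (2 pixels) changes the effective
    pixel size by ``2 * apix / box``: 0.02 Å for a 100-pixel box at
    1 Å/px, 0.01 Å for a 200-pixel box.
    """
    box = int(box)
    if box % 2:
        raise ValueError(f"box must be even, got {box}")
    if box < 4:
        raise ValueError(f"box must be >= 4, got {box}")
    return 2.0 * float(apix) / box


def _nearest_even(x: float) -> int:
    return int(round(x / 2.0)) * 2


def _check_even(n: int, what: str = "box") -> None:
    if n % 2:
        raise ValueError(f"{what} sizes must be even-numbered, got {n}")


def _pad_crop_centered(spec: np.ndarray, new_sizes, axes) -> np.ndarray:
    """Symmetric pad/crop of a centered (fftshifted) spectrum.

    Zero-padding leaves every original coefficient in place, so total spectral
    power is conserved exactly (Parseval); cropping discards the shells beyond
    the new Nyquist.
    """
    out = spec
    for ax, n_new in zip(axes, new_sizes):
        n_old = out.shape[ax]
        if n_new == n_old:
            continue
        sl = [slice(None)] * out.ndim
        if n_new < n_old:
            start = (n_old - n_new) // 2
            sl[ax] = slice(start, start + n_new)
            out = out[tuple(sl)]
        else:
            shape = list(out.shape)
            shape[ax] = n_new
            padded = np.zeros(shape, dtype=out.dtype)
            start = (n_new - n_old) // 2
            sl[ax] = slice(start, start + n_old)
            padded[tuple(sl)] = out
            out = padded
    return out


def _spatial_axes(obj) -> tuple[int, ...]:
    return (0, 1, 2) if isinstance(obj, DensityMap) else (1, 2)


def _rescale_data(data: np.ndarray, axes, new_sizes) -> np.ndarray:
    spec = np.fft.fftshift(np.fft.fftn(data, axes=axes), axes=axes)
    spec = _pad_crop_centered(spec, new_sizes, axes)
    out = np.fft.ifftn(np.fft.ifftshift(spec, axes=axes), axes=axes).real
    old_n = np.prod([data.shape[a] for a in axes])
    new_n = np.prod(new_sizes)
    return (out * (new_n / old_n)).astype(np.float32)


def fourier_rescale(
    obj: DensityMap | ImageStack, target_apix: float
) -> RescaleResult:
    """Rescale a map, micrograph or movie to (approximately) ``target_apix``.

    The new box is the nearest even integer to ``box * apix / target_apix``
    per spatial axis; the achieved pixel size is reported in the result.
    Movies and stacks rescale frame by frame with the same spatial factor.
    """
    apix = obj.require_apix()
    if target_apix <= 0:
        raise ValueError("target apix must be > 0")
    axes = _spatial_axes(obj)
    for ax in axes:
        _check_even(obj.data.shape[ax])
    factor = apix / float(target_apix)
    new_sizes = [_nearest_even(obj.data.shape[ax] * factor) for ax in axes]
    if min(new_sizes) < 4:
        raise CryomergeError(
            f"rescale to {target_apix} Å/px would shrink the box below 4 pixels"
        )
    out = _rescale_data(obj.data, axes, new_sizes)
    n0 = obj.data.shape[axes[0]]
    achieved = n0 * apix / new_sizes[0]
    if isinstance(obj, DensityMap):
        center = obj.center_physical()
        new_origin = center - np.array([n // 2 for n in new_sizes]) * achieved
        result = DensityMap(out, apix=achieved, origin=new_origin)
        new_box = new_sizes[0]
    else:
        result = ImageStack(out, apix=achieved, is_movie=obj.is_movie)
        new_box = new_sizes[-1]
    return RescaleResult(result, float(target_apix), achieved, new_box)


def fourier_rescale_to_box(
    obj: DensityMap | ImageStack, extract_box: int, scaled_box: int
) -> RescaleResult:
    """Rescale by the exact factor ``scaled_box / extract_box``.

    This is the particle-extraction flavour: the object must currently have
    spatial size ``extract_box`` and is resampled to ``scaled_box``; the
    achieved pixel size is ``apix * extract_box / scaled_box`` exactly (e.g.
    560 px at 0.880 Å/px -> 440 px at 1.120 Å/px).
    """
    apix = obj.require_apix()
    _check_even(extract_box)
    _check_even(scaled_box)
    axes = _spatial_axes(obj)
    for ax in axes:
        if obj.data.shape[ax] != extract_box:
            raise GridMismatchError(
                f"object box {obj.data.shape[ax]} != extract_box {extract_box}"
            )
    achieved = apix * extract_box / scaled_box
    new_sizes = [scaled_box] * len(axes)
    out = _rescale_data(obj.data, axes, new_sizes)
    if isinstance(obj, DensityMap):
        center = obj.center_physical()
        new_origin = center - np.array([scaled_box // 2] * 3) * achieved
        result = DensityMap(out, apix=achieved, origin=new_origin)
    else:
        result = ImageStack(out, apix=achieved, is_movie=obj.is_movie)
    return RescaleResult(result, achieved, achieved, scaled_box)


def crop_window(obj: DensityMap | ImageStack, new_box: int):
    """Centered real-space window; the pixel size is unchanged.

    Crops every spatial axis to ``new_box`` about the center pixel
    ``box // 2`` (which remains the center pixel of the window), e.g. the
    440 -> 420 crop after extraction with rescale.
    """
    _check_even(new_box)
    axes = _spatial_axes(obj)
    slices = [slice(None)] * obj.data.ndim
    for ax in axes:
        n = obj.data.shape[ax]
        _check_even(n)
        if new_box > n:
            raise ValueError(f"window {new_box} exceeds current box {n}")
        start = (n - new_box) // 2
        slices[ax] = slice(start, start + new_box)
    out = obj.data[tuple(slices)].copy()
    if isinstance(obj, DensityMap):
        start_off = np.array([(obj.data.shape[a] - new_box) // 2 for a in axes])
        new_origin = obj.origin + start_off * (obj.apix or 0.0)
        return DensityMap(out, apix=obj.apix, origin=new_origin)
    return ImageStack(out, apix=obj.apix, is_movie=obj.is_movie)


def pad_window(obj: DensityMap | ImageStack, new_box: int):
    """Centered zero-pad to a larger box; inverse of :func:`crop_window`."""
    _check_even(new_box)
    axes = _spatial_axes(obj)
    shape = list(obj.data.shape)
    slices = [slice(None)] * obj.data.ndim
    for ax in axes:
        n = obj.data.shape[ax]
        _check_even(n)
        if new_box < n:
            raise ValueError(f"pad target {new_box} smaller than current box {n}")
        shape[ax] = new_box
        start = (new_box - n) // 2
        slices[ax] = slice(start, start + n)
    out = np.zeros(shape, dtype=np.float32)
    out[tuple(slices)] = obj.data
    if isinstance(obj, DensityMap):
        start_off = np.array([(new_box - obj.data.shape[a]) // 2 for a in axes])
        new_origin = obj.origin - start_off * (obj.apix or 0.0)
        return DensityMap(out, apix=obj.apix, origin=new_origin)
    return ImageStack(out, apix=obj.apix, is_movie=obj.is_movie)


def resample_real_space(
    map: DensityMap, new_apix: float, onto: DensityMap
) -> DensityMap:
    """Re-declare ``map`` at ``new_apix`` and interpolate it onto ``onto``'s grid.

    After this both maps share box, pixel size and origin, as required for
    FSC.  The re-declaration keeps the center voxel in place (see
    :meth:`DensityMap.with_apix`); interpolation is trilinear with zeros
    outside the source grid.
    """
    moving = map.with_apix(new_apix)
    onto_apix = onto.require_apix()
    # affine mapping from output voxel index to moving-map index, per axis
    scale = np.full(3, onto_apix / moving.apix)
    offset = (onto.origin - moving.origin) / moving.apix
    # overlap check in physical space
    for a in range(3):
        m_lo, m_hi = moving.origin[a], moving.origin[a] + (moving.box[a] - 1) * moving.apix
        o_lo, o_hi = onto.origin[a], onto.origin[a] + (onto.box[a] - 1) * onto_apix
        if m_hi < o_lo or o_hi < m_lo:
            raise GridMismatchError(
                "maps do not overlap in physical space after origin accounting"
            )
    out = ndimage.affine_transform(
        moving.data.astype(np.float64),
        np.diag(scale),
        offset=offset,
        output_shape=onto.box,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return DensityMap(out, apix=onto_apix, origin=onto.origin.copy())
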