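"""Empirical determination of the relative pixel size between two datasets.

Both entry points take two independent reconstructions of the same particle.
:func:`scan_relative_pixel_size` is the coarse stage: declare the target map
at a grid of candidate pixel sizes, resample each candidate onto the
reference grid, re-register (rescaling shifts the origin), and rank by mean
FSC.  Because the underlying pad/crop rescaling can only change the pixel
size in steps of ``2 * apix / box``, the scan reports a *plateau* — the range
of candidates whose score is indistinguishable from the best — rather than a
single sharp optimum.

:func:`refine_scale_realspace` is the fine stage: continuous golden-section
maximization of the real-space correlation coefficient within the plateau
bounds.  Real-space correlation over trilinear resampling is not granularity
limited, so it resolves the pixel size below the FSC scan's step.

Convention: the dataset with the larger pixel size is the reference and is
held constant; a warning is emitted when the call violates this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CalibrationWarning
from .formats_io import DensityMap
from .grid_rescale import granularity, resample_real_space
from .map_compare import (
    apply_shift,
    fsc,
    fsc_score,
    real_space_cc,
    register_translation,
)

__all__ = [
    "ScaleScanResult",
    "scan_relative_pixel_size",
    "refine_scale_realspace",
    "scaling_factor",
]


@dataclass
class ScaleScanResult:
    """Result of a coarse pixel-size scan.

    ``best_apix`` maximizes the FSC score; ``range_low``/``range_high`` bound
    the plateau of candidates scoring within ``plateau_tol`` of the best —
    the natural starting bracket for continuous refinement.  ``granularity``
    is the pad/crop pixel-size step of the target map's box.
    """

    best_apix: float
    range_low: float
    range_high: float
    candidates: list[tuple[float, float]] = field(default_factory=list)
    granularity: float = 0.0

    def format(self) -> str:
        """One-line report, e.g. ``BEST:1.282 range:1.274 - 1.29``."""
        return (
            f"BEST:{self.best_apix:.4g} "
            f"range:{self.range_low:.4g} - {self.range_high:.4g}"
        )

    def plot(self, path: str | None = None):
        """Score-vs-pixel-size plot of the scanned candidates.

        Returns the matplotlib Axes; saves to ``path`` when given.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        apix = [a for a, _ in self.candidates]
        score = [s for _, s in self.candidates]
        ax.plot(apix, score, "o-")
        ax.axvline(self.best_apix, color="red", lw=0.8, label=f"best {self.best_apix:.4g}")
        ax.axvspan(self.range_low, self.range_high, color="red", alpha=0.1)
        ax.set_xlabel("candidate pixel size (Å)")
        ax.set_ylabel("mean FSC")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax


def scaling_factor(actual_apix: float, reference_apix: float) -> float:
    """Relative scale between datasets: actual / reference pixel size.

    E.g. 1.28 / 1.40 = 0.914.
    """
    if actual_apix <= 0 or reference_apix <= 0:
        raise ValueError("pixel sizes must be > 0")
    return actual_apix / reference_apix


def _score_candidate(
    ref: DensityMap, target: DensityMap, candidate_apix: float, metric: str
) -> float:
    resampled = resample_real_space(target, candidate_apix, ref)
    shift = register_translation(ref, resampled)
    aligned = apply_shift(resampled, shift)
    if metric == "fsc":
        return fsc_score(fsc(ref, aligned))
    return real_space_cc(ref, aligned)


def scan_relative_pixel_size(
    ref_map: DensityMap,
    apix_ref: float,
    target_map: DensityMap,
    apix_nominal: float,
    scan_halfwidth: float = 0.10,
    step: float | None = None,
    plateau_tol: float = 1e-3,
) -> ScaleScanResult:
    """Scan candidate pixel sizes for ``target_map`` against a fixed reference.

    Candidates span ``apix_nominal * (1 ± scan_halfwidth)`` with spacing
    ``step`` (default: the target map's granularity, floored at 0.002 Å).
    Each candidate is resampled onto the reference grid, re-registered and
    scored by mean FSC.  The reference pixel size is held constant; pass the
    dataset with the *larger* pixel size as the reference.
    """
    if apix_nominal > apix_ref:
        warnings.warn(
            "target nominal pixel size exceeds the reference; convention is to "
            "hold the larger pixel size constant as the reference",
            CalibrationWarning,
            stacklevel=2,
        )
    ref = ref_map.with_apix(apix_ref)
    target_box = target_map.box[0]
    gran = granularity(target_box, apix_nominal)
    if step is None:
        step = max(gran, 0.002)
    lo = apix_nominal * (1.0 - scan_halfwidth)
    hi = apix_nominal * (1.0 + scan_halfwidth)
    if hi - lo < step:
        warnings.warn(
            "scan window collapsed below one granularity step; "
            "returning a single-candidate result",
            CalibrationWarning,
            stacklevel=2,
        )
        score = _score_candidate(ref, target_map, apix_nominal, "fsc")
        return ScaleScanResult(
            apix_nominal, apix_nominal, apix_nominal, [(apix_nominal, score)], gran
        )
    # grid centered on the nominal value, so the declared pixel size itself
    # is always among the candidates
    k = int(np.floor((hi - lo) / (2.0 * step)))
    candidates = apix_nominal + step * np.arange(-k, k + 1)
    scored = [
        (float(a), _score_candidate(ref, target_map, float(a), "fsc"))
        for a in candidates
    ]
    best_apix, best_score = max(scored, key=lambda t: t[1])
    plateau = [a for a, s in scored if s >= best_score - plateau_tol]
    return ScaleScanResult(
        best_apix=best_apix,
        range_low=min(plateau),
        range_high=max(plateau),
        candidates=scored,
        granularity=gran,
    )


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def refine_scale_realspace(
    ref_map: DensityMap,
    target_map: DensityMap,
    bounds: tuple[float, float],
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Continuous refinement of the relative pixel size by real-space CC.

    Golden-section maximization of the Pearson correlation (after trilinear
    resampling and translational registration) over ``bounds``, typically the
    plateau from :func:`scan_relative_pixel_size`.  Converges to ``tol`` Å.
    Returns ``(apix, cc)``.

    The score is assumed unimodal inside the bracket; a coarse pre-sample
    checks this and warns (returning the best sampled point's bracket) when
    more than one local maximum is seen.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi < lo:
        raise ValueError("bounds must satisfy low <= high")
    ref = ref_map
    if hi - lo <= tol:
        mid = 0.5 * (lo + hi)
        return mid, _score_candidate(ref, target_map, mid, "cc")

    def f(a: float) -> float:
        return _score_candidate(ref, target_map, a, "cc")

    # coarse unimodality check, and a tighter bracket around the best sample
    n_coarse = 7
    xs = np.linspace(lo, hi, n_coarse)
    ys = [f(x) for x in xs]
    interior = np.array(ys[1:-1])
    left = np.array(ys[:-2])
    right = np.array(ys[2:])
    n_maxima = int(np.sum((interior >= left) & (interior >= right)))
    if n_maxima > 1:
        warnings.warn(
            "correlation is not unimodal within the bounds; refining around "
            "the best sampled point only",
            CalibrationWarning,
            stacklevel=2,
        )
    i = int(np.argmax(ys))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_coarse - 1)]

    # golden-section on the bracket [a, b]
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    best = 0.5 * (a + b)
    return float(best), f(best)
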