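"""End-to-end de-noising pipeline.

The pipeline follows the standard wavelet-shrinkage recipe: decompose the
noisy image with a multi-level 2-D discrete wavelet transform, shrink the
detail ("high-frequency") coefficients with the chosen rule and
per-subband thresholds, leave the approximation subband untouched, and
invert the transform.  Signal energy concentrates in few large
coefficients while i.i.d. Gaussian noise spreads evenly across all of
them, so attenuating small coefficients removes mostly noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pywt

from wavedn.metrics import mse as _mse, psnr as _psnr
from wavedn.shrinkage import ShrinkageSpec, apply_shrinkage
from wavedn.thresholds import ORIENTATIONS, ThresholdPolicy, thresholds_for_decomposition

__all__ = ["Image2D", "CoeffSet", "DenoiseReport", "decompose", "reconstruct", "denoise"]

logger = logging.getLogger(__name__)

DEFAULT_WAVELET = "sym4"
DEFAULT_LEVELS = 3
DEFAULT_BOUNDARY = "symmetric"


@dataclass(frozen=True)
class Image2D:
    """An M x N grayscale image with a declared peak intensity."""

    pixels: np.ndarray
    peak: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale array, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8 for a meaningful decomposition, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        if self.peak <= 0:
            raise ValueError(f"peak intensity must be > 0, got {self.peak!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class CoeffSet:
    """A multi-level 2-D wavelet decomposition.

    ``details[0]`` is the finest level (j = 1); each entry maps
    orientation ("horizontal", "vertical", "diagonal") to its subband.
    ``meta`` records wavelet name, level count, boundary mode, original
    image shape and peak, so the decomposition is exactly invertible.
    """

    approx: np.ndarray
    details: List[Dict[str, np.ndarray]]
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def image_shape(self) -> Tuple[int, int]:
        return tuple(self.meta["shape"])


def _max_levels(shape: Tuple[int, int], wavelet: str) -> int:
    w = pywt.Wavelet(wavelet)
    return pywt.dwtn_max_level(shape, w)


def decompose(img: Image2D, wavelet: str = DEFAULT_WAVELET, levels: int = DEFAULT_LEVELS) -> CoeffSet:
    """Multi-level 2-D DWT of ``img`` into approximation + detail subbands."""
    if levels < 1:
        raise ValueError(f"level count must be >= 1, got {levels!r}")
    jmax = _max_levels(img.shape, wavelet)
    if levels > jmax:
        raise ValueError(
            f"image of shape {img.shape} supports at most {jmax} decomposition "
            f"levels with wavelet {wavelet!r}, requested {levels}"
        )
    arr = pywt.wavedec2(img.pixels, wavelet, mode=DEFAULT_BOUNDARY, level=levels)
    approx = arr[0]
    # pywt orders detail tuples coarsest-first; store finest-first (j = 1 first)
    details = [
        {"horizontal": h, "vertical": v, "diagonal": d} for (h, v, d) in reversed(arr[1:])
    ]
    meta = {
        "wavelet": wavelet,
        "levels": levels,
        "mode": DEFAULT_BOUNDARY,
        "shape": img.shape,
        "peak": img.peak,
    }
    return CoeffSet(approx=approx, details=details, meta=meta)


def reconstruct(coeffs: CoeffSet) -> Image2D:
    """Inverse transform; exact (to float rounding) on untouched coefficients."""
    arr = [coeffs.approx] + [
        (lvl["horizontal"], lvl["vertical"], lvl["diagonal"]) for lvl in reversed(coeffs.details)
    ]
    try:
        px = pywt.waverec2(arr, coeffs.meta["wavelet"], mode=coeffs.meta["mode"])
    except ValueError as exc:
        raise ValueError(f"inconsistent coefficient subband shapes: {exc}") from exc
    M, N = coeffs.image_shape
    # waverec2 may pad odd dimensions by one sample
    px = px[:M, :N]
    return Image2D(pixels=px, peak=float(coeffs.meta.get("peak", 1.0)))


@dataclass
class DenoiseReport:
    """Record of one de-noising run: thresholds used and quality metrics."""

    thresholds: Dict[Tuple[int, str], float]
    rule: ShrinkageSpec
    delta: float
    wavelet: str
    levels: int
    mse: Optional[float] = None
    psnr: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        return {
            "rule": self.rule.rule,
            "m": self.rule.m,
            "wavelet": self.wavelet,
            "levels": self.levels,
            "delta": self.delta,
            "thresholds": {f"L{j}/{o}": lam for (j, o), lam in sorted(self.thresholds.items())},
            "mse": self.mse,
            "psnr": self.psnr,
        }


def denoise(
    img: Image2D,
    spec: ShrinkageSpec,
    policy: ThresholdPolicy = ThresholdPolicy(),
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    reference: Optional[Image2D] = None,
) -> Tuple[Image2D, DenoiseReport]:
    """De-noise ``img`` by shrinking detail subbands only.

    ``spec`` is a rule template; its threshold is bound per (level,
    orientation) subband from ``policy``.  The approximation subband is
    passed through untouched and the reconstruction is clipped to
    ``[0, peak]``.  When ``reference`` (the clean image) is given, MSE and
    PSNR of the result are recorded in the report.
    """
    coeffs = decompose(img, wavelet=wavelet, levels=levels)
    table = thresholds_for_decomposition(coeffs, policy)
    delta = policy.resolve_delta(coeffs.details[0]["diagonal"])

    shrunk = CoeffSet(approx=coeffs.approx, details=[], meta=dict(coeffs.meta))
    for j, lvl in enumerate(coeffs.details, start=1):
        out_lvl = {}
        for orient in ORIENTATIONS:
            lam = table[(j, orient)]
            logger.info("level %d %s: lambda = %.6g", j, orient, lam)
            out_lvl[orient] = apply_shrinkage(lvl[orient], spec.with_lam(lam))
        shrunk.details.append(out_lvl)

    restored = reconstruct(shrunk)
    px = np.clip(restored.pixels, 0.0, img.peak)
    result = Image2D(pixels=px, peak=img.peak)

    report = DenoiseReport(
        thresholds=table, rule=spec, delta=delta, wavelet=wavelet, levels=levels
    )
    if reference is not None:
        report.mse = _mse(reference, result)
        report.psnr = _psnr(report.mse)
    return result, report
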