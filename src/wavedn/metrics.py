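"""Objective image-quality metrics: MSE and PSNR on the 0-255 scale.

Both metrics are always computed on the 8-bit intensity scale: images held
internally on [0, 1] (or any other declared peak) are mapped to 0-255 by
``255 * pixels / peak`` before differencing, without integer quantization.
PSNR is referenced to the fixed peak 255,

    PSNR = 10 * log10(255**2 / MSE)   [dB]

so an MSE of 65025 (a constant full-range error) gives 0 dB and MSE -> 0
gives +inf.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["mse", "psnr", "PEAK_255"]

PEAK_255 = 255.0


def _to_255(img) -> np.ndarray:
    # accepts Image2D or a bare array already on the 0-255 scale
    peak = getattr(img, "peak", PEAK_255)
    px = np.asarray(getattr(img, "pixels", img), dtype=float)
    return px * (PEAK_255 / peak)


def mse(reference, restored) -> float:
    """Mean squared error between two images on the 0-255 scale.

    Accepts :class:`~wavedn.pipeline.Image2D` (mapped via its peak) or
    bare arrays (assumed already on 0-255).
    """
    g = _to_255(reference)
    ghat = _to_255(restored)
    if g.shape != ghat.shape:
        raise ValueError(f"image shapes differ: {g.shape} vs {ghat.shape}")
    return float(np.mean((g - ghat) ** 2))


def psnr(mse_value: float) -> float:
    """Peak signal-to-noise ratio in dB for a 0-255-scale MSE."""
    if mse_value < 0:
        raise ValueError(f"MSE must be >= 0, got {mse_value!r}")
    if mse_value == 0:
        return math.inf
    return 10.0 * math.log10(PEAK_255**2 / mse_value)
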