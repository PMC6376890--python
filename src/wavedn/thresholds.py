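"""Threshold selection: noise-scale estimation and per-level thresholds.

Two selection modes are provided.  The universal (VisuShrink) threshold

    lam = delta * sqrt(2 * ln(M*N))

grows with image size and in practice over-smooths, because every detail
coefficient in every subband is measured against the same bar.  The
level-dependent variant

    lam_j = delta * sqrt(2 * ln(M*N * (1 - alpha*j)))

lowers the bar at coarser scales (larger ``alpha*j``), reflecting that
noise energy halves per decomposition level while signal energy
concentrates.  ``j = 1`` is the finest level throughout this package; the
adjustment parameter ``alpha`` lies in (0, 1) and may vary per level.

The noise scale ``delta`` is estimated, when not supplied, by the robust
median-absolute-deviation rule on the finest diagonal detail subband,
``delta = median(|d|) / 0.6745``, which is insensitive to the sparse
signal coefficients present in that subband.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ThresholdPolicy",
    "estimate_noise_sigma",
    "universal_threshold",
    "level_threshold",
    "default_alpha_schedule",
    "thresholds_for_decomposition",
]

MAD_SCALE = 0.6745  # Phi^-1(3/4): normalizes the MAD of a Gaussian to its sigma

ORIENTATIONS = ("horizontal", "vertical", "diagonal")


def estimate_noise_sigma(diag_detail) -> float:
    """Robust noise standard deviation from finest diagonal coefficients."""
    d = np.asarray(diag_detail, dtype=float)
    if d.size == 0:
        raise ValueError("cannot estimate noise scale from an empty coefficient array")
    return float(np.median(np.abs(d)) / MAD_SCALE)


def universal_threshold(delta: float, M: int, N: int) -> float:
    """Universal threshold ``delta * sqrt(2 * ln(M*N))``."""
    if delta < 0:
        raise ValueError(f"noise scale delta must be >= 0, got {delta!r}")
    if M < 1 or N < 1 or M * N < 2:
        raise ValueError(f"image size M*N must be >= 2 for the log, got M={M}, N={N}")
    return float(delta * math.sqrt(2.0 * math.log(M * N)))


def level_threshold(delta: float, M: int, N: int, j: int, alpha: float) -> float:
    """Level-dependent threshold ``delta * sqrt(2 * ln(M*N*(1 - alpha*j)))``.

    Strictly smaller than the universal threshold for the same ``delta``,
    ``M``, ``N``, and decreasing in the product ``alpha*j``.
    """
    if delta < 0:
        raise ValueError(f"noise scale delta must be >= 0, got {delta!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"adjustment parameter alpha must lie in (0, 1), got {alpha!r}")
    if j < 1:
        raise ValueError(f"level index j must be >= 1 (1 = finest), got {j!r}")
    arg = M * N * (1.0 - alpha * j)
    if arg <= 1.0:
        raise ValueError(
            f"level-threshold guard violated: M*N*(1 - alpha*j) = {arg:.6g} <= 1 "
            f"(M={M}, N={N}, alpha={alpha}, j={j}); reduce alpha or the level count"
        )
    return float(delta * math.sqrt(2.0 * math.log(arg)))


def default_alpha_schedule(levels: int) -> List[float]:
    """Default per-level alpha values, finest (j=1) first.

    Linearly increasing from 0.1 at the finest level to 0.3 at the
    coarsest, so coarse (low-frequency) levels get a larger ``alpha`` and
    hence a smaller threshold, while fine (high-frequency) levels keep a
    larger one.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels!r}")
    if levels == 1:
        return [0.1]
    return [0.1 + 0.2 * (j - 1) / (levels - 1) for j in range(1, levels + 1)]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How to choose the threshold for each detail subband.

    Parameters
    ----------
    mode : {"universal", "level_dependent"}
        One threshold for every subband, or one per decomposition level.
    alpha : float, sequence of float, or None
        Per-level adjustment in (0, 1), finest level first.  A scalar is
        broadcast to every level; ``None`` selects the default schedule.
        Ignored in universal mode.
    delta : float or "estimate"
        Noise standard deviation in coefficient units, or ``"estimate"``
        to use the MAD rule on the finest diagonal subband.
    """

    mode: str = "level_dependent"
    alpha: Union[float, Sequence[float], None] = None
    delta: Union[float, str] = "estimate"

    def __post_init__(self) -> None:
        if self.mode not in ("universal", "level_dependent"):
            raise ValueError(
                f"threshold mode must be 'universal' or 'level_dependent', got {self.mode!r}"
            )
        if isinstance(self.delta, str):
            if self.delta != "estimate":
                raise ValueError(f"delta must be a number >= 0 or 'estimate', got {self.delta!r}")
        elif self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")
        for a in self._alpha_list():
            if not 0 < a < 1:
                raise ValueError(f"alpha values must lie in (0, 1), got {a!r}")

    def _alpha_list(self) -> List[float]:
        if self.alpha is None:
            return []
        if np.isscalar(self.alpha):
            return [float(self.alpha)]
        return [float(a) for a in self.alpha]

    def alpha_for_levels(self, levels: int) -> List[float]:
        """Resolve the alpha schedule for a ``levels``-deep decomposition."""
        if self.alpha is None:
            return default_alpha_schedule(levels)
        alphas = self._alpha_list()
        if len(alphas) == 1:
            return alphas * levels
        if len(alphas) != levels:
            raise ValueError(
                f"alpha schedule has {len(alphas)} entries but the decomposition has "
                f"{levels} levels"
            )
        return alphas

    def resolve_delta(self, finest_diagonal) -> float:
        if self.delta == "estimate":
            return estimate_noise_sigma(finest_diagonal)
        return float(self.delta)


def thresholds_for_decomposition(coeffs, policy: ThresholdPolicy) -> Dict[Tuple[int, str], float]:
    """One threshold per (level, orientation) detail subband of a CoeffSet.

    ``coeffs`` is a :class:`wavedn.pipeline.CoeffSet`; the noise scale is
    taken from the policy or estimated from its finest diagonal subband.
    Returns a dict keyed by ``(level, orientation)`` with level 1 = finest
    and orientation in {"horizontal", "vertical", "diagonal"}.
    """
    levels = coeffs.levels
    if levels < 1:
        raise ValueError("coefficient set has no detail levels")
    M, N = coeffs.image_shape
    delta = policy.resolve_delta(coeffs.details[0]["diagonal"])

    table: Dict[Tuple[int, str], float] = {}
    if policy.mode == "universal":
        lam = universal_threshold(delta, M, N)
        for j in range(1, levels + 1):
            for orient in ORIENTATIONS:
                table[(j, orient)] = lam
    else:
        alphas = policy.alpha_for_levels(levels)
        for j in range(1, levels + 1):
            lam = level_threshold(delta, M, N, j, alphas[j - 1])
            for orient in ORIENTATIONS:
                table[(j, orient)] = lam
    return table
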