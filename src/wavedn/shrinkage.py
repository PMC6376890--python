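"""Elementwise shrinkage rules applied to wavelet detail coefficients.

Four rules are provided.  Hard thresholding keeps a coefficient unchanged
when its magnitude reaches the threshold ``lam`` and zeroes it otherwise;
it preserves edges but is discontinuous at ``|w| = lam``, which produces
pseudo-Gibbs oscillations near image edges.  Soft thresholding is
continuous but subtracts ``lam`` from every surviving coefficient, a
constant bias that blurs strong features.  Semisoft thresholding ramps
linearly between an inner kill zone and an outer pass-through zone.

The improved rule blends the two classical behaviours.  With threshold
``lam`` and adjustment factor ``m`` it maps a coefficient ``w`` to::

    w - w*m / 2.1**(100*|w|/lam - 99)          for |w| > lam
    w*m / 2.1**(1 - log_100(|w|/lam))          for 0 < |w| <= lam
    0                                          for w = 0 (by continuity)

Both one-sided limits at ``|w| = lam`` equal ``sgn(w)*lam*m/2.1``; at the
default ``m = 1.05`` ( = 2.1/2) this is exactly ``lam/2``, so the rule is
continuous at the threshold.  Below the threshold the output decays to
zero like ``|w|**(1 + ln(2.1)/ln(100))``; above roughly ``2*lam`` the
exponential correction term is below 1e-12, so the rule is
indistinguishable from the identity (hard-threshold tail) while remaining
smooth through the threshold.

All rules are odd functions of ``w`` and accept scalars or numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ShrinkageSpec",
    "shrink_hard",
    "shrink_soft",
    "shrink_semisoft",
    "shrink_improved",
    "apply_shrinkage",
    "DEFAULT_M",
]

#: Default adjustment factor: 2.1/2, which makes both one-sided limits of
#: the improved rule at the threshold equal to lam/2.
DEFAULT_M = 1.05

_LN_21 = math.log(2.1)
# exponent of the sub-threshold power law: log_100(2.1) ~= 0.16111
_P_SUB = math.log(2.1) / math.log(100.0)

_RULES = ("hard", "soft", "semisoft", "improved")


def _check_lam(lam: float) -> None:
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"threshold lam must be finite and >= 0, got {lam!r}")


def shrink_hard(w, lam):
    """Hard threshold: keep ``w`` when ``|w| >= lam``, else zero."""
    _check_lam(lam)
    w = np.asarray(w, dtype=float)
    out = np.where(np.abs(w) >= lam, w, 0.0)
    return out[()] if out.ndim == 0 else out


def shrink_soft(w, lam):
    """Soft threshold: ``sgn(w) * (|w| - lam)`` when ``|w| >= lam``, else zero."""
    _check_lam(lam)
    w = np.asarray(w, dtype=float)
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return out[()] if out.ndim == 0 else out


def shrink_semisoft(w, lam1, lam2):
    """Semisoft threshold with inner kill zone and outer pass-through zone.

    Returns 0 for ``|w| <= lam1``, ``w`` for ``|w| >= lam2``, and the
    linear ramp ``sgn(w) * lam2 * (|w| - lam1) / (lam2 - lam1)`` in
    between.  The ramp meets both zone boundaries continuously.
    """
    if not (0 <= lam1 < lam2):
        raise ValueError(
            f"semisoft thresholds must satisfy 0 <= lam1 < lam2, got lam1={lam1!r}, lam2={lam2!r}"
        )
    w = np.asarray(w, dtype=float)
    a = np.abs(w)
    ramp = np.sign(w) * lam2 * (a - lam1) / (lam2 - lam1)
    out = np.where(a <= lam1, 0.0, np.where(a >= lam2, w, ramp))
    return out[()] if out.ndim == 0 else out


def shrink_improved(w, lam, m: float = DEFAULT_M):
    """Smooth shrinkage rule, continuous at the threshold for ``m = 1.05``.

    Parameters
    ----------
    w : scalar or array
        Detail coefficient(s).
    lam : float
        Threshold, strictly positive.
    m : float
        Dimensionless adjustment factor, strictly positive.  ``m = 1.05``
        makes the two branches meet at ``sgn(w)*lam/2``; larger ``m``
        shrinks sub-threshold coefficients less aggressively (and breaks
        exact continuity at the threshold).
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"threshold lam must be finite and > 0, got {lam!r}")
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"adjustment factor m must be finite and > 0, got {m!r}")
    w = np.asarray(w, dtype=float)
    a = np.abs(w)
    # |w| > lam: correction decays like 2.1**-(100|w|/lam - 99); the exponent
    # is computed in log space so large |w|/lam underflows to 0 instead of
    # overflowing.
    with np.errstate(under="ignore"):
        above = w - w * m * np.exp((99.0 - 100.0 * a / lam) * _LN_21)
        # 0 < |w| <= lam: w*m / 2.1**(1 - log_100(|w|/lam))
        #              == w * (m/2.1) * (|w|/lam)**log_100(2.1);
        # the power form is exact and extends continuously to 0 at w = 0.
        below = w * (m / 2.1) * (a / lam) ** _P_SUB
    out = np.where(a > lam, above, below)
    return out[()] if out.ndim == 0 else out


@dataclass(frozen=True)
class ShrinkageSpec:
    """A shrinkage rule plus its parameters.

    ``lam`` may be left as ``None`` in a template spec; the de-noising
    pipeline then fills it per subband from the threshold policy.  For the
    semisoft rule, ``lam1``/``lam2`` default to ``lam`` and ``2*lam`` when
    only ``lam`` is supplied.
    """

    rule: str
    lam: Optional[float] = None
    m: float = DEFAULT_M
    lam1: Optional[float] = None
    lam2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"unknown shrinkage rule {self.rule!r}; expected one of {_RULES}")
        if self.lam is not None and self.lam < 0:
            raise ValueError(f"threshold lam must be >= 0, got {self.lam!r}")
        if self.m <= 0:
            raise ValueError(f"adjustment factor m must be > 0, got {self.m!r}")
        if self.rule == "semisoft":
            lam1, lam2 = self._semisoft_bounds(allow_none=True)
            degenerate_identity = lam1 == 0 and lam2 == 0  # lam = 0: no shrinkage at all
            if (
                lam1 is not None
                and lam2 is not None
                and not degenerate_identity
                and not (0 <= lam1 < lam2)
            ):
                raise ValueError(
                    f"semisoft requires 0 <= lam1 < lam2, got lam1={lam1!r}, lam2={lam2!r}"
                )

    def _semisoft_bounds(self, allow_none: bool = False):
        lam1 = self.lam1 if self.lam1 is not None else self.lam
        lam2 = self.lam2 if self.lam2 is not None else (None if self.lam is None else 2.0 * self.lam)
        if not allow_none and (lam1 is None or lam2 is None):
            raise ValueError("semisoft spec needs lam (or explicit lam1/lam2)")
        return lam1, lam2

    def with_lam(self, lam: float) -> "ShrinkageSpec":
        """Return a copy with the threshold bound to ``lam``."""
        return replace(self, lam=float(lam))


def apply_shrinkage(coeffs, spec: ShrinkageSpec):
    """Apply ``spec`` elementwise to an array of coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    if spec.rule == "semisoft":
        lam1, lam2 = spec._semisoft_bounds()
        if lam1 == 0 and lam2 == 0:
            return coeffs.copy()
        return shrink_semisoft(coeffs, lam1, lam2)
    if spec.lam is None:
        raise ValueError("spec.lam is unbound; use with_lam() or supply lam")
    if spec.rule == "hard":
        return shrink_hard(coeffs, spec.lam)
    if spec.rule == "soft":
        return shrink_soft(coeffs, spec.lam)
    if spec.lam == 0:
        # improved rule degenerates to the identity at lam = 0
        return coeffs.copy()
    return shrink_improved(coeffs, spec.lam, spec.m)
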