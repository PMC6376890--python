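"""Run configuration: flat dotted-key YAML plus CLI-flag overrides.

The config file is a flat mapping of dotted keys to values, e.g.::

    rule: improved
    wavelet: sym4
    levels: 3
    m: 1.05
    threshold.mode: level_dependent
    threshold.alpha: [0.1, 0.2, 0.3]
    threshold.delta: estimate
    seed: 0

Unknown keys are rejected; every key has a documented default, and CLI
flags override file values.  A RunConfig round-trips losslessly through
``to_dict``/``load_config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from wavedn.shrinkage import DEFAULT_M, ShrinkageSpec
from wavedn.thresholds import ThresholdPolicy

__all__ = ["RunConfig", "load_config"]

_KEY_TO_ATTR = {
    "rule": "rule",
    "wavelet": "wavelet",
    "levels": "levels",
    "m": "m",
    "lam1": "lam1",
    "lam2": "lam2",
    "threshold.mode": "threshold_mode",
    "threshold.alpha": "threshold_alpha",
    "threshold.delta": "threshold_delta",
    "seed": "seed",
}
_ATTR_TO_KEY = {v: k for k, v in _KEY_TO_ATTR.items()}


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the de-noising pipeline with their defaults."""

    rule: str = "improved"
    wavelet: str = "sym4"
    levels: int = 3
    m: float = DEFAULT_M
    lam1: Optional[float] = None
    lam2: Optional[float] = None
    threshold_mode: str = "level_dependent"
    threshold_alpha: Union[float, Sequence[float], None] = None
    threshold_delta: Union[float, str] = "estimate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("hard", "soft", "semisoft", "improved"):
            raise ValueError(
                "config key 'rule' must be one of hard, soft, semisoft, improved; "
                f"got {self.rule!r}"
            )
        if self.levels < 1:
            raise ValueError(f"config key 'levels' must be an integer >= 1, got {self.levels!r}")
        if self.m <= 0:
            raise ValueError(f"config key 'm' must be > 0, got {self.m!r}")
        if self.threshold_mode not in ("universal", "level_dependent"):
            raise ValueError(
                "config key 'threshold.mode' must be 'universal' or 'level_dependent', "
                f"got {self.threshold_mode!r}"
            )
        alphas = (
            []
            if self.threshold_alpha is None
            else [self.threshold_alpha]
            if isinstance(self.threshold_alpha, (int, float))
            else list(self.threshold_alpha)
        )
        for a in alphas:
            if not 0 < a < 1:
                raise ValueError(
                    f"config key 'threshold.alpha' must lie in the open range (0, 1), got {a!r}"
                )
        if isinstance(self.threshold_delta, str):
            if self.threshold_delta != "estimate":
                raise ValueError(
                    "config key 'threshold.delta' must be a number >= 0 or 'estimate', "
                    f"got {self.threshold_delta!r}"
                )
        elif self.threshold_delta < 0:
            raise ValueError(
                f"config key 'threshold.delta' must be >= 0, got {self.threshold_delta!r}"
            )

    def shrinkage_spec(self) -> ShrinkageSpec:
        return ShrinkageSpec(rule=self.rule, m=self.m, lam1=self.lam1, lam2=self.lam2)

    def threshold_policy(self) -> ThresholdPolicy:
        alpha = self.threshold_alpha
        if alpha is not None and not isinstance(alpha, (int, float)):
            alpha = tuple(alpha)
        return ThresholdPolicy(mode=self.threshold_mode, alpha=alpha, delta=self.threshold_delta)

    def to_dict(self) -> Dict[str, object]:
        """Flat dotted-key representation; inverse of :func:`load_config`."""
        out = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, tuple):
                val = list(val)
            out[_ATTR_TO_KEY[f.name]] = val
        return out


def load_config(path=None, overrides: Optional[Dict[str, object]] = None) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides.

    ``overrides`` (typically CLI flags) take precedence over file values;
    keys absent from both fall back to the documented defaults.  Unknown
    keys raise with the offending key named.
    """
    merged: Dict[str, object] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a key/value mapping")
        merged.update(raw)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})

    kwargs = {}
    for key, val in merged.items():
        if key not in _KEY_TO_ATTR:
            raise ValueError(
                f"unknown config key {key!r}; allowed keys: {', '.join(sorted(_KEY_TO_ATTR))}"
            )
        kwargs[_KEY_TO_ATTR[key]] = val
    return RunConfig(**kwargs)
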