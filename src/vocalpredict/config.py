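"""Pipeline configuration.

Holds every tunable shared across stages: the 13-type call alphabet, the
contour-classifier thresholds, interval-model settings, Markov tier
multipliers, FDR levels and the master RNG seed.  All randomness in the
package flows from ``rng_seed``: the same configuration reproduces the same
outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

#: The 13-type call alphabet, in display order.
#: Har harmonic; Su step-up; Ts two-steps; Cx complex; Sd step-down;
#: Ms multiple-steps; D downward; Ch chevron; Sh short; F flat; U upward;
#: RCh reverse chevron; Amb ambiguous.
ALPHABET: tuple[str, ...] = (
    "Har", "Su", "Ts", "Cx", "Sd", "Ms", "D",
    "Ch", "Sh", "F", "U", "RCh", "Amb",
)

class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric thresholds of the contour decision tree.

    These are conventions from the USV-classification literature, not
    published values; every one is overridable.

    Parameters
    ----------
    jump_hz : float
        Minimum instantaneous frequency discontinuity (Hz) to count as a
        pitch jump.
    jump_ms : float
        Maximum time span (ms) over which a discontinuity counts as a jump.
    short_ms : float
        Calls shorter than this (ms) are classified as short (Sh).
    flat_hz : float
        Total frequency excursion (Hz) below which a jump-free call is
        flat (F).
    chevron_hz : float
        Minimum excursion (Hz) for chevron / reverse-chevron shapes.
    """

    jump_hz: float = 10_000.0
    jump_ms: float = 10.0
    short_ms: float = 10.0
    flat_hz: float = 6_000.0
    chevron_hz: float = 6_000.0


@dataclass
class PipelineConfig:
    session_duration_s: float = 300.0
    alphabet: tuple[str, ...] = ALPHABET
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    #: KDE bandwidth for the observed inter-call-interval density; None means
    #: Silverman's rule.  A float is passed through to scipy's bw_method.
    kde_bandwidth: float | None = None
    #: Step (ms) of the sign-scan grid used to bracket the density crossing.
    grid_step_ms: float = 1.0
    #: Chance-level multipliers for Markov tier thresholds tau = m / K.
    tier_multipliers: tuple[float, ...] = (1.5, 2.0, 2.5)
    fdr_levels: tuple[float, ...] = (0.05, 0.10, 0.25)
    #: "per_symbol" divides k-gram entropy by k; "joint" reports it raw.
    entropy_mode: str = "per_symbol"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.alphabet) != 13 or len(set(self.alphabet)) != 13:
            raise ConfigError("alphabet must contain exactly 13 unique labels")
        if self.session_duration_s <= 0:
            raise ConfigError("session_duration_s must be positive")
        if not all(0.0 < f < 1.0 for f in self.fdr_levels):
            raise ConfigError("fdr_levels must lie in (0, 1)")
        if self.entropy_mode not in ("per_symbol", "joint"):
            raise ConfigError("entropy_mode must be 'per_symbol' or 'joint'")
        if self.grid_step_ms <= 0:
            raise ConfigError("grid_step_ms must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = ClassifierThresholds(**raw["thresholds"])
        for key in ("alphabet", "tier_multipliers", "fdr_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("alphabet", "tier_multipliers", "fdr_levels"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def tier_thresholds(multipliers: Sequence[float] = (1.5, 2.0, 2.5),
                    n_types: int = 13) -> list[float]:
    """Chance-multiple tier thresholds ``m * (1 / n_types)``.

    With the 13-type alphabet the defaults give 0.1154, 0.1538 and 0.1923
    (4 dp), the cutoffs drawn as grey / light brown / dark brown edges in
    the transition diagrams.
    """
    if n_types <= 0:
        raise ConfigError("n_types must be positive")
    return [m / n_types for m in multipliers]
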