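"""Configuration for the synthetic-subject generator and simulation studies.

The defaults mirror the design of the delayed-estimation experiment the
simulations emulate: 28 subjects, 576 trials per load condition, 30
electrodes, 8 spatial channels with a half-sinusoid-to-the-25th tuning
profile, and unit-SD Gaussian electrode noise.  The three canonical study
configurations differ only in the two-item condition:

* :func:`simulation1` -- identical noise (SD 1) and amplitude in both
  conditions; a type-I-error calibration of the load comparison.
* :func:`simulation2` -- extra noise (SD 2) in the two-item condition.
* :func:`simulation3` -- two-item channel responses scaled by 0.9.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

__all__ = [
    "SimulationConfig",
    "simulation1",
    "simulation2",
    "simulation3",
]

_ENCODINGS = ("additive", "alternating")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic-subject generator.

    ``min_item_separation`` is the smallest allowed angular distance between
    the exact positions of the two items on a two-item trial, in degrees of
    angular position.  The default 4.6 deg corresponds to a 0.2 deg
    visual-angle separation between item centers on a circle of 4 deg radius
    (2*asin(0.1/4)).

    ``jitter_width`` is the width (degrees) of the uniform within-bin jitter
    of exact positions around the bin center; the default 45 covers the full
    wedge, 0 pins every trial to its bin center (useful for noiseless
    exactness checks).

    ``two_item_encoding`` selects how the two items drive the channels:
    ``"additive"`` sums the two items' channel responses (the default,
    concurrent-storage model); ``"alternating"`` makes each trial carry only
    one of the two items, chosen at random (a strict switching ground truth).
    """

    n_subjects: int = 28
    n_trials_per_condition: int = 576
    n_electrodes: int = 30
    n_channels: int = 8
    basis_exponent: float = 25
    noise_sd_one_item: float = 1.0
    noise_sd_two_item: float = 1.0
    amplitude_scale_two_item: float = 1.0
    min_item_separation: float = 4.6
    jitter_width: float = 45.0
    two_item_encoding: str = "additive"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials_per_condition", "n_electrodes", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.basis_exponent <= 0:
            raise ValueError("basis_exponent must be positive")
        if self.noise_sd_one_item < 0 or self.noise_sd_two_item < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.amplitude_scale_two_item <= 1:
            raise ValueError("amplitude_scale_two_item must lie in [0, 1]")
        if self.min_item_separation < 0:
            raise ValueError("min_item_separation must be non-negative")
        if not 0 <= self.jitter_width <= 45:
            raise ValueError("jitter_width must lie in [0, 45] degrees")
        n_pairs = self.n_channels**2
        if self.n_trials_per_condition % n_pairs:
            raise ValueError(
                "n_trials_per_condition must be divisible by n_channels**2 "
                f"({n_pairs}) so two-item bin pairs counterbalance exactly"
            )
        if self.n_electrodes < self.n_channels:
            raise ValueError("need at least as many electrodes as channels")
        if self.two_item_encoding not in _ENCODINGS:
            raise ValueError(f"two_item_encoding must be one of {_ENCODINGS}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def simulation1(**overrides) -> SimulationConfig:
    """Equal noise (SD 1) and equal amplitude in both load conditions."""
    return SimulationConfig(**overrides)


def simulation2(**overrides) -> SimulationConfig:
    """Noise SD 1 for one-item trials, SD 2 for two-item trials."""
    overrides.setdefault("noise_sd_two_item", 2.0)
    return SimulationConfig(**overrides)


def simulation3(**overrides) -> SimulationConfig:
    """Equal noise, two-item channel responses scaled by 0.9."""
    overrides.setdefault("amplitude_scale_two_item", 0.9)
    return SimulationConfig(**overrides)
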