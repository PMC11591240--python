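"""Synthetic catalyst-test log generator.

Emulates the structure of the real-time measurement table: a handful of
Pd/Al2O3 sachets, each reused across gassing runs, with activity that
decays per use (surface poisoning between bake-outs) and multiplicative
measurement noise.  Each drawn turnover frequency is inverted through the
ideal-gas pressure-loss relation to a dP_loss reading rounded to the
logger's 100 Pa granularity, so a generated log round-trips through
:func:`jargas.tof_estimation.turnover_frequency` up to that rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import R_GAS
from .tof_estimation import (
    JAR_VOLUME,
    T_CONVENTION,
    VALID_DURATIONS,
    CatalystTest,
)

__all__ = ["SyntheticLogSpec", "generate_test_log"]

#: pressure resolution of the control unit's logged readings, Pa
DP_GRANULARITY = 100.0


@dataclass(frozen=True)
class SyntheticLogSpec:
    """Study design of a synthetic measurement campaign.

    Defaults mirror the real campaign: a few sachets tested repeatedly at
    laboratory temperature (295-296 K), base activity of order 1.3e-5
    mol/s on first use, a per-use decay factor well below one (the
    poisoning effect seen from repeated use), and percent-level
    measurement scatter.
    """

    n_sachets: int = 3
    tests_per_sachet: int = 3
    base_tof: float = 1.3e-5          # mol/s, fresh-sachet activity
    decay: float = 0.75               # per-use activity factor, (0, 1]
    noise_sd: float = 0.05            # relative SD of multiplicative noise
    t_range: tuple = (295.15, 296.15)  # ambient K, uniform draw
    volume: float = JAR_VOLUME        # m^3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.decay <= 1):
            raise ValueError("decay factor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_sachets < 1 or self.tests_per_sachet < 1:
            raise ValueError("need at least one sachet and one test")
        if not (270.0 < self.t_range[0] <= self.t_range[1] < 320.0):
            raise ValueError("ambient temperature range out of bounds")


def generate_test_log(spec: SyntheticLogSpec) -> list:
    """Draw a reproducible catalyst-test log from the campaign spec.

    For each test the effective TOF is base * decay^(use-1) * (1 + eps),
    eps ~ N(0, noise_sd); the emitted pressure loss is TOF * dt * R *
    273.15 / V rounded to the nearest 100 Pa.  The same seed always yields
    the identical log.
    """
    rng = np.random.default_rng(spec.seed)
    tests = []
    for sachet in range(1, spec.n_sachets + 1):
        for use in range(1, spec.tests_per_sachet + 1):
            tof = spec.base_tof * spec.decay ** (use - 1)
            if spec.noise_sd > 0:
                tof *= 1.0 + rng.normal(0.0, spec.noise_sd)
            tof = max(tof, 0.0)
            dt = float(rng.choice(VALID_DURATIONS))
            t_tof = float(rng.uniform(*spec.t_range))
            dp = tof * dt * R_GAS * T_CONVENTION / spec.volume
            dp = DP_GRANULARITY * round(dp / DP_GRANULARITY)
            tests.append(
                CatalystTest(
                    dp_loss=dp,
                    duration=dt,
                    t_tof=t_tof,
                    sachet=str(sachet),
                    use_count=use,
                )
            )
    return tests
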