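"""Turnover frequencies from catalyst-test pressure loss, and the measured
Arrhenius rate curve they define.

During the catalyst test the jar is filled with anaerobic mixture and the
Pd/Al2O3 sachet recombines residual O2 with H2 into water, which
condenses; the observed pressure loss is an ideal-gas proxy for the moles
of water formed:

    dn  = dP_loss * V_jar / (R * T)
    TOF = dn / dt_cat_test        (mol/s)

The bookkeeping temperature is 273.15 K — the convention under which the
control unit's logged TOF values back-calculate exactly — although the
sensor also records the ambient temperature ``T_tof`` of each test.

A single (TOF, T_tof) measurement is extended to a rate-vs-temperature
curve ``k_system(T)`` by anchoring a straight line in (1/T, ln k) space
through the measured point and a predefined reference rate at 292 K; that
curve is exactly Arrhenius-form and serves as the target of the
extremum-seeking parameter identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import K_B, PLANCK, R_GAS

__all__ = [
    "CatalystTest",
    "TofResult",
    "ArrheniusParams",
    "RateCurve",
    "moles_formed",
    "turnover_frequency",
    "build_k_system",
    "default_grid",
    "JAR_VOLUME",
]

#: reference jar volume, m^3
JAR_VOLUME = 0.00238483

#: bookkeeping temperature of the pressure-to-moles conversion, K
T_CONVENTION = 273.15

#: allowed catalyst-test durations, s
VALID_DURATIONS = (90, 120, 180)

#: temperature resolution of all rate curves, K
GRID_STEP = 0.5


@dataclass(frozen=True)
class CatalystTest:
    """One logged catalyst test: pressure loss over a timed interval."""

    dp_loss: float      # Pa
    duration: float     # s, one of 90 / 120 / 180
    t_tof: float        # K, ambient temperature at measurement
    sachet: str = ""    # sachet label
    use_count: int = 1  # how many gassing runs this sachet has seen

    def __post_init__(self) -> None:
        if self.dp_loss < 0:
            raise ValueError("pressure loss must be >= 0")
        if self.duration not in VALID_DURATIONS:
            raise ValueError(
                f"test duration must be one of {VALID_DURATIONS}, got {self.duration}"
            )
        if not (270.0 < self.t_tof < 320.0):
            raise ValueError(f"ambient temperature {self.t_tof} K out of range")
        if self.use_count < 1:
            raise ValueError("use count starts at 1")


@dataclass(frozen=True)
class TofResult:
    """Moles of water formed and the turnover frequency."""

    delta_n: float  # mol
    tof: float      # mol/s

    def __post_init__(self) -> None:
        if self.delta_n < 0 or self.tof < 0:
            raise ValueError("moles and TOF must be >= 0")


@dataclass(frozen=True)
class ArrheniusParams:
    """The (E_act, beta) pair of k(T) = beta * exp(-E_act / (R T))."""

    e_act: float  # J/mol
    beta: float   # s^-1

    def __post_init__(self) -> None:
        if self.e_act <= 0 or self.beta <= 0:
            raise ValueError("Arrhenius parameters must be positive")

    def rate(self, temperature) -> np.ndarray:
        return self.beta * np.exp(-self.e_act / (R_GAS * np.asarray(temperature)))


@dataclass(frozen=True)
class RateCurve:
    """Rate values on a uniform temperature grid with 0.5 K resolution."""

    temperatures: np.ndarray  # K, strictly increasing, 0.5 K step
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise ValueError("grid and values must be matching 1-d arrays")
        steps = np.diff(t)
        if np.any(np.abs(steps - GRID_STEP) > 1e-9):
            raise ValueError(f"temperature grid must step uniformly by {GRID_STEP} K")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.temperatures.size)

    def same_grid(self, other: "RateCurve") -> bool:
        return self.n == other.n and np.allclose(
            self.temperatures, other.temperatures, atol=1e-9
        )


def default_grid(t_min: float = 291.15, t_max: float = 310.15) -> np.ndarray:
    """The standard 0.5 K identification grid (inclusive of both ends)."""
    n = int(round((t_max - t_min) / GRID_STEP)) + 1
    return t_min + GRID_STEP * np.arange(n)


def moles_formed(
    dp_loss: float, volume: float = JAR_VOLUME, temperature: float = T_CONVENTION
) -> float:
    """Moles of water condensed for a given jar pressure loss (ideal gas)."""
    if dp_loss < 0 or volume <= 0 or temperature <= 0:
        raise ValueError("pressure loss must be >= 0, volume and T positive")
    return dp_loss * volume / (R_GAS * temperature)


def turnover_frequency(test: CatalystTest, volume: float = JAR_VOLUME) -> TofResult:
    """TOF of one catalyst test under the 273.15 K conversion convention."""
    dn = moles_formed(test.dp_loss, volume)
    return TofResult(dn, dn / test.duration)


def build_k_system(
    tof: float,
    t_tof: float,
    k_s292: float,
    grid: np.ndarray | None = None,
    variant: str = "interpolate",
) -> RateCurve:
    """Measured-rate Arrhenius curve through (292 K, k_s292) and (T_tof, TOF).

    The default ``"interpolate"`` variant is the two-point construction in
    (1/T, ln k) space: slope = [ln k_s292 - ln TOF] / [1/292 - 1/T_tof],
    intercept fixed so the curve passes through both anchor points.  The
    ``"offset"`` variant keeps the same slope but replaces the intercept
    with ln(k_B T_tof / h), the literal printed form; it no longer passes
    through the anchors and is retained for comparison only.  Either way
    the result is exactly log-linear in 1/T, so a two-parameter Arrhenius
    model can represent it with zero residual.
    """
    if tof <= 0 or k_s292 <= 0:
        raise ValueError("rates must be positive")
    if abs(t_tof - 292.0) < 1e-9:
        raise ValueError("T_tof must differ from the 292 K reference")
    if grid is None:
        grid = default_grid()
    slope = (np.log(k_s292) - np.log(tof)) / (1.0 / 292.0 - 1.0 / t_tof)
    if variant == "interpolate":
        intercept = np.log(k_s292) - slope / 292.0
    elif variant == "offset":
        intercept = np.log(K_B * t_tof / PLANCK)
    else:
        raise ValueError(f"unknown k_system variant {variant!r}")
    values = np.exp(slope / np.asarray(grid, dtype=float) + intercept)
    return RateCurve(np.asarray(grid, dtype=float), values)
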