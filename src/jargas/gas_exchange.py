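"""Evacuation-replacement gas exchange in a sealed anaerobic jar.

The McIntosh & Fildes method removes oxygen from a culture jar stepwise:
each cycle evacuates the jar to a gauge vacuum depth ``P_vac`` below
atmospheric pressure and refills it with an anaerobic cylinder mixture
(nominally 85% N2 / 10% CO2 / 5% H2).  With ideal-gas bookkeeping the
retained gas amounts to ``(P_atm - P_vac) * V / (R * T)`` moles of the old
jar atmosphere and the refill adds ``P_vac * V / (R * T)`` moles of
cylinder gas, so the jar mole-fraction vector follows the linear recursion

    x(c+1) = [(P_atm - P_vac) * x(c) + P_vac * x_cyl] / P_atm

The control firmware reports concentrations as mass percentages: each
species' mass is its retained-plus-added moles times its molar mass, and
the reported fraction is mass over total mass.  Under this convention air
at 21% O2 (by volume) reads 4.953% O2 after one cycle with the reference
jar geometry, and roughly 0.2% after three.

Two bookkeeping variants are provided.  The default (``"molar"``) advances
the state in mole-fraction space and derives the mass readout per cycle;
it is self-consistent (identical cylinder and jar compositions are a fixed
point, a zero-depth evacuation changes nothing) and reproduces both
printed reference values.  The ``"literal"`` variant feeds the
mass-fraction readout of each cycle straight back into the next update, as
the firmware equations read when taken verbatim; it reproduces the
one-cycle value but drifts from the mole-consistent trajectory afterwards
(0.27% instead of 0.22% O2 after three cycles) and loses the fixed-point
property, so it is kept only for cross-checking against the firmware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._constants import MOLAR_MASSES, R_GAS, SPECIES_ORDER

__all__ = [
    "GasComposition",
    "SpeciesTable",
    "ExchangeConfig",
    "JarState",
    "ExchangeTrajectory",
    "run_cycle",
    "simulate",
    "partial_pressures",
    "AIR",
    "ANAEROBIC_CYLINDER",
    "reference_config",
]

_FRACTION_TOL = 1e-9


class GasExchangeError(ValueError):
    """Invalid composition, configuration or non-physical intermediate."""


@dataclass(frozen=True)
class GasComposition:
    """Dimensionless fraction per species, ordered (O2, N2, Ar, H2, CO2)."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.shape != (len(SPECIES_ORDER),):
            raise GasExchangeError(
                f"expected {len(SPECIES_ORDER)} fractions in order "
                f"{SPECIES_ORDER}, got shape {arr.shape}"
            )
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise GasExchangeError(f"fractions must be finite and >= 0, got {arr}")
        if abs(arr.sum() - 1.0) > _FRACTION_TOL:
            raise GasExchangeError(f"fractions must sum to 1, got {arr.sum()!r}")
        object.__setattr__(self, "fractions", arr)

    def __getitem__(self, species: str) -> float:
        return float(self.fractions[SPECIES_ORDER.index(species)])


@dataclass(frozen=True)
class SpeciesTable:
    """Molar mass per species (g/mol), order matching :data:`SPECIES_ORDER`."""

    masses: np.ndarray = field(default_factory=lambda: np.array(MOLAR_MASSES))

    def __post_init__(self) -> None:
        arr = np.asarray(self.masses, dtype=float)
        if arr.shape != (len(SPECIES_ORDER),) or np.any(arr <= 0):
            raise GasExchangeError(f"molar masses must be positive, got {arr}")
        object.__setattr__(self, "masses", arr)


@dataclass(frozen=True)
class ExchangeConfig:
    """Jar geometry, pressures and the refill gas.

    ``p_vac`` is the gauge vacuum depth below atmospheric pressure: the jar
    retains an absolute pressure of ``p_atm - p_vac`` after evacuation and
    the refill restores ``p_vac`` worth of cylinder gas.
    """

    cylinder: GasComposition
    p_atm: float = 101325.0     # Pa absolute
    p_vac: float = 80000.0      # Pa gauge vacuum depth
    v_jar: float = 0.00238483   # m^3
    temperature: float = 273.15  # K, molar bookkeeping temperature
    r_gas: float = R_GAS        # J mol^-1 K^-1
    species: SpeciesTable = field(default_factory=SpeciesTable)

    def __post_init__(self) -> None:
        if not (0 <= self.p_vac < self.p_atm):
            raise GasExchangeError(
                f"need 0 <= p_vac < p_atm, got p_vac={self.p_vac}, p_atm={self.p_atm}"
            )
        if self.v_jar <= 0 or self.temperature <= 0:
            raise GasExchangeError("jar volume and temperature must be positive")

    @property
    def n_retained(self) -> float:
        """Moles of jar atmosphere surviving one evacuation."""
        return (self.p_atm - self.p_vac) * self.v_jar / (self.r_gas * self.temperature)

    @property
    def n_added(self) -> float:
        """Moles of cylinder gas added by one refill."""
        return self.p_vac * self.v_jar / (self.r_gas * self.temperature)


@dataclass(frozen=True)
class JarState:
    """Jar atmosphere after ``cycle`` completed exchange cycles.

    ``composition`` is the firmware's mass-fraction readout (mass of each
    species over total mass); ``mole_fractions`` is the underlying molar
    state that drives the recursion.
    """

    cycle: int
    mole_fractions: GasComposition
    masses: np.ndarray       # g per species
    total_mass: float        # g

    def __post_init__(self) -> None:
        if self.cycle < 0:
            raise GasExchangeError("cycle index must be >= 0")
        arr = np.asarray(self.masses, dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise GasExchangeError(f"non-physical species masses {arr}")
        object.__setattr__(self, "masses", arr)

    @property
    def composition(self) -> GasComposition:
        """Mass fractions, ``masses / total_mass``."""
        return GasComposition(self.masses / self.total_mass)


@dataclass(frozen=True)
class ExchangeTrajectory:
    """Initial state plus one :class:`JarState` per completed cycle."""

    states: tuple

    def __post_init__(self) -> None:
        cycles = [s.cycle for s in self.states]
        if cycles != list(range(len(self.states))):
            raise GasExchangeError(f"cycle indices must run 0..n, got {cycles}")

    def fraction(self, species: str, kind: str = "mass") -> np.ndarray:
        """Per-cycle fraction of one species (``kind``: 'mass' or 'mole')."""
        if kind == "mass":
            return np.array([s.composition[species] for s in self.states])
        return np.array([s.mole_fractions[species] for s in self.states])


def initial_state(composition: GasComposition, config: ExchangeConfig) -> JarState:
    """Jar at ambient pressure before any exchange cycle."""
    n_total = config.p_atm * config.v_jar / (config.r_gas * config.temperature)
    masses = n_total * composition.fractions * config.species.masses
    return JarState(0, composition, masses, float(masses.sum()))


def run_cycle(
    state: JarState, config: ExchangeConfig, bookkeeping: str = "molar"
) -> JarState:
    """Advance the jar atmosphere by one evacuation-replacement cycle."""
    if bookkeeping not in ("molar", "literal"):
        raise GasExchangeError(f"unknown bookkeeping variant {bookkeeping!r}")
    masses_m = config.species.masses
    # Both variants advance the stored state vector; the literal firmware
    # recursion stores the mass readout there, the default stores mole
    # fractions.
    x = state.mole_fractions.fractions
    m_resid = config.n_retained * x * masses_m
    m_cyl = config.n_added * config.cylinder.fractions * masses_m
    masses = m_resid + m_cyl
    if np.any(~np.isfinite(masses)) or np.any(masses < 0):
        bad = SPECIES_ORDER[int(np.argmin(masses))]
        raise GasExchangeError(f"non-physical mass for species {bad} after cycle")
    total = float(masses.sum())
    if total <= 0:
        raise GasExchangeError("empty jar after cycle")
    if bookkeeping == "literal":
        x_next = masses / total
    else:
        x_next = (config.n_retained * x + config.n_added * config.cylinder.fractions)
        x_next = x_next / x_next.sum()
    return JarState(state.cycle + 1, GasComposition(x_next), masses, total)


def simulate(
    config: ExchangeConfig,
    initial: GasComposition,
    n_cycles: int,
    bookkeeping: str = "molar",
) -> ExchangeTrajectory:
    """Run ``n_cycles`` exchange cycles from an initial jar composition."""
    if n_cycles < 1:
        raise GasExchangeError(f"n_cycles must be >= 1, got {n_cycles}")
    states = [initial_state(initial, config)]
    for _ in range(n_cycles):
        states.append(run_cycle(states[-1], config, bookkeeping=bookkeeping))
    return ExchangeTrajectory(tuple(states))


def partial_pressures(
    composition: GasComposition,
    total_pressure: float,
    species: SpeciesTable | None = None,
) -> dict:
    """Per-species partial pressures (Pa) from a mass-fraction composition.

    Converts mass fractions w_i to mole fractions x_i = (w_i/M_i) / sum_j
    (w_j/M_j) and multiplies by the total pressure.  This is the bridge
    from the firmware's mass readout to the microkinetics inputs.
    """
    if total_pressure <= 0:
        raise GasExchangeError("total pressure must be positive")
    masses = (species or SpeciesTable()).masses
    moles = composition.fractions / masses
    if moles.sum() <= 0:
        raise GasExchangeError("composition has zero total content")
    x = moles / moles.sum()
    return dict(zip(SPECIES_ORDER, x * total_pressure))


#: Laboratory air by volume, as used for the jar's initial atmosphere.
AIR = GasComposition(np.array([0.21, 0.78, 0.01, 0.0, 0.0]))

#: GC/MS-measured anaerobic cylinder mixture (volume fractions).
ANAEROBIC_CYLINDER = GasComposition(np.array([0.0, 0.84404, 0.0, 0.04916, 0.1068]))


def reference_config() -> ExchangeConfig:
    """The reference jar: 2.385 L, 80 kPa vacuum depth, anaerobic refill."""
    return ExchangeConfig(cylinder=ANAEROBIC_CYLINDER)
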