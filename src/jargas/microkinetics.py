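"""Mean-field microkinetics of H2 oxidation on Pd(111).

The Pd/Al2O3 sachet in a jar gassing system removes residual O2 by
recombining it with H2 from the refill gas.  The surface chemistry follows
a six-step Langmuir-Hinshelwood mechanism on the Pd(111) facet:

    O2(g) + 2*  <->  2 O*
    H2(g) + 2*  <->  2 H*
    H* + O*     <->  OH* + *
    H* + OH*    <->  H2O* + *
    2 OH*       <->  H2O* + O*
    H2O*         ->  H2O(g) + *

Adsorption is collision-limited (Hertz-Knudsen), desorption of the
diatomics gains 2D translation and free rotation in the transition state,
and the surface steps follow transition-state theory with DFT-derived
pre-exponential factors and barriers.  Coverages are treated as well-mixed
mean fields; the model integrates the coverage balance from an empty
surface to steady state and reports per-step rates, turnover frequency
(TOF, per site per second), Campbell degree-of-rate-control (DRC)
coefficients, apparent activation energy and gas-phase reaction orders.

All energies are molar (J/mol) and enter rate laws through exp(-E/(R T)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

import scipy.constants as _sc

from ._constants import AMU, C_CM, K_B, N_AV, PLANCK

R = _sc.R  # exact molar gas constant for the statistical-mechanics layer

__all__ = [
    "VibrationalSpec",
    "AdsorptionParams",
    "SurfaceStepParams",
    "ThermoConstraint",
    "Step",
    "Mechanism",
    "OperatingConditions",
    "SteadyState",
    "SensitivityResult",
    "SiteAreaInputs",
    "vib_entropy",
    "tst_prefactor",
    "hertz_knudsen_ads",
    "desorption_rate",
    "site_area",
    "build_reference_model",
    "steady_state",
    "degree_of_rate_control",
    "apparent_ea",
    "reaction_orders",
    "REFERENCE_PARTIAL_PRESSURES",
]


class MechanismError(ValueError):
    """Unbalanced or otherwise invalid mechanism definition."""


class ConvergenceError(RuntimeError):
    """Steady-state solve failed; carries the residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


# --------------------------------------------------------------------------
# elementary-step parameter containers and rate-constant formulas


@dataclass(frozen=True)
class VibrationalSpec:
    """Harmonic vibrational frequencies of a surface species.

    Frequencies are stored in s^-1; ``from_wavenumbers`` accepts cm^-1.
    """

    frequencies: tuple

    def __post_init__(self) -> None:
        freqs = tuple(float(v) for v in self.frequencies)
        if any(v <= 0 for v in freqs):
            raise ValueError("vibrational frequencies must be positive")
        object.__setattr__(self, "frequencies", freqs)

    @classmethod
    def from_wavenumbers(cls, wavenumbers) -> "VibrationalSpec":
        return cls(tuple(w * C_CM for w in wavenumbers))

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


def vib_entropy(spec: VibrationalSpec, temperature: float) -> float:
    """Harmonic vibrational entropy in units of k_B.

    S_vib/k_B = sum_i [ x_i/(exp(x_i)-1) - ln(1-exp(-x_i)) ],
    x_i = h v_i / (k_B T).  High frequencies contribute nothing; an empty
    spectrum returns zero with a warning.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if spec.n_modes == 0:
        warnings.warn("empty vibrational spectrum: entropy taken as zero")
        return 0.0
    x = PLANCK * np.asarray(spec.frequencies) / (K_B * temperature)
    ex = np.exp(-x)  # overflow-safe form of x/(e^x - 1) - ln(1 - e^-x)
    return float(np.sum(x * ex / (1.0 - ex) - np.log1p(-ex)))


def tst_prefactor(entropy_kb: float, temperature: float) -> float:
    """Transition-state-theory prefactor (s^-1), (k_B T / h) exp(dS/k_B)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return K_B * temperature / PLANCK * np.exp(entropy_kb)


@dataclass(frozen=True)
class AdsorptionParams:
    """Hertz-Knudsen parameters for dissociative adsorption/desorption.

    ``mass_amu`` is the molecular mass in atomic mass units, ``sticking``
    the sticking coefficient, ``site_area`` the surface site area (m^2),
    ``e_ads``/``e_des`` the adsorption barrier and desorption energy
    (J/mol; adsorption is non-activated by default), ``theta_rot`` the
    rotational temperature (K) and ``sigma`` the symmetry number.
    """

    mass_amu: float
    sticking: float
    site_area: float
    e_des: float
    theta_rot: float
    sigma: int
    e_ads: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_amu <= 0 or self.site_area <= 0:
            raise ValueError("mass and site area must be positive")
        if not (0 <= self.sticking <= 1):
            raise ValueError("sticking coefficient must lie in [0, 1]")
        if self.e_des < 0:
            raise ValueError("desorption energy must be >= 0")


def hertz_knudsen_ads(p: AdsorptionParams, temperature: float) -> float:
    """Adsorption rate constant (Pa^-1 s^-1 per site pair).

    k_ads = A_site S / sqrt(2 pi m k_B T) * exp(-E_ads / (R T)).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = p.mass_amu * AMU
    flux = p.site_area * p.sticking / np.sqrt(2 * np.pi * m * K_B * temperature)
    return flux * np.exp(-p.e_ads / (R * temperature))


def desorption_rate(p: AdsorptionParams, temperature: float) -> float:
    """Desorption rate constant (s^-1) of an adsorbed diatomic.

    k_des = A_site 2 pi m k_B^2 T^3 / (h^3 sigma theta_rot)
            * exp(-E_des / (R T))

    i.e. attempt frequency k_B T / h times the 2D translational partition
    function (2 pi m k_B T / h^2) A_site and the free-rotor partition
    function T / (sigma theta_rot) gained in the transition state.  At
    E_des = 0 the constant scales as T^3.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = p.mass_amu * AMU
    pref = (
        p.site_area * 2 * np.pi * m * K_B**2 * temperature**3
        / (PLANCK**3 * p.sigma * p.theta_rot)
    )
    return pref * np.exp(-p.e_des / (R * temperature))


@dataclass(frozen=True)
class SurfaceStepParams:
    """TST parameters of a reversible surface step (``beta_b = 0`` marks an
    irreversible one)."""

    beta_f: float
    e_f: float
    beta_b: float
    e_b: float

    def __post_init__(self) -> None:
        if self.beta_f <= 0 or self.beta_b < 0:
            raise ValueError("prefactors must be positive (beta_b may be 0)")
        if self.e_f < 0 or self.e_b < 0:
            raise ValueError("barriers must be >= 0")

    def k_forward(self, temperature: float) -> float:
        return self.beta_f * np.exp(-self.e_f / (R * temperature))

    def k_backward(self, temperature: float) -> float:
        if self.beta_b == 0:
            return 0.0
        return self.beta_b * np.exp(-self.e_b / (R * temperature))


@dataclass(frozen=True)
class ThermoConstraint:
    """Standard reaction entropy/enthalpy and the equilibrium constant they
    imply, K = exp(dS/R) exp(-dH/(R T))."""

    delta_s: float  # J mol^-1 K^-1
    delta_h: float  # J/mol

    def k_equ(self, temperature: float) -> float:
        return float(
            np.exp(self.delta_s / R) * np.exp(-self.delta_h / (R * temperature))
        )


# --------------------------------------------------------------------------
# mechanism as a mass-action reaction network over surface + gas species

#: element composition (H, O) and site count of the recognised species
_SPECIES = {
    "*": (0, 0, 1),
    "O*": (0, 1, 1),
    "H*": (1, 0, 1),
    "OH*": (1, 1, 1),
    "H2O*": (2, 1, 1),
    "O2": (0, 2, 0),
    "H2": (2, 0, 0),
    "H2O": (2, 1, 0),
}

SURFACE_SPECIES = ("O*", "H*", "OH*", "H2O*")  # vacancy closes the balance
GAS_SPECIES = ("O2", "H2", "H2O")


@dataclass(frozen=True)
class Step:
    """One elementary step: reactants/products with stoichiometric counts,
    and forward/backward rate-constant callables of temperature."""

    name: str
    reactants: dict
    products: dict
    k_forward: object   # callable T -> rate constant
    k_backward: object  # callable T -> rate constant (None = irreversible)

    def net_stoich(self, species: str) -> int:
        return self.products.get(species, 0) - self.reactants.get(species, 0)

    @property
    def reversible(self) -> bool:
        return self.k_backward is not None


def _check_balance(step: Step) -> None:
    for axis, label in ((0, "H"), (1, "O"), (2, "surface sites")):
        lhs = sum(n * _SPECIES[s][axis] for s, n in step.reactants.items())
        rhs = sum(n * _SPECIES[s][axis] for s, n in step.products.items())
        if lhs != rhs:
            raise MechanismError(
                f"step {step.name!r} does not conserve {label}: {lhs} vs {rhs}"
            )


@dataclass(frozen=True)
class Mechanism:
    """Ordered elementary steps over the recognised surface/gas species."""

    steps: tuple

    def __post_init__(self) -> None:
        for step in self.steps:
            unknown = (set(step.reactants) | set(step.products)) - set(_SPECIES)
            if unknown:
                raise MechanismError(f"unknown species {unknown} in {step.name!r}")
            _check_balance(step)

    @property
    def step_names(self) -> tuple:
        return tuple(s.name for s in self.steps)

    def scaled(self, step_name: str, factor: float) -> "Mechanism":
        """Copy with one step's forward and backward constants scaled
        together, leaving its equilibrium constant unchanged."""
        new = []
        for s in self.steps:
            if s.name == step_name:
                kf, kb = s.k_forward, s.k_backward
                new.append(
                    Step(
                        s.name,
                        s.reactants,
                        s.products,
                        (lambda T, kf=kf: factor * kf(T)),
                        None if kb is None else (lambda T, kb=kb: factor * kb(T)),
                    )
                )
            else:
                new.append(s)
        if len([s for s in new if s.name == step_name]) != 1:
            raise MechanismError(f"no unique step named {step_name!r}")
        return Mechanism(tuple(new))


@dataclass(frozen=True)
class OperatingConditions:
    """Reactor temperature (K) and constant gas partial pressures (Pa)."""

    temperature: float
    pressures: dict

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if any(p < 0 for p in self.pressures.values()):
            raise ValueError("partial pressures must be >= 0")

    def pressure(self, gas: str) -> float:
        return float(self.pressures.get(gas, 0.0))

    def with_pressure(self, gas: str, value: float) -> "OperatingConditions":
        p = dict(self.pressures)
        p[gas] = value
        return OperatingConditions(self.temperature, p)

    def with_temperature(self, temperature: float) -> "OperatingConditions":
        return OperatingConditions(temperature, dict(self.pressures))


@dataclass(frozen=True)
class SteadyState:
    """Converged coverages, per-step net rates (s^-1 per site) and TOF."""

    coverages: dict          # surface species (incl. "*") -> coverage
    step_rates: dict         # step name -> net rate
    tof: float               # net H2O formation rate, s^-1 per site

    @property
    def dominant_species(self) -> str:
        return max(self.coverages, key=self.coverages.get)


@dataclass(frozen=True)
class SensitivityResult:
    """Campbell DRC coefficients, apparent activation energy and orders."""

    drc: dict = field(default_factory=dict)
    apparent_ea: np.ndarray | None = None
    temperatures: np.ndarray | None = None
    orders: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SiteAreaInputs:
    """Inputs of the crystallite-geometry site-area estimate."""

    crystallite_size: float  # m
    atomic_radius: float     # m
    atomic_mass: float       # g/mol
    bulk_density: float      # g/cm^3
    n_avogadro: float = N_AV

    def __post_init__(self) -> None:
        for v in (
            self.crystallite_size,
            self.atomic_radius,
            self.atomic_mass,
            self.bulk_density,
            self.n_avogadro,
        ):
            if v <= 0:
                raise ValueError("all site-area inputs must be positive")


def site_area(inp: SiteAreaInputs) -> float:
    """Surface site area estimate A = 0.6 d m / (rho N_Av L).

    Unit convention: ``atomic_radius`` and ``crystallite_size`` in m,
    ``atomic_mass`` in g/mol, ``bulk_density`` in g/cm^3; the result is
    quoted in m^2.  The convention is heuristic (the published reference
    value 4.37e-26 m^2 for Pd(111) is used for the reference model rather
    than this estimate, which lands ~25% below it for the measured
    crystallite size).
    """
    return (
        0.6 * inp.atomic_radius * inp.atomic_mass
        / (inp.bulk_density * inp.n_avogadro * inp.crystallite_size)
    )


# --------------------------------------------------------------------------
# the Pd(111) reference model (published TST / Hertz-Knudsen parameters)

#: site area used throughout the reference model, m^2
PD111_SITE_AREA = 4.37e-26

#: adsorption/desorption parameters of the two dissociative steps
PD111_O2 = AdsorptionParams(
    mass_amu=32.0, sticking=1.0, site_area=PD111_SITE_AREA,
    e_des=77e3, theta_rot=2.1, sigma=2,
)
PD111_H2 = AdsorptionParams(
    mass_amu=2.0, sticking=0.5, site_area=PD111_SITE_AREA,
    e_des=96e3, theta_rot=87.9, sigma=2,
)

#: TST parameters of the four surface steps, in mechanism order
PD111_SURFACE_STEPS = {
    "H*+O*<->OH*+*": SurfaceStepParams(1.228e13, 94570.0, 1.66e13, 97369.0),
    "H*+OH*<->H2O*+*": SurfaceStepParams(1.03e13, 47285.0, 1.03e13, 95535.0),
    "2OH*<->H2O*+O*": SurfaceStepParams(4.97e13, 4825.0, 5.166e13, 20265.0),
    "H2O*->H2O+*": SurfaceStepParams(7.288e15, 43425.0, 0.0, 0.0),
}

#: normalized catalyst-test partial pressures (O2, N2, Ar, H2, CO2) recorded
#: by the control unit during the catalyst-test fill
REFERENCE_PARTIAL_PRESSURES = {
    "O2": 0.047, "N2": 0.834, "Ar": 0.00223, "H2": 0.0388, "CO2": 0.0776,
}


def reference_conditions(
    temperature: float = 295.15, total_pressure: float = 101325.0
) -> OperatingConditions:
    """Catalyst-test gas atmosphere at the given temperature."""
    pressures = {
        g: REFERENCE_PARTIAL_PRESSURES[g] * total_pressure for g in GAS_SPECIES[:2]
    }
    pressures["H2O"] = 0.0
    return OperatingConditions(temperature, pressures)


def build_reference_model(params: dict | None = None) -> Mechanism:
    """Assemble the six-step Pd(111) mechanism.

    ``params`` may override the packaged parameter set; it uses the same
    layout as :func:`jargas.io.load_mechanism_params` returns.
    """
    if params is None:
        from .io import load_mechanism_params

        params = load_mechanism_params()
    o2 = params["adsorption"]["O2"]
    h2 = params["adsorption"]["H2"]
    surf = params["surface"]

    def ads_pair(p: AdsorptionParams):
        return (
            lambda T, p=p: hertz_knudsen_ads(p, T),
            lambda T, p=p: desorption_rate(p, T),
        )

    def tst_pair(sp: SurfaceStepParams):
        kb = None if sp.beta_b == 0 else (lambda T, sp=sp: sp.k_backward(T))
        return (lambda T, sp=sp: sp.k_forward(T)), kb

    kf1, kb1 = ads_pair(o2)
    kf2, kb2 = ads_pair(h2)
    kf3, kb3 = tst_pair(surf["H*+O*<->OH*+*"])
    kf4, kb4 = tst_pair(surf["H*+OH*<->H2O*+*"])
    kf5, kb5 = tst_pair(surf["2OH*<->H2O*+O*"])
    kf6, kb6 = tst_pair(surf["H2O*->H2O+*"])
    return Mechanism(
        (
            Step("O2+2*<->2O*", {"O2": 1, "*": 2}, {"O*": 2}, kf1, kb1),
            Step("H2+2*<->2H*", {"H2": 1, "*": 2}, {"H*": 2}, kf2, kb2),
            Step("H*+O*<->OH*+*", {"H*": 1, "O*": 1}, {"OH*": 1, "*": 1}, kf3, kb3),
            Step("H*+OH*<->H2O*+*", {"H*": 1, "OH*": 1}, {"H2O*": 1, "*": 1}, kf4, kb4),
            Step("2OH*<->H2O*+O*", {"OH*": 2}, {"H2O*": 1, "O*": 1}, kf5, kb5),
            Step("H2O*->H2O+*", {"H2O*": 1}, {"H2O": 1, "*": 1}, kf6, None),
        )
    )


def default_params() -> dict:
    """In-code copy of the packaged Pd(111) parameter set."""
    return {
        "adsorption": {"O2": PD111_O2, "H2": PD111_H2},
        "surface": dict(PD111_SURFACE_STEPS),
    }


# --------------------------------------------------------------------------
# steady-state solution and sensitivity analysis


def _step_rate(step: Step, theta: dict, cond: OperatingConditions, T: float):
    fwd = step.k_forward(T)
    for sp, n in step.reactants.items():
        conc = cond.pressure(sp) if sp in GAS_SPECIES else theta[sp]
        fwd *= conc**n
    bwd = 0.0
    if step.reversible:
        bwd = step.k_backward(T)
        for sp, n in step.products.items():
            conc = cond.pressure(sp) if sp in GAS_SPECIES else theta[sp]
            bwd *= conc**n
    return fwd - bwd


def _coverage_rhs(y: np.ndarray, model: Mechanism, cond: OperatingConditions):
    theta = dict(zip(SURFACE_SPECIES, y))
    theta["*"] = 1.0 - float(np.sum(y))
    rates = [_step_rate(s, theta, cond, cond.temperature) for s in model.steps]
    dydt = np.zeros_like(y)
    for r, step in zip(rates, model.steps):
        for i, sp in enumerate(SURFACE_SPECIES):
            nu = step.net_stoich(sp)
            if nu:
                dydt[i] += nu * r
    return dydt, rates


def steady_state(
    model: Mechanism,
    cond: OperatingConditions,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    t_final: float = 1e6,
    deriv_tol: float = 1e-10,
) -> SteadyState:
    """Integrate the coverage balance from an empty surface to steady state.

    The vacancy coverage closes the site balance exactly (theta_* = 1 -
    sum theta_i).  A stiff integrator relaxes the system until the largest
    coverage derivative falls below ``deriv_tol`` s^-1 (or ``t_final`` is
    reached), then a Newton polish on the algebraic system sharpens the
    root.  Raises :class:`ConvergenceError` if the residual stays large.
    """

    def rhs(t, y):
        return _coverage_rhs(y, model, cond)[0]

    y0 = np.zeros(len(SURFACE_SPECIES))
    sol = solve_ivp(rhs, (0.0, t_final), y0, method="LSODA", rtol=rtol, atol=atol)
    y = sol.y[:, -1]
    res = float(np.max(np.abs(rhs(0.0, y))))
    polish = root(lambda v: rhs(0.0, v), y, method="hybr", tol=1e-13)
    if polish.success and np.all(polish.x > -1e-12) and polish.x.sum() < 1 + 1e-9:
        y = np.clip(polish.x, 0.0, None)
        res = float(np.max(np.abs(rhs(0.0, y))))
    if res > deriv_tol:
        raise ConvergenceError("steady state not reached", res)

    theta = dict(zip(SURFACE_SPECIES, y))
    theta["*"] = 1.0 - float(np.sum(y))
    rates = [_step_rate(s, theta, cond, cond.temperature) for s in model.steps]
    tof = sum(
        r * s.net_stoich("H2O") for r, s in zip(rates, model.steps)
    )
    return SteadyState(theta, dict(zip(model.step_names, rates)), float(tof))


def gas_consumption(state: SteadyState, model: Mechanism, gas: str) -> float:
    """Net consumption rate of a gas species at steady state (s^-1/site)."""
    return -sum(
        state.step_rates[s.name] * s.net_stoich(gas) for s in model.steps
    )


def degree_of_rate_control(
    model: Mechanism,
    cond: OperatingConditions,
    *,
    delta: float = 0.01,
) -> dict:
    """Campbell DRC coefficients X_s = dln(TOF)/dln(k_s) at fixed K_equ.

    Forward and backward constants of each step are perturbed together by
    a factor (1 +/- delta) and the TOF response is differenced centrally.
    The coefficients obey the sum rule sum_s X_s = 1.
    """
    drc = {}
    for name in model.step_names:
        tof_p = steady_state(model.scaled(name, 1 + delta), cond).tof
        tof_m = steady_state(model.scaled(name, 1 - delta), cond).tof
        drc[name] = float(
            (np.log(tof_p) - np.log(tof_m))
            / (np.log(1 + delta) - np.log(1 - delta))
        )
    return drc


def apparent_ea(
    model: Mechanism, cond: OperatingConditions, temperatures: np.ndarray
) -> SensitivityResult:
    """Apparent activation energy -R dln(TOF)/d(1/T) on a temperature grid
    (central differences; one-sided at the grid ends)."""
    temps = np.asarray(temperatures, dtype=float)
    if temps.size < 3:
        raise ValueError("need at least 3 grid points")
    if temps.min() < 273.0 or temps.max() > 320.0:
        raise ValueError("temperature grid must lie within 273-320 K")
    tofs = np.array(
        [steady_state(model, cond.with_temperature(t)).tof for t in temps]
    )
    ea = -R * np.gradient(np.log(tofs), 1.0 / temps)
    return SensitivityResult(apparent_ea=ea, temperatures=temps)


def reaction_orders(
    model: Mechanism,
    cond: OperatingConditions,
    gases: tuple = ("O2", "H2"),
    *,
    delta: float = 0.02,
) -> dict:
    """Reaction orders n = dln(TOF)/dln(p) by central finite differences."""
    orders = {}
    for gas in gases:
        p0 = cond.pressure(gas)
        if p0 <= 0:
            raise ValueError(f"cannot take order in {gas}: zero base pressure")
        tof_p = steady_state(model, cond.with_pressure(gas, p0 * (1 + delta))).tof
        tof_m = steady_state(model, cond.with_pressure(gas, p0 * (1 - delta))).tof
        orders[gas] = float(
            (np.log(tof_p) - np.log(tof_m))
            / (np.log(1 + delta) - np.log(1 - delta))
        )
    return orders
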