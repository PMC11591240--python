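"""Discrete sinusoid-perturbation extremum seeking for Arrhenius parameters.

The optimizer superimposes a cosine dither on each parameter, watches the
scalar cost respond, and demodulates that response to estimate and descend
the gradient without a model of the cost surface.  Per iteration n, with
cost J evaluated at the dithered parameters and a first-order bias filter
xi:

    xi(n)          = -h xi(n-1) + J
    theta_hat(n+1) = theta_hat(n) - gamma_t alpha_t cos(w n) [J + h xi(n)]
    theta(n+1)     = theta_hat(n+1) + alpha_t cos(w (n+1))

Both parameters share the dither frequency w = a pi (rad/iteration, 0 < a
< 1) and the scalar cost, but carry their own dither amplitude alpha_t and
gain gamma_t.  The cost demodulated at phase cos(w n) is the one evaluated
at the point whose dither phase was cos(w n): pairing the dither with the
cost of an earlier iterate shifts the demodulation phase by w per step of
delay, which for a = 0.8 flips the sign of the estimated gradient and
turns the scheme into an ascent.  The loop is fully deterministic.

The cost is the root-mean-square error between the measured rate curve
``k_system`` and the Arrhenius model curve on a shared 0.5 K temperature
grid.  Because ``k_system`` is itself exactly log-linear in 1/T, zero cost
is attainable; the (E_act, beta) pair that achieves a given small cost is
not unique (Arrhenius compensation over a narrow temperature window), so
convergence is judged on the curve, not on the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._constants import R_GAS
from .tof_estimation import ArrheniusParams, RateCurve

__all__ = ["ESConfig", "ESState", "ESResult", "rmse_cost", "es_step", "fit_arrhenius"]


class ESError(RuntimeError):
    """Non-finite cost or diverging optimization."""


@dataclass(frozen=True)
class ESConfig:
    """Extremum-seeking hyperparameters.

    ``alpha`` and ``gamma`` hold one dither amplitude / estimation gain per
    parameter, in the parameter's own (raw) units.
    """

    alpha: tuple          # dither amplitude per parameter
    gamma: tuple          # estimation gain per parameter
    h: float = 0.5        # high-pass filter denominator, (0, 1)
    a: float = 0.8        # frequency factor, w = a*pi, (0, 1)
    xi0: float = 0.0135   # initial filter bias
    epsilon: float = 1e-4  # cost termination threshold
    max_iter: int = 200_000

    def __post_init__(self) -> None:
        if not (0 < self.h < 1):
            raise ValueError("h must lie strictly inside (0, 1)")
        if not (0 < self.a < 1):
            raise ValueError("a must lie strictly inside (0, 1), w = a*pi")
        if self.epsilon <= 0:
            raise ValueError("termination threshold must be positive")
        if len(self.alpha) != len(self.gamma):
            raise ValueError("alpha and gamma must have one entry per parameter")
        object.__setattr__(self, "alpha", tuple(float(x) for x in self.alpha))
        object.__setattr__(self, "gamma", tuple(float(x) for x in self.gamma))

    @property
    def omega(self) -> float:
        return self.a * np.pi

    @property
    def n_params(self) -> int:
        return len(self.alpha)


#: hyperparameters of the published Test-4 identification run, for the
#: parameter vector (E_act, beta)
TEST4_ES_CONFIG = ESConfig(alpha=(20.0, 12e3), gamma=(1000.0, 15e8))


@dataclass(frozen=True)
class ESState:
    """Optimizer state after iteration ``n``."""

    n: int
    theta_hat: np.ndarray     # unperturbed estimate per parameter
    xi: np.ndarray            # filter bias per parameter
    cost_history: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_hat", np.asarray(self.theta_hat, float))
        object.__setattr__(self, "xi", np.asarray(self.xi, float))

    def theta(self, config: ESConfig) -> np.ndarray:
        """Dithered parameter vector theta = theta_hat + alpha cos(w n)."""
        return self.theta_hat + np.asarray(config.alpha) * np.cos(
            config.omega * self.n
        )


@dataclass(frozen=True)
class ESResult:
    """Outcome of a fit: final parameters, convergence flag, cost trace."""

    params: ArrheniusParams
    iterations: int
    final_cost: float
    converged: bool
    cost_trace: np.ndarray = field(repr=False, default=None)


def initial_state(theta0, config: ESConfig) -> ESState:
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.shape != (config.n_params,):
        raise ValueError("theta0 length must match the config's parameter count")
    return ESState(0, theta0, np.full(config.n_params, config.xi0))


def rmse_cost(k_system: RateCurve, k_model: RateCurve) -> float:
    """Root-mean-square difference of two rate curves on a shared grid."""
    if not k_system.same_grid(k_model):
        raise ValueError("rate curves must share one temperature grid")
    return float(np.sqrt(np.mean((k_system.values - k_model.values) ** 2)))


def _es_update(theta_hat, xi, j_new: float, n: int, config: ESConfig):
    """The bias-filter and demodulated-gradient update shared by
    :func:`es_step` and :func:`fit_arrhenius`."""
    alpha = np.asarray(config.alpha)
    gamma = np.asarray(config.gamma)
    cos_n = np.cos(config.omega * n)
    xi_new = -config.h * xi + j_new
    theta_new = theta_hat - gamma * alpha * cos_n * (j_new + config.h * xi_new)
    return theta_new, xi_new


def es_step(state: ESState, j_new: float, config: ESConfig) -> ESState:
    """One extremum-seeking update given the cost at the current dithered
    parameters."""
    if not np.isfinite(j_new):
        raise ESError(f"non-finite cost {j_new!r} at iteration {state.n}")
    theta_hat, xi = _es_update(state.theta_hat, state.xi, j_new, state.n, config)
    return ESState(
        state.n + 1, theta_hat, xi, state.cost_history + (float(j_new),)
    )


def fit_arrhenius(
    k_system: RateCurve,
    init: ArrheniusParams,
    config: ESConfig = TEST4_ES_CONFIG,
) -> ESResult:
    """Identify (E_act, beta) by extremum seeking against a measured curve.

    Each iteration evaluates the Arrhenius model at the dithered parameter
    vector on the target's grid, computes the RMSE cost, and applies
    :func:`es_step`; the loop stops when the cost reaches the termination
    threshold or the iteration cap.  Raises :class:`ESError` if the cost
    exceeds 1e6 times its initial value.
    """
    if config.n_params != 2:
        raise ValueError("Arrhenius identification needs a 2-parameter config")
    temps = k_system.temperatures
    alpha = np.asarray(config.alpha)
    theta_hat = np.array([init.e_act, init.beta])
    xi = np.full(2, config.xi0)
    trace = np.empty(config.max_iter)
    j0 = None
    for n in range(config.max_iter):
        e_act, beta = theta_hat + alpha * np.cos(config.omega * n)
        k_model = beta * np.exp(-e_act / (R_GAS * temps))
        j = float(np.sqrt(np.mean((k_system.values - k_model) ** 2)))
        if not np.isfinite(j):
            raise ESError(f"non-finite cost at iteration {n}")
        trace[n] = j
        if j0 is None:
            j0 = j if j > 0 else 1.0
        if j > 1e6 * j0:
            raise ESError(
                f"diverged at iteration {n}: cost {j:.3e} from {j0:.3e}"
            )
        if j <= config.epsilon:
            return ESResult(
                ArrheniusParams(float(theta_hat[0]), float(theta_hat[1])),
                n + 1,
                j,
                True,
                trace[: n + 1].copy(),
            )
        theta_hat, xi = _es_update(theta_hat, xi, j, n, config)
    return ESResult(
        ArrheniusParams(float(theta_hat[0]), float(theta_hat[1])),
        config.max_iter,
        float(trace[-1]),
        False,
        trace.copy(),
    )
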