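"""Characteristic-curve dynamics of the growth-augmented continuity equation.

Along a characteristic dx/dt = v(x, t) of

    d rho/dt + div(v rho) = g rho,

the log density obeys d(ln rho)/dt = g - div(v), the accumulated log mass
factor is the integral of g, and the transport-plus-growth cost density is
(|v|^2 + alpha g^2) e^{int g ds}.  The augmented state bundles these four
quantities and is integrated either with an adaptive Dormand-Prince 4(5)
solver (inference and analysis; scipy's RK45) or with a fixed-step
fourth-order Runge-Kutta scheme expressed in autodiff-graph operations so
that training gradients flow through the discretized solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _autodiff as ad
from ._autodiff import Tensor
from .fields import FieldPair


@dataclass
class AugmentedState:
    """State carried along characteristics: positions plus density bookkeeping.

    ``lnrho`` is the log density along each curve, ``logmass`` the integral
    of g (so e^{logmass} is the mass factor), ``cost`` the accumulated
    Wasserstein-Fisher-Rao cost integrand.
    """

    x: np.ndarray
    lnrho: np.ndarray
    logmass: np.ndarray
    cost: np.ndarray

    @classmethod
    def initial(cls, x0: np.ndarray, lnrho0: np.ndarray | None = None) -> "AugmentedState":
        x0 = np.atleast_2d(np.asarray(x0, dtype=np.float64))
        n = x0.shape[0]
        if lnrho0 is None:
            lnrho0 = np.zeros(n)
        return cls(x0, np.asarray(lnrho0, dtype=np.float64), np.zeros(n), np.zeros(n))

    def pack(self) -> np.ndarray:
        return np.hstack([
            self.x, self.lnrho[:, None], self.logmass[:, None], self.cost[:, None]
        ]).ravel()

    @classmethod
    def unpack(cls, y: np.ndarray, n: int, d: int) -> "AugmentedState":
        m = y.reshape(n, d + 3)
        return cls(m[:, :d].copy(), m[:, d], m[:, d + 1], m[:, d + 2])


# ------------------------------------------------------- derivative access
def divergence(field: FieldPair, x: np.ndarray, t: float) -> np.ndarray:
    """Exact div(v) at (x, t) as the trace of the analytic Jacobian."""
    return field.divergence(x, t)


def jacobian(field: FieldPair, x: np.ndarray, t: float) -> np.ndarray:
    """J_ij = dv_i/dx_j at (x, t)."""
    return field.jacobian(x, t)


def growth_gradient(field: FieldPair, x: np.ndarray, t: float) -> np.ndarray:
    """grad_x g at (x, t)."""
    return field.growth_gradient(x, t)


def augmented_rhs(field: FieldPair, state: AugmentedState, t: float,
                  alpha: float = 1.0) -> AugmentedState:
    """Time derivative of the augmented state (numpy path)."""
    if not (np.all(np.isfinite(state.x)) and np.all(np.isfinite(state.lnrho))
            and np.all(np.isfinite(state.logmass)) and np.all(np.isfinite(state.cost))):
        raise ValueError("non-finite augmented state")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    v = field.velocity(state.x, t)
    g = field.growth(state.x, t)
    div = field.divergence(state.x, t)
    cost_rate = ((v * v).sum(axis=1) + alpha * g * g) * np.exp(state.logmass)
    return AugmentedState(v, g - div, g, cost_rate)


def integrate(
    field: FieldPair,
    state0: AugmentedState,
    t0: float,
    t1: float,
    alpha: float = 1.0,
    rtol: float = 1e-5,
    atol: float = 1e-7,
    t_eval: np.ndarray | None = None,
):
    """Adaptive Dormand-Prince integration of the augmented state.

    Works forward or backward in time.  Returns the state at ``t1``, or a
    list of states if ``t_eval`` is given.  Raises on solver failure with
    the offending interval named.
    """
    x0 = state0.x
    n, d = x0.shape

    def rhs(t, y):
        st = AugmentedState.unpack(y, n, d)
        dst = augmented_rhs(field, st, t, alpha)
        return np.hstack([
            dst.x, dst.lnrho[:, None], dst.logmass[:, None], dst.cost[:, None]
        ]).ravel()

    try:
        sol = solve_ivp(
            rhs, (t0, t1), state0.pack(), method="RK45", rtol=rtol, atol=atol,
            t_eval=t_eval, dense_output=False,
        )
    except (ValueError, FloatingPointError) as exc:
        raise RuntimeError(
            f"ODE solver failed on interval [{t0}, {t1}]: {exc}"
        ) from exc
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed on interval [{t0}, {t1}]: {sol.message}"
        )
    if t_eval is None:
        return AugmentedState.unpack(sol.y[:, -1], n, d)
    return [AugmentedState.unpack(sol.y[:, k], n, d) for k in range(sol.y.shape[1])]


# ----------------------------------------------------- differentiable path
def rhs_position(field: FieldPair):
    """Graph rhs for position-only integration: dx/dt = v."""

    def rhs(y: Tensor, t: float) -> Tensor:
        return field.velocity_graph(y, t)

    return rhs


def rhs_position_lnrho(field: FieldPair, d: int):
    """Graph rhs for [x, lnrho]: the change-of-variables identity."""

    def rhs(y: Tensor, t: float) -> Tensor:
        n = y.value.shape[0]
        x = ad.slice_cols(y, 0, d)
        v, div = field.velocity_and_divergence_graph(x, t)
        g = field.growth_graph(x, t)
        dln = g - ad.reshape(div, (n, 1))
        return ad.concat_cols([v, dln])

    return rhs


def rhs_cost(field: FieldPair, d: int, alpha: float):
    """Graph rhs for [x, logmass, cost]: the WFR cost accumulator."""

    def rhs(y: Tensor, t: float) -> Tensor:
        x = ad.slice_cols(y, 0, d)
        logmass = ad.slice_cols(y, d, d + 1)
        v = field.velocity_graph(x, t)
        g = field.growth_graph(x, t)
        speed2 = ad.reduce_sum(ad.square(v), axis=1, keepdims=True)
        integrand = (speed2 + alpha * ad.square(g)) * ad.exp(logmass)
        return ad.concat_cols([v, g, integrand])

    return rhs


def rhs_position_spans(field: FieldPair, t0: np.ndarray, span: np.ndarray):
    """Span-normalized position rhs: rows with different intervals integrate
    together over a common clock s in [0, 1], with dx/ds = span * v."""
    span_t = ad.constant(span)

    def rhs(y: Tensor, s: float) -> Tensor:
        return span_t * field.velocity_graph(y, t0 + s * span)

    return rhs


def rhs_position_lnrho_spans(field: FieldPair, d: int, t0: np.ndarray,
                             span: np.ndarray):
    span_t = ad.constant(span)

    def rhs(y: Tensor, s: float) -> Tensor:
        n = y.value.shape[0]
        x = ad.slice_cols(y, 0, d)
        tt = t0 + s * span
        v, div = field.velocity_and_divergence_graph(x, tt)
        g = field.growth_graph(x, tt)
        dln = g - ad.reshape(div, (n, 1))
        return span_t * ad.concat_cols([v, dln])

    return rhs


def rhs_cost_spans(field: FieldPair, d: int, alpha: float, t0: np.ndarray,
                   span: np.ndarray):
    span_t = ad.constant(span)

    def rhs(y: Tensor, s: float) -> Tensor:
        x = ad.slice_cols(y, 0, d)
        logmass = ad.slice_cols(y, d, d + 1)
        tt = t0 + s * span
        v = field.velocity_graph(x, tt)
        g = field.growth_graph(x, tt)
        speed2 = ad.reduce_sum(ad.square(v), axis=1, keepdims=True)
        integrand = (speed2 + alpha * ad.square(g)) * ad.exp(logmass)
        return span_t * ad.concat_cols([v, g, integrand])

    return rhs


def rk4_graph(rhs, y0: Tensor, t0: float, t1: float, n_steps: int) -> Tensor:
    """Fixed-step classical RK4, differentiable through every stage."""
    h = (t1 - t0) / n_steps
    y, t = y0, t0
    for _ in range(n_steps):
        k1 = rhs(y, t)
        k2 = rhs(y + (h / 2) * k1, t + h / 2)
        k3 = rhs(y + (h / 2) * k2, t + h / 2)
        k4 = rhs(y + h * k3, t + h)
        y = y + (h / 6) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
    return y
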