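"""Downstream analyses of a fitted velocity/growth field.

The Jacobian J_ij = dv_i/dx_j of the velocity field is read as a signed,
directed, weighted regulatory matrix (positive entries: activation from gene
j to gene i; negative: inhibition), usually averaged over a group of cells
to suppress single-cell noise.  The gradient of the growth field ranks genes
by their contribution to population growth.  Characteristic-curve
integration provides per-cell trajectories (including unmeasured times),
descendant-based fate probabilities, and group mass dynamics through the
accumulated growth factor e^{int g}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import AugmentedState, integrate
from .fields import FieldPair


def _field_of(model) -> FieldPair:
    # accept a fitted estimator or anything exposing the field API directly
    return model.field_ if hasattr(model, "field_") else model


def _tolerances(model) -> tuple[float, float]:
    rtol = getattr(model, "rtol", 1e-5)
    atol = getattr(model, "atol", 1e-7)
    return rtol, atol


@dataclass
class Trajectory:
    """Characteristic curves for a batch of cells on a common time grid."""

    times: np.ndarray  # (n_times,)
    states: np.ndarray  # (n_times, n_cells, d)
    lnrho: np.ndarray  # (n_times, n_cells)
    logmass: np.ndarray  # (n_times, n_cells)


@dataclass
class RegulatoryMatrix:
    """Group-averaged Jacobian with its evaluation context."""

    matrix: np.ndarray
    time: float
    n_cells: int


@dataclass
class GrowthGeneRanking:
    """Genes ordered by descending mean growth gradient."""

    gradients: np.ndarray  # mean d g / d x_j, in gene order
    order: np.ndarray  # gene indices sorted by descending gradient
    time: float

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def trajectories(model, x0, t0: float, t_grid) -> Trajectory:
    """Integrate cells from (x0, t0) across a sorted time grid.

    The grid must contain t0; times before t0 are reached by backward
    integration.  Supports unmeasured intermediate times by construction.
    """
    field = _field_of(model)
    rtol, atol = _tolerances(model)
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    i0 = int(np.argmin(np.abs(t_grid - t0)))
    if abs(t_grid[i0] - t0) > 1e-9:
        raise ValueError("t_grid must include t0")
    x0 = np.atleast_2d(np.asarray(x0, dtype=np.float64))
    n, d = x0.shape
    states = np.empty((len(t_grid), n, d))
    lnrho = np.empty((len(t_grid), n))
    logmass = np.empty((len(t_grid), n))

    def run(direction: range):
        st = AugmentedState.initial(x0)
        states[i0], lnrho[i0], logmass[i0] = st.x, st.lnrho, st.logmass
        prev = i0
        for k in direction:
            st = integrate(field, st, t_grid[prev], t_grid[k], rtol=rtol, atol=atol)
            states[k], lnrho[k], logmass[k] = st.x, st.lnrho, st.logmass
            prev = k

    run(range(i0 + 1, len(t_grid)))
    run(range(i0 - 1, -1, -1))
    return Trajectory(t_grid, states, lnrho, logmass)


def regulatory_matrix(model, cells, t: float) -> RegulatoryMatrix:
    """Mean velocity Jacobian over a group of cells at time t."""
    cells = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    if cells.shape[0] == 0:
        raise ValueError("cells must be non-empty")
    J = _field_of(model).jacobian(cells, t)
    return RegulatoryMatrix(J.mean(axis=0), float(t), cells.shape[0])


def growth_genes(model, cells, t: float, k: int | None = None) -> GrowthGeneRanking:
    """Rank genes by mean growth gradient over a group of cells."""
    cells = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    d = cells.shape[1]
    if k is not None and k > d:
        raise ValueError("k cannot exceed the number of genes")
    grad = _field_of(model).growth_gradient(cells, t).mean(axis=0)
    # stable sort so exact ties fall back to gene index order
    order = np.argsort(-grad, kind="stable")
    return GrowthGeneRanking(grad, order, float(t))


def prune_edges(matrix: np.ndarray, keep_quantile: float = 0.75) -> np.ndarray:
    """Zero out regulatory edges below a magnitude quantile (display aid)."""
    thresh = np.quantile(np.abs(matrix), keep_quantile)
    out = matrix.copy()
    out[np.abs(out) < thresh] = 0.0
    return out


def fate_probability(
    model,
    cells,
    t0: float,
    t_final: float,
    fate_classifier,
    n_descendants: int = 20,
    jitter: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell probability of reaching fate 1, from jittered descendants.

    Each starting cell is replicated ``n_descendants`` times with isotropic
    Gaussian jitter (default scale: the model's density bandwidth),
    integrated to ``t_final``, and classified by ``fate_classifier``, which
    maps an (m, d) array of endpoint states to integer labels: 1 (fate of
    interest), 0 (alternative fate), -1 (uncommitted).  The probability is
    the committed fraction labelled 1; cells with no committed descendants
    get NaN.
    """
    field = _field_of(model)
    rtol, atol = _tolerances(model)
    cells = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    n, d = cells.shape
    if jitter is None:
        jitter = getattr(model, "sigma", 0.2)
    rng = np.random.default_rng(seed)
    copies = np.repeat(cells, n_descendants, axis=0)
    copies = copies + jitter * rng.standard_normal(copies.shape)
    end = integrate(
        field, AugmentedState.initial(copies), t0, t_final, rtol=rtol, atol=atol
    ).x
    labels = np.asarray(fate_classifier(end)).reshape(n, n_descendants)
    committed = labels >= 0
    n_committed = committed.sum(axis=1)
    prob = np.full(n, np.nan)
    ok = n_committed > 0
    prob[ok] = (labels == 1)[ok].sum(axis=1) / n_committed[ok]
    return prob


def population_ratio(model, group1, group2, t0: float, t_grid) -> np.ndarray:
    """Mass ratio of two cell groups over time via accumulated growth.

    Each member carries mass factor e^{int g ds} along its characteristic
    (the group mass is the sum of member factors), so with growth clamped to
    zero the ratio is exactly constant.
    """
    group1 = np.atleast_2d(np.asarray(group1, dtype=np.float64))
    group2 = np.atleast_2d(np.asarray(group2, dtype=np.float64))
    if group1.shape[0] == 0 or group2.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    tr1 = trajectories(model, group1, t0, t_grid)
    tr2 = trajectories(model, group2, t0, t_grid)
    mass1 = np.exp(tr1.logmass).sum(axis=1)
    mass2 = np.exp(tr2.logmass).sum(axis=1)
    if np.any(mass2 == 0):
        raise ZeroDivisionError("denominator group has zero mass")
    return mass1 / mass2


def mass_factor(model, x0, t0: float, t1: float) -> float:
    """Population mass ratio M(t1)/M(t0) implied by the growth field.

    Monte-Carlo estimate of E_{x0 ~ rho_{t0}}[e^{int_{t0}^{t1} g ds}] along
    characteristics started at the given representative cells.
    """
    field = _field_of(model)
    rtol, atol = _tolerances(model)
    x0 = np.atleast_2d(np.asarray(x0, dtype=np.float64))
    end = integrate(field, AugmentedState.initial(x0), t0, t1, rtol=rtol, atol=atol)
    return float(np.exp(end.logmass).mean())


def back_project(reduction, latent_J: np.ndarray | None = None,
                 latent_grad_g: np.ndarray | None = None,
                 latent_v: np.ndarray | None = None):
    """Map latent-space derivatives back to gene space through a linear map.

    For the reversible reduction y = a * (P (x - mu)) + b (principal
    components followed by per-axis box scaling), the chain rule gives

        v_gene      = P' diag(1/a) v_latent
        J_gene      = P' diag(1/a) J_latent diag(a) P
        grad_g_gene = P' diag(a) grad_g_latent

    Returns a dict with whichever of 'J', 'grad_g', 'v' were requested.
    """
    if not (hasattr(reduction, "components_") and hasattr(reduction, "scale_alpha_")):
        raise TypeError(
            "reduction is not a reversible linear map (needs components_ and "
            "scale_alpha_); back-projection is unsupported for it"
        )
    P = reduction.components_
    a = reduction.scale_alpha_
    out = {}
    if latent_J is not None:
        out["J"] = P.T @ (np.diag(1.0 / a) @ latent_J @ np.diag(a)) @ P
    if latent_grad_g is not None:
        out["grad_g"] = P.T @ (a * np.asarray(latent_grad_g))
    if latent_v is not None:
        out["v"] = np.asarray(latent_v) @ np.diag(1.0 / a) @ P
    return out
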