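"""Stochastic three-gene benchmark circuit and analytic linear-field fixtures.

The benchmark models a toggle switch (genes A and B: self-activation plus
mutual inhibition, both driven by a constant external signal S) under strong
inhibition by a third gene C.  Two founder populations are simulated: one
starting A-high that transitions to the B-high state while dividing (division
probability increases with B), and one C-high quiescent population that stays
put.  Production is Hill-type, degradation linear, noise additive white;
integration is Euler-Maruyama with negative expression clipped to zero.

The linear-field generator produces Gaussian snapshot data whose density is
known in closed form at every time, used to validate the characteristic-curve
identities of the transport model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .data import Snapshot, TimeSeriesDataset

TRANSITION, QUIESCENT = "transition", "quiescent"


@dataclass
class ThreeGeneParams:
    """Parameters of the three-gene stochastic circuit.

    All strengths and rates are dimensionless / per unit time.  ``S`` is the
    level of the constant external signal activating A and B; it is the one
    circuit constant without a canonical published value, and the default 0.5
    is chosen so that the C-high state is an exact fixed point (at C=2,
    production C^2/(1+C^2)=0.8 balances degradation 0.4*2) while the A-high
    state is destabilized and transitions to B-high.
    """

    C_A: float = 0.5
    C_B: float = 1.0
    C_C: float = 1.0
    H_A: float = 0.5
    H_B: float = 1.0
    H_C: float = 10.0
    S: float = 0.5
    d_A: float = 0.4
    d_B: float = 0.4
    d_C: float = 0.4
    sigma_A: float = 0.05
    sigma_B: float = 0.05
    sigma_C: float = 0.01
    sigma_D: float = 0.014
    dt: float = 0.2
    t_max: float = 40.0

    def __post_init__(self):
        for name in ("C_A", "C_B", "C_C", "H_A", "H_B", "H_C", "S",
                     "d_A", "d_B", "d_C", "sigma_A", "sigma_B", "sigma_C",
                     "sigma_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class CellPopulation:
    """A living population: states (n, 3), founder lineage ids, and time."""

    states: np.ndarray
    lineage_ids: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.float64))
        self.lineage_ids = np.asarray(self.lineage_ids, dtype=np.int64)
        if self.states.shape[0] != self.lineage_ids.shape[0]:
            raise ValueError("states and lineage_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]


@dataclass
class GroundTruth:
    """Per-snapshot ground truth for the three-gene benchmark."""

    times: np.ndarray
    velocities: list  # drift evaluated at each recorded state, per snapshot
    division_probs: list  # per-step division probability g(B), per snapshot
    group_labels: list  # founder-derived label per cell, per snapshot
    counts: dict = field(default_factory=dict)  # label -> counts across times

    def ratio(self, group1: str = TRANSITION, group2: str = QUIESCENT) -> np.ndarray:
        return np.asarray(self.counts[group1], float) / np.asarray(self.counts[group2], float)


def drift(state: np.ndarray, params: ThreeGeneParams) -> np.ndarray:
    """Deterministic part of the circuit: Hill production minus degradation.

    Accepts a single 3-vector or an (n, 3) batch of nonnegative states.
    """
    st = np.asarray(state, dtype=np.float64)
    squeeze = st.ndim == 1
    st = np.atleast_2d(st)
    if st.shape[1] != 3:
        raise ValueError("state must have 3 components (A, B, C)")
    if np.any(st < 0):
        raise ValueError("expression state must be nonnegative")
    A, B, C = st[:, 0], st[:, 1], st[:, 2]
    p = params
    A2, B2, C2 = A * A, B * B, C * C
    dA = (p.C_A * A2 + p.S) / (1.0 + p.C_A * A2 + p.H_B * B2 + p.H_C * C2 + p.S) - p.d_A * A
    dB = (p.C_B * B2 + p.S) / (1.0 + p.H_A * A2 + p.C_B * B2 + p.H_C * C2 + p.S) - p.d_B * B
    dC = p.C_C * C2 / (1.0 + p.C_C * C2) - p.d_C * C
    out = np.column_stack([dA, dB, dC])
    return out[0] if squeeze else out


def division_probability(B: np.ndarray) -> np.ndarray:
    """Per-step probability of division, B^2/(1+B^2) percent (max 1%)."""
    B = np.asarray(B, dtype=np.float64)
    return B * B / (1.0 + B * B) / 100.0


def step_em(pop: CellPopulation, params: ThreeGeneParams,
            rng: np.random.Generator) -> CellPopulation:
    """One Euler-Maruyama step; negative expression clipped to zero."""
    sig = np.array([params.sigma_A, params.sigma_B, params.sigma_C])
    noise = rng.standard_normal(pop.states.shape) * sig * np.sqrt(params.dt)
    new = pop.states + params.dt * drift(pop.states, params) + noise
    np.clip(new, 0.0, None, out=new)
    return CellPopulation(new, pop.lineage_ids.copy(), pop.time + params.dt)


def divide(pop: CellPopulation, params: ThreeGeneParams,
           rng: np.random.Generator) -> CellPopulation:
    """Divide each cell with probability B^2/(1+B^2)% (evaluated per step).

    A dividing parent is replaced by two children at the parent state plus
    independent Gaussian perturbations of scale sigma_D on each gene, clipped
    to remain nonnegative; children inherit the parent's lineage id.
    """
    g = division_probability(pop.states[:, 1])
    divides = rng.random(pop.n_cells) < g
    if not divides.any():
        return CellPopulation(pop.states.copy(), pop.lineage_ids.copy(), pop.time)
    parents = pop.states[divides]
    children = np.repeat(parents, 2, axis=0)
    children = children + params.sigma_D * rng.standard_normal(children.shape)
    np.clip(children, 0.0, None, out=children)
    child_ids = np.repeat(pop.lineage_ids[divides], 2)
    states = np.vstack([pop.states[~divides], children])
    ids = np.concatenate([pop.lineage_ids[~divides], child_ids])
    return CellPopulation(states, ids, pop.time)


def simulate_three_gene(
    params: ThreeGeneParams | None = None,
    n_per_group: tuple[int, int] = (100, 100),
    snapshot_times: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0),
    seed: int = 0,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Run the stochastic benchmark and record snapshots with ground truth.

    Founders are drawn i.i.d. from N([2, 0.2, 0], 0.01*I) (transition group)
    and N([0, 0, 2], 0.01*I) (quiescent group); snapshot times must lie on
    the Euler-Maruyama grid.  Each step applies the EM update first, then the
    division check.  Group labels follow the founder, not the later state.
    """
    p = params or ThreeGeneParams()
    rng = np.random.default_rng(seed)
    snapshot_times = tuple(float(t) for t in snapshot_times)
    n_steps_at = []
    for t in snapshot_times:
        k = t / p.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"snapshot time {t} is not on the EM grid (dt={p.dt})")
        n_steps_at.append(int(round(k)))

    n1, n2 = n_per_group
    centers = np.array([[2.0, 0.2, 0.0], [0.0, 0.0, 2.0]])
    init = np.vstack([
        centers[0] + np.sqrt(0.01) * rng.standard_normal((n1, 3)),
        centers[1] + np.sqrt(0.01) * rng.standard_normal((n2, 3)),
    ])
    np.clip(init, 0.0, None, out=init)
    founder_group = np.array([TRANSITION] * n1 + [QUIESCENT] * n2)
    pop = CellPopulation(init, np.arange(n1 + n2), 0.0)

    snaps, vels, gprobs, labels = [], [], [], []
    counts = {TRANSITION: [], QUIESCENT: []}

    def record(pop: CellPopulation) -> None:
        lab = founder_group[pop.lineage_ids]
        snaps.append(Snapshot(pop.time, pop.states.copy()))
        vels.append(drift(pop.states, p))
        gprobs.append(division_probability(pop.states[:, 1]))
        labels.append(lab)
        counts[TRANSITION].append(int((lab == TRANSITION).sum()))
        counts[QUIESCENT].append(int((lab == QUIESCENT).sum()))

    max_step = max(n_steps_at)
    step_set = dict.fromkeys(n_steps_at)
    if 0 in step_set:
        record(pop)
    for k in range(1, max_step + 1):
        pop = step_em(pop, p, rng)
        pop = divide(pop, p, rng)
        if k in step_set:
            record(pop)

    n0 = snaps[0].n_cells
    dataset = TimeSeriesDataset([
        replace_mass(s, s.n_cells / n0) for s in snaps
    ])
    truth = GroundTruth(np.array(snapshot_times), vels, gprobs, labels, counts)
    return dataset, truth


def replace_mass(snap: Snapshot, mass: float) -> Snapshot:
    return Snapshot(snap.time, snap.X, mass)


class LinearGaussianDensity:
    """Closed-form density for dx/dt = A x with spatially uniform growth g.

    Starting from N(mu0, Sigma0) with unit mass, the density at time t is the
    Gaussian with mean e^{At} mu0 and covariance e^{At} Sigma0 e^{A't},
    carrying total mass e^{g t}.
    """

    def __init__(self, A: np.ndarray, g: float, mean0: np.ndarray, cov0: np.ndarray):
        self.A = np.asarray(A, dtype=np.float64)
        self.g = float(g)
        self.mean0 = np.asarray(mean0, dtype=np.float64)
        self.cov0 = np.asarray(cov0, dtype=np.float64)
        self.d = self.mean0.shape[0]

    def mean(self, t: float) -> np.ndarray:
        return expm(self.A * t) @ self.mean0

    def cov(self, t: float) -> np.ndarray:
        E = expm(self.A * t)
        return E @ self.cov0 @ E.T

    def mass(self, t: float) -> float:
        return float(np.exp(self.g * t))

    def log_density(self, x: np.ndarray, t: float) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        mu, cov = self.mean(t), self.cov(t)
        diff = x - mu
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        _, logdet = np.linalg.slogdet(cov)
        return (self.g * t - 0.5 * (self.d * np.log(2 * np.pi) + logdet + maha))

    def density(self, x: np.ndarray, t: float) -> np.ndarray:
        return np.exp(self.log_density(x, t))

    def sample(self, n: int, t: float, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean(t), self.cov(t), size=n)


def simulate_linear_field(
    A_matrix: np.ndarray,
    g_value: float,
    mean0: np.ndarray,
    cov0: np.ndarray,
    times: tuple[float, ...],
    n: int,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, LinearGaussianDensity]:
    """Sample snapshots from the exactly solvable linear-drift Gaussian flow."""
    A_matrix = np.asarray(A_matrix, dtype=np.float64)
    if A_matrix.ndim != 2 or A_matrix.shape[0] != A_matrix.shape[1]:
        raise ValueError("A_matrix must be square")
    if np.any(np.linalg.eigvalsh(np.asarray(cov0, float)) <= 0):
        raise ValueError("cov0 must be positive definite")
    truth = LinearGaussianDensity(A_matrix, g_value, mean0, cov0)
    rng = np.random.default_rng(seed)
    snaps = [
        Snapshot(t, truth.sample(n, t, rng), truth.mass(t)) for t in times
    ]
    return TimeSeriesDataset(snaps), truth
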