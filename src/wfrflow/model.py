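"""Estimator interface: fit velocity and growth fields to snapshot data.

`UnbalancedFlowModel` follows scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit(X, t)`` where ``t`` labels each cell with its
snapshot time, fitted state in trailing-underscore attributes.  Fitting
minimizes the Wasserstein-Fisher-Rao transport cost plus density
reconstruction errors with Adam, re-sampling all Monte-Carlo draws every
epoch; gradients flow through the Runge-Kutta discretization of the
characteristic ODEs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._autodiff import Tensor
from .data import Snapshot, TimeSeriesDataset
from .density import build_densities
from .fields import FieldPair
from .objective import total_loss_graph


class Adam:
    """Adam optimizer updating parameter tensors in place."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                # decoupled decay: parameters without data support relax to
                # zero instead of wandering on the unidentified directions
                p.value -= self.lr * self.weight_decay * p.value


class UnbalancedFlowModel(BaseEstimator):
    """Dynamic unbalanced optimal transport over time-series snapshots.

    Parameters
    ----------
    hidden_dims_v, hidden_dims_g : tuple of int
        Hidden-layer widths of the Tanh networks for the velocity field
        v(x, t) and the growth field g(x, t).
    alpha : float
        Weight of the Fisher-Rao (growth) energy relative to the
        Wasserstein (transport) energy in the cost.
    lambda_d : float
        Weight of the combined reconstruction error in the loss.
    K : int
        Monte-Carlo samples per cost/reconstruction term per epoch.
    sigma : float
        Bandwidth of the per-snapshot Gaussian-mixture densities.
    epochs, learning_rate : training schedule (Adam).
    clamp_growth : bool
        If True, g is pinned to zero and excluded from optimization
        (balanced-transport ablation).
    recon_space : {'density', 'log_density'}
        Whether reconstruction errors compare densities or log densities.
    train_base_dt : float or None
        Time step of the fixed-step RK4 discretization used during training;
        default is one fifth of the smallest snapshot interval.
    rtol, atol : tolerances of the adaptive solver used at inference.
    random_state : seed for initialization and per-epoch resampling.

    Attributes
    ----------
    field_ : FieldPair
        Fitted velocity/growth networks.
    times_, masses_ : snapshot times and relative populations.
    densities_ : per-snapshot mixtures used during fitting.
    loss_history_ : DataFrame with per-epoch loss components.
    loss_breakdown_ : components of the final epoch's loss.
    """

    def __init__(
        self,
        hidden_dims_v=(64, 64, 64),
        hidden_dims_g=(32, 32),
        alpha=1.0,
        lambda_d=1.0,
        K=100,
        sigma=0.2,
        epochs=2000,
        learning_rate=1e-3,
        learning_rate_final=None,
        weight_decay=0.0,
        clamp_growth=False,
        recon_space="density",
        train_base_dt=None,
        time_scale=None,
        rtol=1e-5,
        atol=1e-7,
        init_scale=0.1,
        random_state=None,
        verbose=0,
    ):
        self.hidden_dims_v = hidden_dims_v
        self.hidden_dims_g = hidden_dims_g
        self.alpha = alpha
        self.lambda_d = lambda_d
        self.K = K
        self.sigma = sigma
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.learning_rate_final = learning_rate_final
        self.weight_decay = weight_decay
        self.clamp_growth = clamp_growth
        self.recon_space = recon_space
        self.train_base_dt = train_base_dt
        self.time_scale = time_scale
        self.rtol = rtol
        self.atol = atol
        self.init_scale = init_scale
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def fit(self, X, t, relative_mass=None):
        """Fit the fields to stacked snapshot data.

        Parameters
        ----------
        X : array (n_cells_total, d)
            All cells from all snapshots stacked row-wise.
        t : array (n_cells_total,)
            Snapshot time of each cell.
        relative_mass : array (n_timepoints,), optional
            Population of each snapshot relative to the first.  Defaults to
            cell-count ratios (equal-initial-culture assumption).
        """
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        X = check_array(X, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64).ravel()
        if t.shape[0] != X.shape[0]:
            raise ValueError("X and t must have the same number of rows")
        times = np.unique(t)
        if len(times) < 2:
            raise ValueError(">= 2 timepoints required")
        counts = np.array([(t == ti).sum() for ti in times], dtype=float)
        if relative_mass is None:
            masses = counts / counts[0]
        else:
            masses = np.asarray(relative_mass, dtype=np.float64)
            if masses.shape[0] != len(times):
                raise ValueError("relative_mass must have one entry per timepoint")
        dataset = TimeSeriesDataset([
            Snapshot(ti, X[t == ti], m) for ti, m in zip(times, masses)
        ])
        return self.fit_dataset(dataset)

    def fit_dataset(self, dataset: TimeSeriesDataset):
        """Fit directly from a :class:`TimeSeriesDataset`."""
        times = dataset.times
        if len(times) < 2:
            raise ValueError(">= 2 timepoints required")
        d = dataset.n_features
        rng = np.random.default_rng(self.random_state)
        densities = build_densities(dataset, self.sigma)
        base_dt = self.train_base_dt or float(np.diff(times).min()) / 5.0

        field = FieldPair(
            d,
            tuple(self.hidden_dims_v),
            tuple(self.hidden_dims_g),
            rng=rng,
            init_scale=self.init_scale,
            clamp_growth=self.clamp_growth,
            time_scale=self.time_scale or max(float(times[-1] - times[0]), 1e-12),
        )
        params = field.parameters()
        opt = Adam(params, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        lr0 = self.learning_rate
        lrf = self.learning_rate_final or lr0
        history = []
        last_good = [p.value.copy() for p in params]
        breakdown = None
        for epoch in range(self.epochs):
            if lrf != lr0 and self.epochs > 1:
                # geometric decay from lr0 to lrf across the run
                opt.lr = lr0 * (lrf / lr0) ** (epoch / (self.epochs - 1))
            opt.zero_grad()
            loss, breakdown = total_loss_graph(
                field, densities, times, self.alpha, self.lambda_d, self.K,
                rng, base_dt, self.recon_space, batched=True,
            )
            if not np.isfinite(breakdown.loss):
                for p, good in zip(params, last_good):
                    p.value[...] = good
                warnings.warn(
                    f"non-finite loss at epoch {epoch}; restored last good "
                    "parameters and stopped early"
                )
                break
            last_good = [p.value.copy() for p in params]
            if self.learning_rate > 0:
                loss.backward()
                opt.step()
            history.append(
                (epoch, breakdown.W, breakdown.R_short, breakdown.R_long,
                 breakdown.R, breakdown.loss)
            )
            if self.verbose and epoch % max(1, self.epochs // 20) == 0:
                print(f"epoch {epoch:5d}  W={breakdown.W:.4g}  "
                      f"R={breakdown.R:.4g}  loss={breakdown.loss:.4g}")

        self.field_ = field
        self.times_ = times
        self.masses_ = dataset.masses
        self.densities_ = densities
        self.train_base_dt_ = base_dt
        self.loss_breakdown_ = breakdown
        self.loss_history_ = pd.DataFrame(
            history, columns=["epoch", "W", "R_short", "R_long", "R", "loss"]
        )
        self.n_features_in_ = d
        return self

    # ------------------------------------------------------------ inference
    def velocity(self, X, t: float) -> np.ndarray:
        check_is_fitted(self, "field_")
        return self.field_.velocity(np.asarray(X, dtype=np.float64), t)

    def predict(self, X, t: float) -> np.ndarray:
        """Alias for :meth:`velocity` (the primary per-cell prediction)."""
        return self.velocity(X, t)

    def growth(self, X, t: float) -> np.ndarray:
        check_is_fitted(self, "field_")
        return self.field_.growth(np.asarray(X, dtype=np.float64), t)

    def jacobian(self, X, t: float) -> np.ndarray:
        check_is_fitted(self, "field_")
        return self.field_.jacobian(np.asarray(X, dtype=np.float64), t)

    def growth_gradient(self, X, t: float) -> np.ndarray:
        check_is_fitted(self, "field_")
        return self.field_.growth_gradient(np.asarray(X, dtype=np.float64), t)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        check_is_fitted(self, "field_")
        payload = {
            "config": self.get_params(),
            "field": self.field_.to_dict(),
            "times": self.times_.tolist(),
            "masses": self.masses_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "UnbalancedFlowModel":
        payload = json.loads(Path(path).read_text())
        config = payload["config"]
        for key in ("hidden_dims_v", "hidden_dims_g"):
            config[key] = tuple(config[key])
        model = cls(**config)
        model.field_ = FieldPair.from_dict(payload["field"])
        model.times_ = np.asarray(payload["times"])
        model.masses_ = np.asarray(payload["masses"])
        model.n_features_in_ = model.field_.d
        return model


def set_growth_clamped(model, clamped: bool = True):
    """Toggle the balanced-transport ablation on a fitted model.

    With the clamp on, g(x, t) is identically zero, its parameters are
    excluded from any further optimization, and the mass factor along every
    characteristic stays exactly one.
    """
    target = model.field_ if isinstance(model, UnbalancedFlowModel) else model
    target.clamp_growth = bool(clamped)
    return model
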