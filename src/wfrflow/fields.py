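"""Smooth parametric velocity and growth fields.

Both fields are small fully connected networks taking the concatenated
(x, t) as input: hidden layers are affine maps followed by Tanh, the output
layer is linear.  Because the architecture is an explicit chain of affine
maps and Tanh nonlinearities, the Jacobian of the output with respect to the
spatial input is itself an explicit product

    J(x, t) = W_L diag(1 - h_{L-1}^2) W_{L-1} ... diag(1 - h_1^2) W_1[:d]

which we evaluate directly -- exactly, not by stochastic estimation -- in a
fast numpy path for inference and as autodiff-graph operations when the
divergence term d(ln rho)/dt = g - div(v) must carry gradients back to the
parameters during training.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class MLP:
    """Tanh multilayer perceptron with linear output layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, init_scale: float = 0.1):
        self.sizes = list(sizes)
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        n_aff = len(sizes) - 1
        for k, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            # hidden layers at unit (Glorot-like) scale so the Tanh features
            # tile the input space from the start; only the output layer is
            # shrunk by init_scale, keeping the initial field near zero and
            # the early ODE solves well conditioned
            scale = (init_scale if k == n_aff - 1 else 1.0) / np.sqrt(a)
            self.Ws.append(rng.normal(0.0, scale, size=(a, b)))
            self.bs.append(np.zeros(b))
        self._tWs = [ad.parameter(W) for W in self.Ws]
        self._tbs = [ad.parameter(b) for b in self.bs]

    # parameters share memory with the Tensor wrappers, so in-place optimizer
    # updates on .value are all that is needed between epochs
    def parameters(self) -> list[Tensor]:
        return self._tWs + self._tbs

    @property
    def n_layers(self) -> int:
        return len(self.Ws)

    # ---------------------------------------------------------- numpy paths
    def forward(self, X: np.ndarray, return_hidden: bool = False):
        h = X
        hidden = []
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            h = np.tanh(h @ W + b)
            hidden.append(h)
        out = h @ self.Ws[-1] + self.bs[-1]
        return (out, hidden) if return_hidden else out

    def input_jacobian(self, X: np.ndarray, d: int) -> np.ndarray:
        """d(output)/d(first d input columns), shape (n, out_dim, d)."""
        _, hidden = self.forward(X, return_hidden=True)
        M = (1.0 - hidden[0] ** 2)[:, :, None] * self.Ws[0][:d, :].T[None, :, :]
        for k in range(1, len(hidden)):
            M = (1.0 - hidden[k] ** 2)[:, :, None] * np.matmul(self.Ws[k].T, M)
        return np.matmul(self.Ws[-1].T, M)

    # ---------------------------------------------------------- graph paths
    def forward_graph(self, x: Tensor, return_hidden: bool = False):
        h = x
        hidden = []
        for W, b in zip(self._tWs[:-1], self._tbs[:-1]):
            h = ad.tanh(ad.affine(h, W, b))
            hidden.append(h)
        out = ad.affine(h, self._tWs[-1], self._tbs[-1])
        return (out, hidden) if return_hidden else out

    def input_jacobian_graph(self, x: Tensor, d: int):
        """Graph version of :meth:`input_jacobian`; also returns the output."""
        out, hidden = self.forward_graph(x, return_hidden=True)
        n = x.value.shape[0]
        h0 = hidden[0]
        D0 = 1.0 - ad.square(h0)
        W1xT = ad.transpose2d(ad.slice_rows(self._tWs[0], 0, d))  # (m1, d)
        M = ad.reshape(D0, (n, D0.value.shape[1], 1)) * W1xT
        for k in range(1, len(hidden)):
            Dk = 1.0 - ad.square(hidden[k])
            M = ad.reshape(Dk, (n, Dk.value.shape[1], 1)) * ad.mat_bmm(
                ad.transpose2d(self._tWs[k]), M
            )
        J = ad.mat_bmm(ad.transpose2d(self._tWs[-1]), M)
        return out, J


def _with_time(X: np.ndarray, t, scale: float) -> np.ndarray:
    if np.isscalar(t):
        tcol = np.full((X.shape[0], 1), t / scale)
    else:
        tcol = np.asarray(t, dtype=np.float64).reshape(-1, 1) / scale
    return np.hstack([X, tcol])


def _with_time_graph(x: Tensor, t, scale: float) -> Tensor:
    # t may be a scalar or a per-row array (batched terms with different
    # time offsets integrate together in a normalized clock)
    if np.isscalar(t):
        tcol = np.full((x.value.shape[0], 1), t / scale)
    else:
        tcol = np.asarray(t, dtype=np.float64).reshape(-1, 1) / scale
    return ad.concat_cols([x, ad.constant(tcol)])


class FieldPair:
    """The velocity field v(x, t) and growth field g(x, t).

    ``clamp_growth=True`` pins g to zero everywhere and removes its
    parameters from optimization, recovering the balanced (mass-conserving)
    transport model.
    """

    def __init__(
        self,
        d: int,
        hidden_dims_v: tuple[int, ...] = (64, 64, 64),
        hidden_dims_g: tuple[int, ...] = (32, 32),
        rng: np.random.Generator | int | None = 0,
        init_scale: float = 0.1,
        clamp_growth: bool = False,
        time_scale: float = 1.0,
    ):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.d = int(d)
        self.hidden_dims_v = tuple(hidden_dims_v)
        self.hidden_dims_g = tuple(hidden_dims_g)
        self.v_net = MLP([d + 1, *hidden_dims_v, d], rng, init_scale)
        self.g_net = MLP([d + 1, *hidden_dims_g, 1], rng, init_scale)
        self.clamp_growth = bool(clamp_growth)
        # times are fed to the networks as t / time_scale so that the time
        # input stays O(1) regardless of the experiment's clock units
        self.time_scale = float(time_scale)

    def parameters(self) -> list[Tensor]:
        params = self.v_net.parameters()
        if not self.clamp_growth:
            params = params + self.g_net.parameters()
        return params

    # ---------------------------------------------------------- numpy paths
    def velocity(self, X: np.ndarray, t: float) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.v_net.forward(_with_time(X, t, self.time_scale))

    def growth(self, X: np.ndarray, t: float) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.clamp_growth:
            return np.zeros(X.shape[0])
        return self.g_net.forward(_with_time(X, t, self.time_scale))[:, 0]

    def jacobian(self, X: np.ndarray, t: float) -> np.ndarray:
        """J_ij = dv_i/dx_j at each row of X, shape (n, d, d)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.v_net.input_jacobian(_with_time(X, t, self.time_scale), self.d)

    def divergence(self, X: np.ndarray, t: float) -> np.ndarray:
        """Exact div(v) as the trace of the Jacobian."""
        return np.trace(self.jacobian(X, t), axis1=1, axis2=2)

    def growth_gradient(self, X: np.ndarray, t: float) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.clamp_growth:
            return np.zeros_like(X)
        J = self.g_net.input_jacobian(_with_time(X, t, self.time_scale), self.d)
        return J[:, 0, :]

    # ---------------------------------------------------------- graph paths
    def velocity_graph(self, x: Tensor, t: float) -> Tensor:
        return self.v_net.forward_graph(_with_time_graph(x, t, self.time_scale))

    def growth_graph(self, x: Tensor, t: float) -> Tensor:
        if self.clamp_growth:
            return ad.constant(np.zeros((x.value.shape[0], 1)))
        return self.g_net.forward_graph(_with_time_graph(x, t, self.time_scale))

    def velocity_and_divergence_graph(self, x: Tensor, t: float):
        out, J = self.v_net.input_jacobian_graph(_with_time_graph(x, t, self.time_scale), self.d)
        return out, ad.btrace(J)

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "hidden_dims_v": list(self.hidden_dims_v),
            "hidden_dims_g": list(self.hidden_dims_g),
            "clamp_growth": self.clamp_growth,
            "time_scale": self.time_scale,
            "v_weights": [W.tolist() for W in self.v_net.Ws],
            "v_biases": [b.tolist() for b in self.v_net.bs],
            "g_weights": [W.tolist() for W in self.g_net.Ws],
            "g_biases": [b.tolist() for b in self.g_net.bs],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FieldPair":
        fp = cls(
            payload["d"],
            tuple(payload["hidden_dims_v"]),
            tuple(payload["hidden_dims_g"]),
            rng=0,
            clamp_growth=payload["clamp_growth"],
            time_scale=payload.get("time_scale", 1.0),
        )
        for net, wkey, bkey in ((fp.v_net, "v_weights", "v_biases"),
                                (fp.g_net, "g_weights", "g_biases")):
            for W, Wnew in zip(net.Ws, payload[wkey]):
                W[...] = np.asarray(Wnew)
            for b, bnew in zip(net.bs, payload[bkey]):
                b[...] = np.asarray(bnew)
        return fp
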