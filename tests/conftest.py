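import numpy as np
import pytest

from wfrflow import _autodiff as ad


class AnalyticField:
    """Closed-form field stub exposing the same API as a fitted field pair.

    Velocity/growth and their derivatives are supplied as callables of
    (X, t); graph methods wrap the numpy values as constants, which is
    sufficient for oracle checks that never differentiate parameters.
    """

    def __init__(self, d, v=None, g=None, jac=None, gradg=None, time_scale=1.0):
        self.d = d
        self._v = v or (lambda X, t: np.zeros_like(X))
        self._g = g or (lambda X, t: np.zeros(X.shape[0]))
        self._jac = jac or (lambda X, t: np.zeros((X.shape[0], d, d)))
        self._gradg = gradg or (lambda X, t: np.zeros((X.shape[0], d)))
        self.clamp_growth = False
        self.time_scale = time_scale

    def velocity(self, X, t):
        return self._v(np.atleast_2d(X), t)

    def growth(self, X, t):
        return self._g(np.atleast_2d(X), t)

    def jacobian(self, X, t):
        return self._jac(np.atleast_2d(X), t)

    def divergence(self, X, t):
        return np.trace(self.jacobian(X, t), axis1=1, axis2=2)

    def growth_gradient(self, X, t):
        return self._gradg(np.atleast_2d(X), t)

    # graph API: constants are fine for value-only oracle checks
    def velocity_graph(self, x, t):
        return ad.constant(self._v(x.value, t))

    def growth_graph(self, x, t):
        return ad.constant(self._g(x.value, t)[:, None])

    def velocity_and_divergence_graph(self, x, t):
        return self.velocity_graph(x, t), ad.constant(self.divergence(x.value, t))


def linear_field(A, g_value=0.0):
    """AnalyticField for dx/dt = A x with spatially uniform growth."""
    A = np.asarray(A, dtype=np.float64)
    d = A.shape[0]
    return AnalyticField(
        d,
        v=lambda X, t: X @ A.T,
        g=lambda X, t: np.full(X.shape[0], g_value),
        jac=lambda X, t: np.broadcast_to(A, (X.shape[0], d, d)).copy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_field():
    from wfrflow.fields import FieldPair

    return FieldPair(2, (8, 8), (6,), rng=1, init_scale=0.5)
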