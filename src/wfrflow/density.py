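"""Snapshot densities: isotropic Gaussian mixtures carrying population mass.

Each snapshot's density places one isotropic Gaussian of bandwidth sigma at
every sampled cell, with identical weights, and scales the mixture by the
snapshot's population relative to the first time point, so the density
integrates to that relative mass rather than to one.  Sampling always uses
the normalized (unit-mass) mixture; expectations against the mass-weighted
density are taken as (normalized-sample average) x mass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp as sp_logsumexp

from . import _autodiff as ad
from .data import Snapshot


def relative_populations(counts, fractions=None) -> np.ndarray:
    """Relative population sizes from cell counts and sampling fractions.

    With no fractions (or all equal to 1) the culture sizes are taken as
    proportional to cell counts: ``N_i / N_1`` (equal-initial-culture mode).

    In sequential-harvest mode, ``fractions[i]`` is the fraction of the
    *remaining* culture collected at time i.  The first count is the
    reference, and for i >= 2 the relative population is
    ``N_i / f_i / prod_{1 < k < i}(1 - f_k) / N_1``: dividing by the fraction
    collected recovers the remaining population, and dividing by the product
    of earlier survival fractions undoes the depletion caused by earlier
    harvests.  For a three-timepoint design with fractions (50%, 30%, 100%)
    this gives (1, (N2/30%)/N1, (N3/70%)/N1).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a 1-D sequence")
    if np.any(counts < 1):
        raise ValueError("all counts must be >= 1")
    if counts[0] == 0:
        raise ValueError("first count must be nonzero")
    if fractions is None:
        return counts / counts[0]
    fr = np.asarray(fractions, dtype=np.float64)
    if fr.shape != counts.shape:
        raise ValueError("fractions must match counts in length")
    if np.any(fr <= 0) or np.any(fr > 1):
        raise ValueError("fractions must lie in (0, 1]")
    if np.allclose(fr, 1.0):
        return counts / counts[0]
    out = np.empty_like(counts)
    out[0] = 1.0
    remaining = 1.0
    for i in range(1, counts.size):
        out[i] = counts[i] / fr[i] / remaining / counts[0]
        remaining *= 1.0 - fr[i]
    return out


class GaussianMixtureDensity:
    """Equal-weight isotropic Gaussian mixture scaled to total mass.

    Parameters
    ----------
    means : ndarray of shape (n_components, d)
        Component centres (the sampled cells).
    sigma : float
        Shared isotropic standard deviation (feature units).
    mass : float
        Total integral of the density (relative population).
    """

    def __init__(self, means: np.ndarray, sigma: float, mass: float = 1.0):
        means = np.atleast_2d(np.asarray(means, dtype=np.float64))
        if means.shape[0] < 1:
            raise ValueError("mixture requires at least one component")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if mass <= 0:
            raise ValueError("mass must be positive")
        self.means = means
        self.sigma = float(sigma)
        self.mass = float(mass)
        self.n_components, self.d = means.shape
        # log of the constant factor of each unit-weight component
        self._log_norm = -0.5 * self.d * np.log(2 * np.pi * self.sigma**2)
        self._log_weight = np.log(self.mass) - np.log(self.n_components)

    # ------------------------------------------------------------ evaluation
    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Stable log of the mass-weighted mixture density at rows of x."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        d2 = ((x[:, None, :] - self.means[None, :, :]) ** 2).sum(axis=2)
        return (
            sp_logsumexp(-d2 / (2 * self.sigma**2), axis=1)
            + self._log_norm
            + self._log_weight
        )

    def density(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(x))

    def log_density_graph(self, x: "ad.Tensor") -> "ad.Tensor":
        """Autodiff-graph version of :meth:`log_density` (gradient w.r.t. x)."""
        n = x.value.shape[0]
        xr = ad.reshape(x, (n, 1, self.d))
        mu = ad.constant(self.means[None, :, :])
        diff = xr - mu
        d2 = ad.reduce_sum(ad.square(diff), axis=2)
        lse = ad.logsumexp(d2 * (-1.0 / (2 * self.sigma**2)), axis=1)
        return lse + (self._log_norm + self._log_weight)

    # -------------------------------------------------------------- sampling
    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw n i.i.d. points from the *normalized* mixture."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        idx = rng.integers(0, self.n_components, size=n)
        return self.means[idx] + self.sigma * rng.standard_normal((n, self.d))


def build_mixture(snapshot: Snapshot, sigma: float = 0.2) -> GaussianMixtureDensity:
    """Mixture with one component per cell, total mass = relative population."""
    return GaussianMixtureDensity(snapshot.X, sigma, snapshot.relative_mass)


def build_densities(dataset, sigma: float = 0.2) -> list[GaussianMixtureDensity]:
    return [build_mixture(s, sigma) for s in dataset]
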