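"""Reversible, differentiable dimension reduction: PCA plus box scaling.

Expression data (already log-transformed and standardized by the caller) is
projected onto its top principal axes and each latent axis is affinely
mapped to [-2, 2].  Because the whole map is affine and orthonormal it is
exactly invertible on the retained subspace and its derivatives are
constant, so Jacobians and growth gradients learned in latent space can be
pushed back to gene space by the chain rule (see analysis.back_project).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted


class BoxScaledPCA(BaseEstimator, TransformerMixin):
    """Top-d principal axes followed by per-axis scaling to [-2, 2].

    The box bounds are fit on whatever matrix is passed to :meth:`fit`
    (pool all snapshots so every time point shares one coordinate system).
    Component signs follow a deterministic convention: the largest-magnitude
    loading of each axis is made positive.

    Attributes
    ----------
    mean_ : (d_gene,) centering vector.
    components_ : (n_components, d_gene) orthonormal rows.
    scale_alpha_, scale_beta_ : per-axis affine map y = alpha*u + beta
        taking latent scores u into [-2, 2].
    explained_variance_ratio_ : per-component variance shares.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        n, d = X.shape
        if self.n_components > min(n, d):
            raise ValueError("n_components exceeds min(n_samples, n_features)")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < self.n_components:
            raise ValueError(
                f"data rank {rank} is below the requested {self.n_components} components"
            )
        comps = pca.components_
        # deterministic sign: largest |loading| per axis is positive
        flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
        comps = comps * flip[:, None]
        scores = scores * flip[None, :]
        lo, hi = scores.min(axis=0), scores.max(axis=0)
        if np.any(hi - lo <= 0):
            raise ValueError("constant latent axis; cannot scale to [-2, 2]")
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.scale_alpha_ = 4.0 / (hi - lo)
        self.scale_beta_ = -2.0 - self.scale_alpha_ * lo
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=np.float64)
        u = (X - self.mean_) @ self.components_.T
        return u * self.scale_alpha_ + self.scale_beta_

    def inverse_transform(self, Y) -> np.ndarray:
        check_is_fitted(self, "components_")
        Y = check_array(Y, dtype=np.float64)
        u = (Y - self.scale_beta_) / self.scale_alpha_
        return u @ self.components_ + self.mean_

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        check_is_fitted(self, "components_")
        payload = {
            "n_components": self.n_components,
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "scale_alpha": self.scale_alpha_.tolist(),
            "scale_beta": self.scale_beta_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "BoxScaledPCA":
        payload = json.loads(Path(path).read_text())
        obj = cls(payload["n_components"])
        obj.mean_ = np.asarray(payload["mean"])
        obj.components_ = np.asarray(payload["components"])
        obj.explained_variance_ratio_ = np.asarray(payload["explained_variance_ratio"])
        obj.scale_alpha_ = np.asarray(payload["scale_alpha"])
        obj.scale_beta_ = np.asarray(payload["scale_beta"])
        obj.n_features_in_ = obj.components_.shape[1]
        return obj


def fit_pca(matrix, d_latent: int) -> BoxScaledPCA:
    """Convenience wrapper: fit the reversible reduction on one matrix."""
    return BoxScaledPCA(d_latent).fit(matrix)


def scale_to_box(latent: np.ndarray):
    """Affinely map each column of `latent` onto [-2, 2]; returns (Y, (a, b)).

    The inverse is u = (y - b) / a.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    lo, hi = latent.min(axis=0), latent.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("constant axis; cannot scale to [-2, 2]")
    a = 4.0 / (hi - lo)
    b = -2.0 - a * lo
    return latent * a + b, (a, b)


def explained_variance_elbow(matrix, max_d: int) -> np.ndarray:
    """Cumulative explained-variance ratios for 1..max_d components."""
    if max_d < 1:
        raise ValueError("max_d must be >= 1")
    matrix = check_array(matrix, dtype=np.float64)
    pca = PCA(n_components=min(max_d, *matrix.shape), svd_solver="full")
    pca.fit(matrix)
    ratios = np.cumsum(pca.explained_variance_ratio_)
    if len(ratios) < max_d:  # rank-deficient tail carries no extra variance
        ratios = np.concatenate([ratios, np.full(max_d - len(ratios), ratios[-1])])
    return ratios
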