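"""Scikit-learn style estimator interfaces.

`StructureEstimator` is fit-shaped in the manner of sklearn.manifold.MDS:
``fit(C)`` consumes an (n, n) contact matrix and exposes the estimated
(n, 3) embedding as ``coords_``; ``fit_transform`` returns it.  It composes
with sklearn model-selection utilities via ``get_params``/``set_params``.
`ShapeClusterer` groups an ensemble of fitted curves by pairwise RMSD.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .energy import ContactMatrix, ModelParams
from .multiscale import DEFAULT_GTOL, DEFAULT_MAX_ITER, DEFAULT_MIN_N, estimate_structure
from .shape import cluster_solutions, pairwise_rmsd


def _as_contact_matrix(C) -> ContactMatrix:
    return C if isinstance(C, ContactMatrix) else ContactMatrix(np.asarray(C, float))


class StructureEstimator(BaseEstimator):
    """Penalized Poisson MAP estimator of a 3D chromosome curve.

    Parameters
    ----------
    a : float, default=-3.0
        Power-law exponent of the distance-contact link (must be < 0).
    b : float, default=1.0
        Poisson scale; arbitrary up to curve scale, so the default is 1.
    lambda1, lambda2, lambda3 : float
        Weights of the uniform-spacing penalty, the smoothness penalty and
        the bulk-Hi-C prior.  Defaults (0.5, 1.0, 0.1) are the documented
        working values for real single-cell matrices.
    min_n : int, default=64
        Coarsest problem size of the multiscale series.
    multiscale : bool, default=True
        Coarse-to-fine optimization; False runs one full-resolution
        L-BFGS descent from the random initialization.
    gtol : float, default=1e-6
        Gradient infinity-norm tolerance per scale.
    max_iter : int, default=2000
        Iteration cap per scale.
    random_state : int or None
        Seed of the standard normal initialization.

    Attributes
    ----------
    coords_ : (n, 3) ndarray
        Estimated curve, centered at the origin.
    energy_ : float
        Final full-resolution energy.
    energies_per_scale_, n_iter_per_scale_, sizes_ : lists
        Per-scale diagnostics of the coarse-to-fine run.
    """

    def __init__(
        self,
        a: float = -3.0,
        b: float = 1.0,
        lambda1: float = 0.5,
        lambda2: float = 1.0,
        lambda3: float = 0.1,
        min_n: int = DEFAULT_MIN_N,
        multiscale: bool = True,
        gtol: float = DEFAULT_GTOL,
        max_iter: int = DEFAULT_MAX_ITER,
        random_state: int | None = None,
    ):
        self.a = a
        self.b = b
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.min_n = min_n
        self.multiscale = multiscale
        self.gtol = gtol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, C, bulk=None):
        """Estimate the curve from a contact matrix (and optional bulk prior)."""
        params = ModelParams(
            a=self.a,
            b=self.b,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            lambda3=self.lambda3,
        )
        result = estimate_structure(
            _as_contact_matrix(C),
            C_bulk=_as_contact_matrix(bulk) if bulk is not None else None,
            params=params,
            min_n=self.min_n,
            seed=self.random_state,
            multiscale=self.multiscale,
            gtol=self.gtol,
            max_iter=self.max_iter,
        )
        self.coords_ = result.curve
        self.energy_ = result.energy
        self.energies_per_scale_ = result.energy_per_scale
        self.n_iter_per_scale_ = result.iterations_per_scale
        self.sizes_ = result.sizes
        self.result_ = result
        return self

    def fit_transform(self, C, bulk=None) -> np.ndarray:
        return self.fit(C, bulk=bulk).coords_


class ShapeClusterer(BaseEstimator):
    """Hierarchical clustering of curve ensembles in RMSD shape space.

    ``fit`` takes a sequence of (n, 3) curves, computes the symmetric
    pairwise RMSD matrix (both curves unit-normalized before Procrustes
    alignment, reflections allowed) and builds an agglomerative dendrogram.

    Attributes
    ----------
    distances_ : (m, m) ndarray
        Pairwise RMSD matrix.
    linkage_ : ndarray
        Scipy linkage table (dendrogram structure).
    labels_ : ndarray or None
        Flat 1-based cluster labels when ``n_clusters`` is set.
    """

    def __init__(self, n_clusters: int | None = None, linkage_method: str = "average"):
        self.n_clusters = n_clusters
        self.linkage_method = linkage_method

    def fit(self, curves):
        self.distances_ = pairwise_rmsd(curves)
        self.linkage_, self.labels_ = cluster_solutions(
            self.distances_, k=self.n_clusters, method=self.linkage_method
        )
        return self

    def fit_predict(self, curves) -> np.ndarray:
        if self.n_clusters is None:
            raise ValueError("fit_predict requires n_clusters")
        return self.fit(curves).labels_
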