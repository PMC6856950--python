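"""Posterior energy for curve estimation: Poisson likelihood, penalties, gradient.

The model links the contact count between bins i and j to the distance
between their spatial positions x_i, x_j via ``C_ij ~ Poisson(b d_ij^a)``
with a power-law exponent ``a < 0`` (polymer physics suggests a = -3) and a
scale ``b > 0``.  Up to constants the negative log-likelihood of a curve X is

    g(X | C, a, b) = -sum_{i<j} ( a c_ij log d_ij - b d_ij^a ).

Two geometric penalties regularize the maximum-likelihood embedding:

* ``penalty_spacing`` (h1) — variance of the adjacent-gap lengths after the
  curve is rescaled to total length n-1; zero iff all gaps are equal.
* ``penalty_smoothness`` (h2) — mean cosine of the interior bend angles;
  -1 for a straight monotone chain, +1 for immediate fold-backs.

A bulk Hi-C matrix C' enters as a prior term (lambda3 / M') g(X | C', a, b),
which is algebraically absorbed into the data: with k = lambda3 M / M',
replacing (C, b) by (C + k C', (1 + k) b) leaves the per-count objective
unchanged.  The working energy minimized by the optimizer is

    E(X) = g(X | C~, a, b~) / M + lambda1 h1(X) + lambda2 h2(X).

All gradients are analytic and validated against central finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: distances are clamped at this floor inside logs, powers and normalizations
EPS_DIST = 1e-10


class DegenerateCurveError(ValueError):
    """Raised when a curve is too degenerate for the requested computation."""


def _as_curve(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"curve must be an (n, 3) array, got shape {X.shape}")
    return X


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric nonnegative contact-count matrix with the diagonal ignored.

    Parameters
    ----------
    counts : (n, n) array_like
        Symmetric nonnegative matrix.  Real values are allowed because the
        bulk-absorbed effective matrix is generally non-integer.  Diagonal
        entries are zeroed on construction (self-contacts carry no distance
        information).

    Attributes
    ----------
    n : int
        Number of genomic bins.
    M : float
        Total strictly-upper-triangular count ``sum_{j>i} c_ij``.
    """

    counts: np.ndarray
    n: int = field(init=False)
    M: float = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {c.shape}")
        if not np.allclose(c, c.T, rtol=0.0, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(c < 0):
            raise ValueError("contact matrix must be nonnegative")
        c = c.copy()
        np.fill_diagonal(c, 0.0)
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "n", c.shape[0])
        object.__setattr__(self, "M", float(np.triu(c, k=1).sum()))

    def upper(self) -> np.ndarray:
        """Strictly-upper-triangular entries in condensed (pdist) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.counts[iu]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: power-law link (a, b) and penalty weights lambda."""

    a: float = -3.0
    b: float = 1.0
    lambda1: float = 0.5
    lambda2: float = 1.0
    lambda3: float = 0.1

    def __post_init__(self):
        if not self.a < 0:
            raise ValueError(f"power-law exponent a must be < 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"Poisson scale b must be > 0, got {self.b}")
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EffectiveData:
    """Single-cell data with the bulk prior absorbed: C~ = C + k C', b~ = (1+k) b."""

    C_tilde: ContactMatrix
    b_tilde: float
    k: float


def _clamped_pdist(X: np.ndarray) -> np.ndarray:
    d = pdist(X)
    n_bad = int(np.count_nonzero(d < EPS_DIST))
    if n_bad:
        warnings.warn(
            f"{n_bad} pairwise distance(s) below {EPS_DIST:g} clamped",
            RuntimeWarning,
            stacklevel=3,
        )
        d = np.maximum(d, EPS_DIST)
    return d


def neg_loglik(X, C: ContactMatrix, a: float, b: float) -> float:
    """Negative log-likelihood g(X | C, a, b), constants in X dropped.

    Pairs with zero count still contribute the repulsion term ``b d^a``;
    only the diagonal is excluded.  Accepts real-valued counts so the same
    code evaluates g on the bulk-absorbed effective matrix.
    """
    X = _as_curve(X)
    if not (a < 0 and b > 0):
        raise ValueError("require a < 0 and b > 0")
    if C.n != X.shape[0]:
        raise ValueError(f"curve has {X.shape[0]} nodes but matrix has {C.n} bins")
    d = _clamped_pdist(X)
    c = C.upper()
    return float(-(a * c @ np.log(d) - b * np.sum(d**a)))


def neg_loglik_gradient(X, C: ContactMatrix, a: float, b: float) -> np.ndarray:
    """Analytic gradient of g with respect to the node coordinates.

    d g / d x_i = -a sum_{j != i} (c_ij - b d_ij^a) (x_i - x_j) / d_ij^2.
    """
    X = _as_curve(X)
    n = X.shape[0]
    d = squareform(_clamped_pdist(X))
    np.fill_diagonal(d, 1.0)  # dummy; the weight matrix diagonal is zeroed below
    W = (C.counts - b * d**a) / d**2
    np.fill_diagonal(W, 0.0)
    # row i of sum_j W_ij (x_i - x_j) = (W 1) * x_i - W X
    return -a * (W.sum(axis=1)[:, None] * X - W @ X)


def _gaps(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive gap vectors and their (clamped) lengths."""
    e = np.diff(X, axis=0)
    s = np.linalg.norm(e, axis=1)
    n_bad = int(np.count_nonzero(s < EPS_DIST))
    if n_bad:
        warnings.warn(
            f"{n_bad} zero-length gap(s) clamped at {EPS_DIST:g}",
            RuntimeWarning,
            stacklevel=3,
        )
        s = np.maximum(s, EPS_DIST)
    return e, s


def penalty_spacing(X) -> float:
    """Uniform-spacing penalty h1: variance of rescaled gap lengths.

    With u_i = (n-1) ||x_{i+1} - x_i|| / L(X) the gaps of the curve rescaled
    to total length n-1, the u_i average exactly 1 and

        h1(X) = (1 / (n-1)) sum_i (u_i - 1)^2.

    Invariant to scale, translation, rotation and reflection; zero iff all
    gaps are equal.
    """
    X = _as_curve(X)
    if X.shape[0] < 2:
        raise ValueError("spacing penalty needs at least 2 points")
    s = np.linalg.norm(np.diff(X, axis=0), axis=1)
    L = s.sum()
    if L <= 0:
        raise DegenerateCurveError("curve has zero length; h1 undefined")
    u = (len(s) / L) * s
    return float(np.mean((u - 1.0) ** 2))


def penalty_spacing_gradient(X) -> np.ndarray:
    """Analytic gradient of h1.

    Using dh1/ds_k = (2 / L) (u_k - 1 - h1), each gap's contribution is
    distributed onto its two endpoints along the unit gap direction.
    """
    X = _as_curve(X)
    e, s = _gaps(X)
    L = s.sum()
    if L <= 0:
        raise DegenerateCurveError("curve has zero length; h1 undefined")
    u = (len(s) / L) * s
    h1 = float(np.mean((u - 1.0) ** 2))
    coef = (2.0 / L) * (u - 1.0 - h1)  # dh1/ds_k
    unit = e / s[:, None]
    contrib = coef[:, None] * unit
    grad = np.zeros_like(X)
    grad[:-1] -= contrib
    grad[1:] += contrib
    return grad


def penalty_smoothness(X) -> float:
    """Smoothness penalty h2: mean cosine of the interior bend angles.

    h2 = (1/(n-2)) sum_{i=2}^{n-1} cos(theta_i), where theta_i is the angle
    at x_i formed with its two neighbours.  Ranges over [-1, 1]; -1 iff the
    chain is straight and monotone.
    """
    X = _as_curve(X)
    if X.shape[0] < 3:
        raise ValueError("smoothness penalty needs at least 3 points")
    _, s = _gaps(X)
    u = X[:-2] - X[1:-1]  # x_{i-1} - x_i
    v = X[2:] - X[1:-1]  # x_{i+1} - x_i
    cos = np.sum(u * v, axis=1) / (s[:-1] * s[1:])
    return float(np.mean(cos))


def penalty_smoothness_gradient(X) -> np.ndarray:
    """Analytic gradient of h2 via normalized-dot-product differentiation."""
    X = _as_curve(X)
    n = X.shape[0]
    if n < 3:
        raise ValueError("smoothness penalty needs at least 3 points")
    _, s = _gaps(X)
    u = X[:-2] - X[1:-1]
    v = X[2:] - X[1:-1]
    nu = s[:-1][:, None]
    nv = s[1:][:, None]
    cos = (np.sum(u * v, axis=1) / (s[:-1] * s[1:]))[:, None]
    dcdu = v / (nu * nv) - cos * u / nu**2
    dcdv = u / (nu * nv) - cos * v / nv**2
    grad = np.zeros_like(X)
    w = 1.0 / (n - 2)
    grad[:-2] += w * dcdu
    grad[2:] += w * dcdv
    grad[1:-1] -= w * (dcdu + dcdv)
    return grad


def effective_data(
    C: ContactMatrix, C_bulk: ContactMatrix | None, lambda3: float, b: float
) -> EffectiveData:
    """Absorb the bulk prior into the data.

    Returns C~ = C + (lambda3 M / M') C' and b~ = (1 + lambda3 M / M') b,
    so that g(X|C,a,b)/M + (lambda3/M') g(X|C',a,b) == g(X|C~,a,b~)/M.
    """
    if lambda3 < 0:
        raise ValueError("lambda3 must be >= 0")
    if lambda3 == 0 or C_bulk is None:
        if lambda3 > 0:
            raise ValueError("lambda3 > 0 requires a bulk matrix")
        return EffectiveData(C_tilde=C, b_tilde=float(b), k=0.0)
    if C_bulk.n != C.n:
        raise ValueError(
            f"bulk matrix has {C_bulk.n} bins but single-cell matrix has {C.n}"
        )
    if C_bulk.M <= 0:
        raise ValueError("bulk matrix has zero total count; prior undefined")
    k = lambda3 * C.M / C_bulk.M
    return EffectiveData(
        C_tilde=ContactMatrix(C.counts + k * C_bulk.counts),
        b_tilde=float((1.0 + k) * b),
        k=float(k),
    )


def energy(X, eff: EffectiveData, M: float, params: ModelParams) -> float:
    """Working objective E = g(X | C~, a, b~)/M + lambda1 h1 + lambda2 h2.

    ``M`` is the total count of the *original* single-cell matrix; the bulk
    prior is already inside ``eff``.
    """
    if M <= 0:
        raise ValueError("single-cell matrix has no contacts (M == 0)")
    E = neg_loglik(X, eff.C_tilde, params.a, eff.b_tilde) / M
    if params.lambda1 > 0:
        E += params.lambda1 * penalty_spacing(X)
    if params.lambda2 > 0:
        E += params.lambda2 * penalty_smoothness(X)
    return float(E)


def energy_gradient(X, eff: EffectiveData, M: float, params: ModelParams) -> np.ndarray:
    """Analytic gradient of the working objective, shape (n, 3)."""
    if M <= 0:
        raise ValueError("single-cell matrix has no contacts (M == 0)")
    g = neg_loglik_gradient(X, eff.C_tilde, params.a, eff.b_tilde) / M
    if params.lambda1 > 0:
        g = g + params.lambda1 * penalty_spacing_gradient(X)
    if params.lambda2 > 0:
        g = g + params.lambda2 * penalty_smoothness_gradient(X)
    return g
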