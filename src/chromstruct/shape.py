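"""Shape-space analysis: Procrustes alignment, RMSD, ensemble clustering.

Estimated curves are identified only up to scale, translation, rotation and
reflection (the likelihood cannot distinguish these), so comparisons are made
after a full similarity alignment.  ``align`` solves the orthogonal
Procrustes problem over the full orthogonal group with optimal scaling;
``pairwise_rmsd`` builds the symmetric solution-by-solution distance matrix
used to cluster an ensemble of local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class AlignmentResult:
    """Similarity transform T(x) = scale * rotation @ x + translation and its RMSD."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    rmsd: float


def _centered(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"curve must be (n, 3), got {X.shape}")
    return X - X.mean(axis=0)


def align(X, Y) -> AlignmentResult:
    """Optimally scale and rigidly align X onto Y; reflections allowed.

    Solves min over (s > 0, orthogonal R, t) of sum_i ||s R x_i + t - y_i||^2
    and returns the transform together with
    RMSD = sqrt(mean_i ||T(x_i) - y_i||^2).
    """
    Xc, Yc = _centered(X), _centered(Y)
    if Xc.shape != Yc.shape:
        raise ValueError("curves must have the same number of nodes")
    if Xc.shape[0] < 3:
        raise ValueError("need at least 3 nodes to align")
    nx = np.linalg.norm(Xc)
    if nx == 0 or np.linalg.norm(Yc) == 0:
        raise ValueError("cannot align a fully collapsed (zero-norm) curve")
    # full orthogonal group: no det(+1) correction, so reflections are free
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    scale = float(s.sum() / nx**2)
    aligned = scale * Xc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Yc) ** 2, axis=1))))
    X_mean = np.asarray(X, float).mean(axis=0)
    Y_mean = np.asarray(Y, float).mean(axis=0)
    return AlignmentResult(
        rotation=R,
        scale=scale,
        translation=Y_mean - scale * R @ X_mean,
        rmsd=rmsd,
    )


def rmsd_to_reference(X, ref) -> float:
    """RMSD of X optimally scaled and aligned onto a fixed reference curve."""
    return align(X, ref).rmsd


def _unit_normalized(X) -> np.ndarray:
    Xc = _centered(X)
    norm = np.linalg.norm(Xc)
    if norm == 0:
        raise ValueError("cannot normalize a collapsed curve")
    return Xc / norm


def pairwise_rmsd(curves) -> np.ndarray:
    """Symmetric pairwise RMSD matrix over an ensemble of solutions.

    Both curves of each pair are first rescaled to unit centered Frobenius
    norm; one-sided optimal scaling would otherwise make the comparison
    asymmetric.  The result is a symmetric premetric (zero diagonal,
    nonnegative); the triangle inequality is not guaranteed.
    """
    curves = [np.asarray(c, float) for c in curves]
    if len(curves) < 2:
        raise ValueError("need at least 2 solutions")
    n = curves[0].shape[0]
    if any(c.shape != (n, 3) for c in curves):
        raise ValueError("all curves must share the same shape (n, 3)")
    normed = [_unit_normalized(c) for c in curves]
    m = len(normed)
    D = np.zeros((m, m))
    for p in range(m):
        for q in range(p + 1, m):
            # after unit normalization the aligned distance is symmetric:
            # rmsd^2 = (1 - (sum of singular values)^2) / n
            s = np.linalg.svd(normed[q].T @ normed[p], compute_uv=False)
            D[p, q] = D[q, p] = np.sqrt(max(1.0 - s.sum() ** 2, 0.0) / n)
    return D


def cluster_solutions(
    D: np.ndarray, k: int | None = None, method: str = "average"
) -> tuple[np.ndarray, np.ndarray | None]:
    """Agglomerative clustering of a solution ensemble from its RMSD matrix.

    Returns the scipy linkage table (the dendrogram structure) and, when
    ``k`` is given, flat 1-based labels from cutting the tree at k clusters.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return Z, labels
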