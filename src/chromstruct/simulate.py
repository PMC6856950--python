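"""Synthetic ground-truth curves and Poisson-sampled Hi-C contact matrices.

The generator emulates a population of cells whose chromosomes share a common
mean conformation but exhibit coherent cell-to-cell shape variability.  Each
ground-truth curve is a smooth perturbation of a procedurally generated mean
curve; a single-cell contact matrix is then drawn from the Poisson power-law
link ``C_ij ~ Poisson(b d_ij^a)``, and a bulk matrix is formed by summing
single-cell matrices (optionally leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .energy import ContactMatrix

#: default coherent shape-variability level, as a fraction of the mean
#: curve's radius of gyration (smooth field amplitude, not per-node jitter)
DEFAULT_VARIABILITY = 0.15


@dataclass(frozen=True)
class GroundTruthEnsemble:
    """K ground-truth curves sharing a mean conformation.

    ``curves`` has shape (K, n, 3); ``variability`` scales the smooth
    perturbation fields relative to the mean curve's radius of gyration.
    """

    curves: np.ndarray
    mean_curve: np.ndarray
    variability: float
    seed: int

    @property
    def K(self) -> int:
        return self.curves.shape[0]

    @property
    def n(self) -> int:
        return self.curves.shape[1]


def _smooth_field(n: int, rng: np.random.Generator, n_modes: int) -> np.ndarray:
    """Random smooth (n, 3) field: low-frequency random-phase sinusoids.

    Amplitudes fall off as 1/frequency so the field is dominated by the
    lowest modes — coherent shape change rather than per-node noise.
    """
    t = np.linspace(0.0, 1.0, n)
    field = np.zeros((n, 3))
    for axis in range(3):
        freqs = np.arange(1, n_modes + 1)
        amps = rng.normal(size=n_modes) / freqs
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        field[:, axis] = np.sum(
            amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
            axis=0,
        )
    return field


def _radius_of_gyration(X: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(Xc**2, axis=1))))


#: self-avoidance floor: minimum distance between non-adjacent nodes, in
#: units of the mean gap length (excluded-volume realism of chromatin fiber)
MIN_SELF_DISTANCE = 0.8
#: per-cell curves may approach themselves somewhat closer than the mean
CELL_MIN_SELF_DISTANCE = 0.5
#: compactness cap: radius of gyration over mean gap (territory-like folding)
MAX_GYRATION_RATIO = 12.0


def _min_nonadjacent_distance(X: np.ndarray) -> float:
    """Smallest distance between nodes at least two positions apart."""
    D = squareform(pdist(X))
    n = len(X)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    return float(D[mask].min())


def generate_mean_curve(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth, self-avoiding mean curve with unit mean gap length.

    Built from 3-6 low-frequency sinusoids per coordinate plus a gentle
    monotone drift along the first axis, rescaled so adjacent points are one
    unit apart on average.  Candidates are rejection-sampled until the curve
    is self-avoiding (non-adjacent nodes at least ``MIN_SELF_DISTANCE`` gap
    units apart — chromatin has excluded volume) and compact
    (radius of gyration at most ``MAX_GYRATION_RATIO`` gap units, a
    territory-like fold rather than an extended thread).
    """
    best, best_score = None, -np.inf
    for _ in range(500):
        n_modes = int(rng.integers(3, 7))
        X = _smooth_field(n, rng, n_modes)
        X[:, 0] += np.linspace(0.0, 1.5, n)
        gaps = np.linalg.norm(np.diff(X, axis=0), axis=1)
        X /= gaps.mean()
        sep = _min_nonadjacent_distance(X)
        if sep >= MIN_SELF_DISTANCE and _radius_of_gyration(X) <= MAX_GYRATION_RATIO:
            return X
        if sep > best_score:
            best, best_score = X, sep
    return best  # most self-avoiding candidate seen


def generate_ground_truth_ensemble(
    n: int,
    K: int,
    variability: float = DEFAULT_VARIABILITY,
    seed: int = 0,
) -> GroundTruthEnsemble:
    """Generate K smooth ground-truth curves around a common mean.

    Each cell's curve is ``mean + variability * Rg(mean) * field_k`` where
    ``field_k`` is an independent smooth random field (unit-normalized).
    Fields are re-drawn (deterministically, from the cell's own substream)
    until the perturbed curve stays self-avoiding, so every cell is a
    physically plausible conformation.  One master seed spawns per-cell
    substreams, so cell k's curve does not change when K is increased.
    """
    if n < 10:
        raise ValueError("need n >= 10 nodes")
    if K < 1:
        raise ValueError("need K >= 1 curves")
    if variability < 0:
        raise ValueError("variability must be >= 0")
    master = np.random.SeedSequence(seed)
    mean_seq, cells_seq = master.spawn(2)
    mean = generate_mean_curve(n, np.random.default_rng(mean_seq))
    scale = variability * _radius_of_gyration(mean)
    curves = np.empty((K, n, 3))
    for k, seq in enumerate(cells_seq.spawn(K)):
        if variability == 0:
            curves[k] = mean
            continue
        rng = np.random.default_rng(seq)
        best, best_sep = None, -np.inf
        for _ in range(100):
            field = _smooth_field(n, rng, n_modes=3)
            field /= np.sqrt(np.mean(np.sum(field**2, axis=1)))
            cand = mean + scale * field
            sep = _min_nonadjacent_distance(cand)
            if sep >= CELL_MIN_SELF_DISTANCE:
                best = cand
                break
            if sep > best_sep:
                best, best_sep = cand, sep
        curves[k] = best
    return GroundTruthEnsemble(
        curves=curves, mean_curve=mean, variability=float(variability), seed=int(seed)
    )


def simulate_contact_matrix(
    X, a: float = -3.0, b: float = 1.0, seed: int = 0
) -> ContactMatrix:
    """Draw a single-cell contact matrix from C_ij ~ Poisson(b d_ij^a).

    Counts are drawn independently for j > i, mirrored to the lower
    triangle; the diagonal is zero.  Large ``b`` (say 1e6) yields dense
    matrices, small ``b`` (say 10) the sparsity typical of single cells.
    """
    X = np.asarray(X, dtype=float)
    if not (a < 0 and b > 0):
        raise ValueError("require a < 0 and b > 0")
    d = pdist(X)
    if np.any(d <= 0):
        raise ValueError("coincident points give an infinite Poisson mean")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(b * d**a)
    return ContactMatrix(squareform(counts))


def sum_bulk(
    matrices: list[ContactMatrix], exclude_index: int | None = None
) -> ContactMatrix:
    """Elementwise sum of single-cell matrices, optionally leave-one-out.

    The total count M' of the result is the sum of the members' M values
    (minus the excluded cell's).
    """
    if not matrices:
        raise ValueError("need at least one matrix to sum")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise ValueError("all matrices must share the same bin count")
    total = np.zeros((n, n))
    for i, m in enumerate(matrices):
        if exclude_index is not None and i == exclude_index:
            continue
        total += m.counts
    return ContactMatrix(total)
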