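"""Scripted simulation experiments: dense recovery, bulk-prior sweep,
multiscale comparison, ensemble clustering.

Each experiment generates its own ground truth and contact data, runs the
estimator under a fixed master seed, and returns a report whose summary
statistics are all recomputable from the per-run tables it carries.
Replication counts default to desk-scale sizes (documented in the methods
note); pass larger values for full-size runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ModelParams
from .multiscale import DEFAULT_MAX_ITER, estimate_structure
from .shape import cluster_solutions, pairwise_rmsd, rmsd_to_reference
from .simulate import (
    generate_ground_truth_ensemble,
    simulate_contact_matrix,
    sum_bulk,
)


def _child_seeds(seed: int, size: int) -> np.ndarray:
    """Deterministic stream of sub-seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=size)


def _radius_of_gyration(X: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(Xc**2, axis=1))))


@dataclass
class ExperimentReport:
    """Per-run table plus summary statistics and optional extra arrays."""

    name: str
    runs: pd.DataFrame
    summary: dict
    extras: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(outdir / f"{self.name}_runs.csv", index=False)
        pd.Series(self.summary).to_csv(outdir / f"{self.name}_summary.csv")
        for key, arr in self.extras.items():
            np.savetxt(outdir / f"{self.name}_{key}.csv", np.asarray(arr), delimiter=",")
        self._plot(outdir)

    def _plot(self, outdir: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if "rmsd" in self.runs and "energy" in self.runs:
            order = self.runs.sort_values("rmsd").reset_index()
            fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
            axes[0].plot(order["rmsd"].to_numpy(), ".")
            axes[0].set(xlabel="solution index (by RMSD)", ylabel="RMSD to truth")
            axes[1].plot(order["energy"].to_numpy(), ".")
            axes[1].set(xlabel="solution index (by RMSD)", ylabel="energy")
            fig.tight_layout()
            fig.savefig(outdir / f"{self.name}_rmsd_energy.png", dpi=120)
            plt.close(fig)
        if "pairwise_rmsd" in self.extras:
            fig, ax = plt.subplots(figsize=(4.5, 4))
            ax.imshow(self.extras["pairwise_rmsd"], cmap="viridis")
            ax.set(title="pairwise RMSD")
            fig.savefig(outdir / f"{self.name}_pairwise.png", dpi=120)
            plt.close(fig)
        if "lambda3" in self.runs.columns and "rmsd" in self.runs.columns:
            mean = self.runs.groupby("lambda3")["rmsd"].mean()
            fig, ax = plt.subplots(figsize=(4.5, 3.5))
            ax.plot(mean.index.to_numpy(), mean.to_numpy(), "o-")
            ax.set(xlabel="lambda3", ylabel="mean RMSD to truth")
            fig.tight_layout()
            fig.savefig(outdir / f"{self.name}_rmsd_vs_lambda3.png", dpi=120)
            plt.close(fig)


def run_dense_recovery(
    n: int = 100,
    b: float = 1e6,
    n_inits: int = 20,
    seed: int = 0,
    a: float = -3.0,
    lambda1: float = 0.001,
    lambda2: float = 0.001,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ExperimentReport:
    """Recovery from a dense contact matrix (high b, tiny penalty weights).

    Simulates one ground-truth curve and a dense matrix, runs ``n_inits``
    single-scale optimizations from independent random starts, and reports
    RMSD-to-truth, energies, and the pairwise solution RMSD matrix.  With
    ample data the best-of-ensemble solution should recover the truth to a
    small fraction of its radius of gyration; other local minima exhibit
    locally reflected substructures with near-equal energy but large RMSD.
    """
    seeds = _child_seeds(seed, 2 + n_inits)
    truth = generate_ground_truth_ensemble(n, K=1, seed=int(seeds[0])).curves[0]
    C = simulate_contact_matrix(truth, a=a, b=b, seed=int(seeds[1]))
    params = ModelParams(a=a, b=b, lambda1=lambda1, lambda2=lambda2, lambda3=0.0)
    rows, curves = [], []
    for i in range(n_inits):
        res = estimate_structure(
            C, params=params, seed=int(seeds[2 + i]), multiscale=False,
            max_iter=max_iter,
        )
        curves.append(res.curve)
        rows.append(
            {
                "init": i,
                "seed": int(seeds[2 + i]),
                "rmsd": rmsd_to_reference(res.curve, truth),
                "energy": res.energy,
            }
        )
    runs = pd.DataFrame(rows)
    rg = _radius_of_gyration(truth)
    summary = {
        "n": n,
        "b": b,
        "n_inits": n_inits,
        "radius_of_gyration": rg,
        "best_rmsd": float(runs["rmsd"].min()),
        "best_rmsd_over_rg": float(runs["rmsd"].min() / rg),
        "median_rmsd": float(runs["rmsd"].median()),
        "best_energy": float(runs["energy"].min()),
    }
    return ExperimentReport(
        name="dense_recovery",
        runs=runs,
        summary=summary,
        extras={"pairwise_rmsd": pairwise_rmsd(curves), "truth": truth},
    )


def run_prior_sweep(
    K: int = 100,
    lambda3_grid=(0.0, 0.1, 0.5, 1.0),
    n_cells: int = 8,
    n_inits: int = 5,
    b: float = 10.0,
    n: int = 100,
    seed: int = 0,
    a: float = -3.0,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ExperimentReport:
    """Bulk-prior benefit on sparse data: mean RMSD versus lambda3.

    K cells are simulated at low b (sparse matrices); the first ``n_cells``
    are reconstructed with a leave-one-out bulk prior over a grid of
    lambda3 values, ``n_inits`` random starts each.  Initialization seeds
    depend only on (cell, init), so the lambda3 = 0 column coincides with a
    no-prior run under the same seeds.
    """
    if 0.0 not in lambda3_grid:
        lambda3_grid = (0.0, *lambda3_grid)
    seeds = _child_seeds(seed, 1 + K + n_cells * n_inits)
    ens = generate_ground_truth_ensemble(n, K=K, seed=int(seeds[0]))
    cells = [
        simulate_contact_matrix(ens.curves[k], a=a, b=b, seed=int(seeds[1 + k]))
        for k in range(K)
    ]
    rows = []
    for ci in range(n_cells):
        bulk = sum_bulk(cells, exclude_index=ci)
        truth = ens.curves[ci]
        for lam3 in lambda3_grid:
            params = ModelParams(
                a=a, b=b, lambda1=lambda1, lambda2=lambda2, lambda3=float(lam3)
            )
            for j in range(n_inits):
                init_seed = int(seeds[1 + K + ci * n_inits + j])
                res = estimate_structure(
                    cells[ci],
                    C_bulk=bulk if lam3 > 0 else None,
                    params=params,
                    seed=init_seed,
                    multiscale=False,
                    max_iter=max_iter,
                )
                rows.append(
                    {
                        "cell": ci,
                        "lambda3": float(lam3),
                        "init": j,
                        "seed": init_seed,
                        "rmsd": rmsd_to_reference(res.curve, truth),
                        "energy": res.energy,
                    }
                )
    runs = pd.DataFrame(rows)
    mean_by_lam = runs.groupby("lambda3")["rmsd"].mean()
    summary = {
        "K": K,
        "b": b,
        "n_cells": n_cells,
        "n_inits": n_inits,
        "mean_rmsd_lambda3_0": float(mean_by_lam.loc[0.0]),
        "min_mean_rmsd": float(mean_by_lam.min()),
        "argmin_lambda3": float(mean_by_lam.idxmin()),
        "improvement": float(mean_by_lam.loc[0.0] - mean_by_lam.min()),
    }
    return ExperimentReport(name="prior_sweep", runs=runs, summary=summary)


def run_multiscale_comparison(
    n: int = 128,
    n_seeds: int = 10,
    seed: int = 0,
    b: float = 10.0,
    a: float = -3.0,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    min_n: int = 32,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ExperimentReport:
    """Paired flat-versus-multiscale comparison of final energies.

    One sparse problem is simulated; for each of ``n_seeds`` paired seeds
    the same random initialization seed drives both a single full-resolution
    optimization and the coarse-to-fine pipeline.  A positive mean of
    (flat energy - multiscale energy) means the multiscale approach reached
    lower-energy solutions.
    """
    seeds = _child_seeds(seed, 2 + n_seeds)
    truth = generate_ground_truth_ensemble(n, K=1, seed=int(seeds[0])).curves[0]
    C = simulate_contact_matrix(truth, a=a, b=b, seed=int(seeds[1]))
    params = ModelParams(a=a, b=b, lambda1=lambda1, lambda2=lambda2, lambda3=0.0)
    rows = []
    for i in range(n_seeds):
        s = int(seeds[2 + i])
        flat = estimate_structure(
            C, params=params, seed=s, multiscale=False, max_iter=max_iter
        )
        multi = estimate_structure(
            C, params=params, seed=s, multiscale=True, min_n=min_n, max_iter=max_iter
        )
        rows.append(
            {
                "seed": s,
                "energy_flat": flat.energy,
                "energy_multiscale": multi.energy,
                "difference": flat.energy - multi.energy,
            }
        )
    runs = pd.DataFrame(rows)
    summary = {
        "n": n,
        "n_seeds": n_seeds,
        "mean_difference": float(runs["difference"].mean()),
        "n_positive": int((runs["difference"] > 0).sum()),
        "n_negative": int((runs["difference"] < 0).sum()),
    }
    return ExperimentReport(name="multiscale_comparison", runs=runs, summary=summary)


def run_ensemble_clustering(
    n_cells: int = 3,
    n_inits: int = 10,
    n: int = 64,
    b: float = 1000.0,
    seed: int = 0,
    a: float = -3.0,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    min_n: int = 32,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ExperimentReport:
    """Cluster solutions from several cells in RMSD shape space.

    Distinct ground-truth curves (one per cell) are simulated; each cell's
    matrix is reconstructed from ``n_inits`` random starts.  The pooled
    solutions are clustered on the symmetric pairwise RMSD matrix; solutions
    from the same cell should land in the same cluster.
    """
    seeds = _child_seeds(seed, 1 + n_cells * (1 + n_inits))
    ens = generate_ground_truth_ensemble(n, K=n_cells, seed=int(seeds[0]))
    params = ModelParams(a=a, b=b, lambda1=lambda1, lambda2=lambda2, lambda3=0.0)
    curves, rows = [], []
    pos = 1
    for ci in range(n_cells):
        C = simulate_contact_matrix(ens.curves[ci], a=a, b=b, seed=int(seeds[pos]))
        pos += 1
        for j in range(n_inits):
            res = estimate_structure(
                C, params=params, seed=int(seeds[pos]), multiscale=True,
                min_n=min_n, max_iter=max_iter,
            )
            pos += 1
            curves.append(res.curve)
            rows.append({"cell": ci, "init": j, "energy": res.energy})
    D = pairwise_rmsd(curves)
    Z, labels = cluster_solutions(D, k=n_cells)
    runs = pd.DataFrame(rows)
    runs["cluster"] = labels
    true_labels = runs["cell"].to_numpy()
    # majority mapping: each cluster votes for its dominant cell of origin
    correct = 0
    for lab in np.unique(labels):
        members = true_labels[labels == lab]
        correct += int(np.bincount(members).max())
    within, between = [], []
    for p in range(len(curves)):
        for q in range(p + 1, len(curves)):
            (within if true_labels[p] == true_labels[q] else between).append(D[p, q])
    summary = {
        "n_cells": n_cells,
        "n_inits": n_inits,
        "majority_fraction": correct / len(curves),
        "within_cell_mean_rmsd": float(np.mean(within)),
        "between_cell_mean_rmsd": float(np.mean(between)),
    }
    return ExperimentReport(
        name="ensemble_clustering",
        runs=runs,
        summary=summary,
        extras={"pairwise_rmsd": D, "linkage": Z},
    )
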