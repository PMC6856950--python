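"""Readers and writers for contact matrices, curves, configs and result bundles.

Conventions
-----------
* Bin indices are **0-based** everywhere, including COO text files (Hi-C bin
  conventions vary between tools; this package is explicit about its own).
* Diagonal entries of contact matrices are zeroed on load with a warning —
  self-contacts carry no distance information and are ignored by the model.
* All formats are plain text: dense whitespace/comma grids, 3-column COO
  (``i j count``), CSV curves, pseudo-atom PDB for molecular viewers, JSON
  configs and result bundles.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ContactMatrix, ModelParams
from .multiscale import OptimizationResult

FORMAT_VERSION = "1"

CONFIG_DEFAULTS = {
    "a": -3.0,
    "b": 1.0,
    "lambda1": 0.5,
    "lambda2": 1.0,
    "lambda3": 0.1,
    "seed": 0,
    "min_n": 64,
    "multiscale": True,
    "bulk": None,
    "out": None,
}
CONFIG_REQUIRED = {"contacts"}
CONFIG_KEYS = CONFIG_REQUIRED | set(CONFIG_DEFAULTS)


def _load_table(path) -> np.ndarray:
    """Numeric table from whitespace- or comma-separated text."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"could not parse numeric table {path}: {exc}") from exc
    return arr


def read_contact_matrix(path, format: str = "dense") -> ContactMatrix:
    """Load a contact matrix from dense-grid or COO three-column text.

    Dense input must be square and symmetric; COO input lists
    ``i j count`` triples (0-based, upper triangle is sufficient — entries
    are mirrored).  Nonzero diagonal entries are zeroed with a warning.
    """
    arr = _load_table(path)
    if format == "dense":
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(
                f"dense contact matrix must be square, got {arr.shape} in {path}"
            )
        counts = arr
    elif format == "coo":
        if arr.shape[1] != 3:
            raise ValueError(f"COO file must have 3 columns, got {arr.shape[1]}")
        i, j, c = arr[:, 0], arr[:, 1], arr[:, 2]
        if np.any(i != np.round(i)) or np.any(j != np.round(j)):
            raise ValueError("COO indices must be integers")
        i, j = i.astype(int), j.astype(int)
        if np.any(i < 0) or np.any(j < 0):
            raise ValueError("COO indices must be >= 0 (0-based)")
        if np.any(c < 0):
            raise ValueError("negative contact counts")
        n = int(max(i.max(), j.max())) + 1
        counts = np.zeros((n, n))
        np.add.at(counts, (i, j), c)
        np.add.at(counts, (j, i), c)
        counts[np.diag_indices(n)] /= 2.0  # i==j rows were added twice
    else:
        raise ValueError(f"unknown format {format!r}; use 'dense' or 'coo'")
    if np.any(np.diag(counts) != 0):
        warnings.warn(
            f"nonzero diagonal entries in {path} zeroed (self-contacts ignored)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ContactMatrix(counts)  # zeroes diagonal, checks symmetry/sign


def write_contact_matrix(C: ContactMatrix, path, format: str = "dense") -> None:
    path = Path(path)
    if format == "dense":
        np.savetxt(path, C.counts, fmt="%.10g")
    elif format == "coo":
        i, j = np.nonzero(np.triu(C.counts, k=1))
        np.savetxt(
            path, np.column_stack([i, j, C.counts[i, j]]), fmt=["%d", "%d", "%.10g"]
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def write_curve(X, path, format: str = "csv") -> None:
    """Write a curve as CSV (``index,x,y,z``) or as pseudo-atom PDB.

    The PDB output places one CA pseudo-atom per node on a single chain with
    sequential residue numbers, coordinates rescaled to fit the fixed-width
    coordinate columns, for viewing in standard molecular viewers.
    """
    X = np.asarray(X, dtype=float)
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(X, columns=["x", "y", "z"])
        df.insert(0, "index", np.arange(len(X)))
        df.to_csv(path, index=False, float_format="%.12g")
    elif format == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        coords = X - X.mean(axis=0)
        extent = np.abs(coords).max()
        if extent > 0:
            coords = coords * (100.0 / extent)  # stay well inside %8.3f columns
        atoms = struc.AtomArray(len(X))
        atoms.coord = coords
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = np.arange(1, len(X) + 1)
        atoms.res_name[:] = "GLY"
        atoms.atom_name[:] = "CA"
        atoms.element[:] = "C"
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'pdb'")


def read_curve(path) -> np.ndarray:
    """Read a CSV curve written by :func:`write_curve`, order preserved."""
    df = pd.read_csv(path)
    if not {"index", "x", "y", "z"} <= set(df.columns):
        raise ValueError(f"{path} is not a curve CSV (need index,x,y,z columns)")
    df = df.sort_values("index")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def load_config(path) -> dict:
    """Load and validate a JSON run configuration, filling defaults.

    Required: ``contacts``.  Optional with defaults: ``bulk``, ``a``, ``b``,
    ``lambda1``..``lambda3``, ``seed``, ``min_n``, ``multiscale``, ``out``.
    Unknown keys are an error, as are a >= 0 and lambda3 > 0 without a bulk
    path.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(raw) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = CONFIG_REQUIRED - set(raw)
    if missing:
        raise ValueError(f"missing required config keys: {sorted(missing)}")
    cfg = {**CONFIG_DEFAULTS, **{k: v for k, v in raw.items() if v is not None}}
    if not isinstance(cfg["multiscale"], bool):
        raise ValueError("multiscale must be a boolean")
    for key in ("a", "b", "lambda1", "lambda2", "lambda3"):
        cfg[key] = float(cfg[key])
    cfg["seed"] = int(cfg["seed"])
    cfg["min_n"] = int(cfg["min_n"])
    if cfg["a"] >= 0:
        raise ValueError("power-law exponent a must be < 0")
    if cfg["b"] <= 0:
        raise ValueError("Poisson scale b must be > 0")
    if any(cfg[k] < 0 for k in ("lambda1", "lambda2", "lambda3")):
        raise ValueError("penalty weights must be >= 0")
    if cfg["lambda3"] > 0 and not cfg["bulk"]:
        raise ValueError("lambda3 > 0 requires a bulk contact matrix path")
    return cfg


def params_from_config(cfg: dict) -> ModelParams:
    return ModelParams(
        a=cfg["a"],
        b=cfg["b"],
        lambda1=cfg["lambda1"],
        lambda2=cfg["lambda2"],
        lambda3=cfg["lambda3"],
    )


def save_result_bundle(
    result: OptimizationResult, params: ModelParams, path
) -> None:
    """Write a self-describing JSON bundle: curve, energies, full parameters."""
    bundle = {
        "format_version": FORMAT_VERSION,
        "params": {
            "a": params.a,
            "b": params.b,
            "lambda1": params.lambda1,
            "lambda2": params.lambda2,
            "lambda3": params.lambda3,
        },
        "seed": result.seed,
        "sizes": list(result.sizes),
        "energy": result.energy,
        "energy_per_scale": list(result.energy_per_scale),
        "iterations_per_scale": list(result.iterations_per_scale),
        "converged": result.converged,
        "curve": np.asarray(result.curve).tolist(),
    }
    Path(path).write_text(json.dumps(bundle, indent=1))


def load_result_bundle(path) -> tuple[OptimizationResult, ModelParams]:
    bundle = json.loads(Path(path).read_text())
    if bundle.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported bundle version {bundle.get('format_version')!r}")
    params = ModelParams(**bundle["params"])
    result = OptimizationResult(
        curve=np.asarray(bundle["curve"], dtype=float),
        energy=float(bundle["energy"]),
        energy_per_scale=[float(e) for e in bundle["energy_per_scale"]],
        iterations_per_scale=[int(i) for i in bundle["iterations_per_scale"]],
        sizes=[int(s) for s in bundle["sizes"]],
        seed=bundle["seed"],
        converged=bool(bundle["converged"]),
    )
    return result, params
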