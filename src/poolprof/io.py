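"""Reading and writing datasets and fit reports.

Matrices travel as CSV (samples as rows by default; a flag accepts the
transposed genes-as-rows layout).  Fit reports are JSON: structured,
diff-able, and consumed by the overlap test and composition prediction.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import FitResult
from .model import ModelSpec, ParameterSet, PooledDataset


def file_digest(path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_pool_sizes(spec, k: int) -> np.ndarray:
    """Pool sizes from a constant (int / numeric string) or a one-column CSV."""
    try:
        n = int(spec)
        return np.full(k, n, dtype=int)
    except (TypeError, ValueError):
        pass
    vec = pd.read_csv(spec, header=None).to_numpy().ravel().astype(int)
    if vec.size != k:
        raise ValueError(
            f"pool-size file has {vec.size} entries but the matrix has {k} samples"
        )
    return vec


def read_expression_matrix(
    path, pool_sizes, genes_as_rows: bool = False
) -> PooledDataset:
    """Read a pooled expression CSV into a dataset.

    The on-disk file has samples as rows and genes as columns (header row of
    gene names); pass ``genes_as_rows=True`` for the transposed m x k
    convention.  ``pool_sizes`` is a constant or a one-column CSV path.
    """
    df = pd.read_csv(path)
    if genes_as_rows:
        df = df.set_index(df.columns[0]).T if df.dtypes.iloc[0] == object else df.T
    names = [str(c) for c in df.columns]
    y = df.to_numpy(dtype=float)
    n = read_pool_sizes(pool_sizes, y.shape[0])
    return PooledDataset(y=y, n=n, gene_names=names)


def write_dataset(data: PooledDataset, prefix) -> dict[str, Path]:
    """Write a dataset as CSVs: matrix, pool sizes, and (if simulated) the
    latent compositions.  Returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    matrix = prefix.with_suffix(".csv")
    pd.DataFrame(data.y, columns=data.gene_names).to_csv(matrix, index=False)
    paths["matrix"] = matrix
    npath = prefix.parent / (prefix.name + "_n.csv")
    pd.DataFrame(data.n).to_csv(npath, index=False, header=False)
    paths["pool_sizes"] = npath
    if data.latent_compositions is not None:
        cpath = prefix.parent / (prefix.name + "_compositions.csv")
        T = data.latent_compositions.shape[1]
        pd.DataFrame(
            data.latent_compositions, columns=[f"pop{h + 1}" for h in range(T)]
        ).to_csv(cpath, index=False)
        paths["compositions"] = cpath
    return paths


def fit_report_dict(
    fit: FitResult, data: PooledDataset, input_digest: str | None = None
) -> dict:
    theta = fit.theta_hat
    return {
        "software": "poolprof",
        "version": __version__,
        "family": fit.spec.family,
        "T": fit.spec.T,
        "m": fit.spec.m,
        "k": data.k,
        "total_cells": int(data.n.sum()),
        "p": theta.p.tolist(),
        "mu": theta.mu.tolist(),
        "sigma": theta.sigma.tolist(),
        "rate": None if theta.rate is None else theta.rate.tolist(),
        "loglik": fit.loglik,
        "bic": fit.bic,
        "ci": {name: list(b) for name, b in fit.ci.items()},
        "seed": fit.seed,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "trace": [[int(i), float(v)] for i, v in fit.trace],
        "input_digest": input_digest,
    }


def write_fit_report(
    fit: FitResult, path, data: PooledDataset, input_digest: str | None = None
) -> None:
    """Serialize a fit to JSON (missing CI bounds become explicit nulls)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fit_report_dict(fit, data, input_digest), fh, indent=2)
        fh.write("\n")


def read_fit_report(path) -> dict:
    """Load a fit report; numeric arrays come back as numpy arrays."""
    with open(path) as fh:
        rep = json.load(fh)
    rep["p"] = np.asarray(rep["p"], dtype=float)
    rep["mu"] = np.atleast_2d(np.asarray(rep["mu"], dtype=float))
    rep["sigma"] = np.asarray(rep["sigma"], dtype=float)
    if rep.get("rate") is not None:
        rep["rate"] = np.asarray(rep["rate"], dtype=float)
    return rep


def report_spec(rep: dict) -> ModelSpec:
    return ModelSpec(rep["family"], int(rep["T"]), int(rep["m"]))


def report_theta(rep: dict) -> ParameterSet:
    return ParameterSet(
        p=rep["p"], mu=rep["mu"], sigma=rep["sigma"], rate=rep.get("rate")
    )
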