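"""On-disk formats: headerless CSV matrices, TSV edge lists, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import PrecisionEstimate
from .models import BipartiteModel, EdgeSet, ThresholdedGeneModel

__all__ = [
    "save_matrix_csv", "load_matrix_csv",
    "save_edges_tsv", "load_edges_tsv",
    "save_model_bundle", "save_estimate",
    "write_table",
]

_FLOAT_FMT = "%.12g"


def save_matrix_csv(path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(M), fmt=_FLOAT_FMT, delimiter=",")


def load_matrix_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_edges_tsv(path, edges: EdgeSet) -> None:
    df = pd.DataFrame(edges.to_array(), columns=["node_i", "node_j"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_edges_tsv(path, p: int) -> EdgeSet:
    df = pd.read_csv(path, sep="\t")
    return EdgeSet.from_pairs(p, df[["node_i", "node_j"]].itertuples(index=False))


def save_model_bundle(directory, model) -> None:
    """Write C.csv, omega_star.csv, support.tsv and meta.json for a model."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if isinstance(model, BipartiteModel):
        meta = {
            "family": "bipartite", "d1": model.d1, "d2": model.d2,
            "sigma_x2": model.sigma_x2, "sigma_eps2": model.sigma_eps2,
            "seed": model.seed,
        }
        save_matrix_csv(d / "A.csv", model.A)
        omega = model.Omega_star
    elif isinstance(model, ThresholdedGeneModel):
        meta = {
            "family": "genelike", "d": model.Lambda.shape[0], "delta": model.delta,
            "zero_fraction": model.zero_fraction, "seed": model.seed,
            "n_retries": model.n_retries,
        }
        omega = model.Lambda
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    save_matrix_csv(d / "C.csv", model.C)
    save_matrix_csv(d / "omega_star.csv", omega)
    save_edges_tsv(d / "support.tsv", model.support)
    (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def save_estimate(directory, est: PrecisionEstimate, settings=None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_matrix_csv(d / "omega_hat.csv", est.Omega_hat)
    meta = {
        "method": est.method, "lam": est.lam, "converged": bool(est.converged),
        "n_iter": int(est.n_iter), "kkt_residual": float(est.kkt_residual),
        "penalise_diagonal": est.penalise_diagonal,
    }
    if settings is not None:
        meta["settings"] = {"tol": settings.tol, "max_iter": settings.max_iter,
                            "zero_tol": settings.zero_tol}
    (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def write_table(path, df: pd.DataFrame) -> None:
    """Deterministic CSV writer (fixed float format, unix newlines)."""
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
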