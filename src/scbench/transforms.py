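"""Composable, serializable preprocessing pipeline.

Each transform is a pure function ``SCDataset -> SCDataset`` identified by a
name and a flat parameter map, so a whole pipeline round-trips through JSON
bit-exactly.  The model registry maps every model name to its documented
default pipeline (clustering models, for example, use
filter -> library-size normalization -> log1p -> top-3000 gene selection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import SCDataset, ValidationError, _densify


@dataclass(frozen=True)
class Transform:
    name: str
    params: dict = field(default_factory=dict)

    def apply(self, ds: SCDataset) -> SCDataset:
        if self.name not in _TRANSFORMS:
            raise KeyError(f"unknown transform {self.name!r}")
        return _TRANSFORMS[self.name](ds, **self.params)


@dataclass
class Pipeline:
    steps: list

    def apply(self, ds: SCDataset) -> SCDataset:
        return apply_pipeline(self, ds)

    def to_json(self) -> str:
        return json.dumps({"steps": [{"name": s.name, "params": s.params}
                                     for s in self.steps]})

    @classmethod
    def from_json(cls, text: str) -> "Pipeline":
        obj = json.loads(text)
        return cls([Transform(s["name"], dict(s["params"])) for s in obj["steps"]])


def apply_pipeline(p: Pipeline, ds: SCDataset) -> SCDataset:
    out = ds
    for i, step in enumerate(p.steps):
        try:
            out = step.apply(out)
        except Exception as e:
            raise type(e)(f"pipeline step {i} ({step.name}): {e}") from e
    return out


# -- individual transforms ----------------------------------------------

def filter_features(ds: SCDataset, min_cells_expressing: int = 3,
                    axis: str = "genes", min_counts: int = 0) -> SCDataset:
    """Drop rarely expressed genes (or sparse cells).

    For ``axis="genes"`` keeps genes with a nonzero value in at least
    ``min_cells_expressing`` cells and total counts >= ``min_counts``;
    symmetric for cells.
    """
    if min_cells_expressing < 0 or min_counts < 0:
        raise ValueError("thresholds must be >= 0")
    X = ds.dense()
    if axis == "genes":
        n_expr = (X > 0).sum(axis=0)
        totals = X.sum(axis=0)
        keep = np.flatnonzero((n_expr >= min_cells_expressing) & (totals >= min_counts))
        if keep.size == 0:
            raise ValidationError("filter would remove every gene")
        out = ds.subset(gene_idx=keep)
    elif axis == "cells":
        n_expr = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
        keep = np.flatnonzero((n_expr >= min_cells_expressing) & (totals >= min_counts))
        if keep.size == 0:
            raise ValidationError("filter would remove every cell")
        out = ds.subset(cell_idx=keep)
    else:
        raise ValueError("axis must be 'genes' or 'cells'")
    return out.with_log("filter_features", min_cells_expressing=min_cells_expressing,
                        axis=axis, min_counts=min_counts)


def normalize_total(ds: SCDataset, target_sum: float = 1e4) -> SCDataset:
    """Scale each cell to the same total count; result stored in layer 'normalized'."""
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    X = ds.dense().astype(np.float64)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("all-zero cell present; run filter_features first")
    Xn = X * (target_sum / totals)[:, None]
    out = ds.copy()
    out.X = Xn
    out.layers["normalized"] = Xn.copy()
    return out.with_log("normalize_total", target_sum=target_sum)


def log1p(ds: SCDataset) -> SCDataset:
    out = ds.copy()
    out.X = np.log1p(_densify(out.X))
    return out.with_log("log1p")


def select_top_genes(ds: SCDataset, k: int = 3000) -> SCDataset:
    """Keep the k genes with largest total counts (ties broken by gene id).

    Ranking uses total raw counts when a raw layer is present so that the
    selection is independent of upstream normalization.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= ds.n_genes:
        return ds.copy().with_log("select_top_genes", k=k)
    totals = ds.raw().sum(axis=0)
    order = sorted(range(ds.n_genes), key=lambda j: (-totals[j], ds.gene_ids[j]))
    keep = np.sort(np.asarray(order[:k]))
    return ds.subset(gene_idx=keep).with_log("select_top_genes", k=k)


def zscore_scale(ds: SCDataset, clip: float = 10.0) -> SCDataset:
    """Per-gene standardization (population variance); zero-variance genes -> 0."""
    if ds.n_cells < 2:
        raise ValueError("need >= 2 cells")
    X = ds.dense().astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out = ds.copy()
    out.X = np.clip(Z, -clip, clip)
    out.layers.pop("raw", None)  # scaled values are no longer counts
    return out.with_log("zscore_scale", clip=clip)


def pca_embed(ds: SCDataset, d: int, seed: int = 0) -> np.ndarray:
    """PCA embedding (cells x d) with a deterministic sign convention.

    Components are ordered by decreasing explained variance; within each
    component the loading of largest magnitude is made positive, so the
    output is identical across runs and seeds.
    """
    if not 1 <= d <= min(ds.n_cells, ds.n_genes):
        raise ValueError(f"d must be in [1, {min(ds.shape)}]")
    X = ds.dense().astype(np.float64)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(d):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return U[:, :d] * S[:d]


_TRANSFORMS = {
    "filter_features": filter_features,
    "normalize_total": normalize_total,
    "log1p": log1p,
    "select_top_genes": select_top_genes,
    "zscore_scale": zscore_scale,
}


# -- per-model defaults --------------------------------------------------

_COUNT_PIPELINE = [
    Transform("filter_features", {"min_cells_expressing": 3, "axis": "genes",
                                  "min_counts": 0}),
    Transform("normalize_total", {"target_sum": 1e4}),
    Transform("log1p", {}),
    Transform("select_top_genes", {"k": 3000}),
]

_LINEAR_PIPELINE = [
    Transform("filter_features", {"min_cells_expressing": 3, "axis": "genes",
                                  "min_counts": 0}),
    Transform("normalize_total", {"target_sum": 1e4}),
]

_DEFAULT_PIPELINES = {
    # clustering
    "zinb_dec": _COUNT_PIPELINE,
    "zinb_dec_constrained": _COUNT_PIPELINE,
    "graph_ae_cluster": _COUNT_PIPELINE,
    # annotation
    "logreg": _COUNT_PIPELINE,
    "mlp": _COUNT_PIPELINE,
    "gnn_annotator": _COUNT_PIPELINE,
    # imputation (pipelines are applied to the masked working matrix)
    "block_mlp_imputer": [Transform("normalize_total", {"target_sum": 1e4}),
                          Transform("log1p", {})],
    "graph_ae_imputer": [Transform("normalize_total", {"target_sum": 1e4}),
                         Transform("log1p", {})],
    # deconvolution: linear-scale solvers, no log transform
    "nnls_deconv": _LINEAR_PIPELINE,
    "seeded_nmf_deconv": _LINEAR_PIPELINE,
}


def registered_models() -> list:
    return sorted(_DEFAULT_PIPELINES)


def default_pipeline(model_name: str) -> Pipeline:
    """The documented default preprocessing for a registered model."""
    if model_name not in _DEFAULT_PIPELINES:
        raise KeyError(
            f"unknown model {model_name!r}; registered: {', '.join(registered_models())}")
    return Pipeline([Transform(s.name, dict(s.params)) for s in _DEFAULT_PIPELINES[model_name]])
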