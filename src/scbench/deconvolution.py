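"""Spatial cell-type deconvolution scored by MSE on known proportions.

A signature matrix S (genes x types) is built from a labeled scRNA-seq
reference as per-type means of library-size-normalized expression restricted
to fold-change-ranked marker genes.  Two solvers estimate per-spot
proportions beta on the simplex:

* ``nnls_deconvolve`` — per-spot non-negative least squares
  min_{beta >= 0} ||y - S beta||^2 (Lawson-Hanson active set), optionally
  iteratively reweighted by 1/(y_g + eps)^2 to approximate a log-normal
  multiplicative error model;
* ``seeded_nmf_deconvolve`` — rank-K NMF of the reference by multiplicative
  updates, W seeded from the signature columns so topics stay identified
  with cell types, followed by NNLS of each spot onto the final W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _nnls

from .data import SCDataset

_EPS = 1e-10
_TARGET_SUM = 1e4


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference profiles."""

    S: np.ndarray
    gene_ids: list
    type_names: list

    def __post_init__(self):
        self.S = np.asarray(self.S, float)
        if self.S.shape != (len(self.gene_ids), len(self.type_names)):
            raise ValueError("signature shape does not match ids")
        if np.any(self.S < 0):
            raise ValueError("signature must be non-negative")
        if np.any(self.S.sum(axis=0) == 0):
            raise ValueError("signature has an all-zero cell-type column")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature gene ids not unique")


@dataclass
class ProportionMatrix:
    """Spots x types proportions; every row on the simplex."""

    P: np.ndarray
    spot_ids: list
    type_names: list

    def __post_init__(self):
        self.P = np.asarray(self.P, float)
        if np.any(self.P < -1e-12):
            raise ValueError("proportions must be >= 0")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")


@dataclass(frozen=True)
class NMFConfig:
    seed: int = 0
    n_iter: int = 200


def build_signature(reference: SCDataset, n_markers: int = 50) -> SignatureMatrix:
    """Per-type mean normalized expression on fold-change-ranked marker genes.

    Markers per type are the ``n_markers`` genes with highest ratio of the
    type's mean to the mean of all other types (eps-stabilized); the
    signature keeps the union across types.  Ties break by gene id.
    """
    labels = reference.cell_table["cell_type"].to_numpy()
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("reference needs >= 2 cell types")
    for t in types:
        if (labels == t).sum() < 3:
            raise ValueError(f"type {t!r} has fewer than 3 cells")
    raw = reference.raw().astype(float)
    totals = raw.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("reference contains an all-zero cell")
    norm = raw * (_TARGET_SUM / totals)[:, None]
    means = np.stack([norm[labels == t].mean(axis=0) for t in types])  # K x g
    g = reference.n_genes
    if n_markers >= g:
        keep = np.arange(g)
    else:
        marker_set = set()
        for k in range(len(types)):
            other = means[[j for j in range(len(types)) if j != k]].mean(axis=0)
            fc = (means[k] + _EPS) / (other + _EPS)
            order = sorted(range(g), key=lambda j: (-fc[j], reference.gene_ids[j]))
            marker_set.update(order[:n_markers])
        keep = np.sort(np.fromiter(marker_set, dtype=int))
    return SignatureMatrix(S=means[:, keep].T, gene_ids=[reference.gene_ids[j] for j in keep],
                           type_names=list(types))


def _align_spots(spots, sig: SignatureMatrix):
    if isinstance(spots, SCDataset):
        idx = []
        pos = {gid: j for j, gid in enumerate(spots.gene_ids)}
        missing = [gid for gid in sig.gene_ids if gid not in pos]
        if missing:
            raise ValueError(f"spot matrix lacks signature genes: {missing[:10]}")
        idx = [pos[gid] for gid in sig.gene_ids]
        Y = spots.dense()[:, idx]
        spot_ids = list(spots.cell_ids)
    else:
        Y = np.asarray(spots, float)
        if Y.shape[1] != len(sig.gene_ids):
            raise ValueError(
                f"spot matrix has {Y.shape[1]} genes; signature expects {len(sig.gene_ids)}")
        spot_ids = [f"spot{i}" for i in range(Y.shape[0])]
    if np.any(Y < 0):
        raise ValueError("spot matrix must be non-negative")
    return Y, spot_ids


def _simplex(beta: np.ndarray) -> np.ndarray:
    s = beta.sum()
    if s <= 0:
        warnings.warn("all-zero NNLS solution; returning a uniform row")
        return np.full(beta.shape, 1.0 / len(beta))
    return beta / s


def nnls_deconvolve(spots, sig: SignatureMatrix, log_weighting: bool = False) -> ProportionMatrix:
    """Per-spot NNLS of expression onto the signature, normalized to the simplex.

    With ``log_weighting`` the solve is iteratively reweighted (3 rounds) with
    per-gene weights 1/(y_g + eps)^2, approximating multiplicative
    (log-normal) measurement error.
    """
    Y, spot_ids = _align_spots(spots, sig)
    S = sig.S
    P = np.empty((Y.shape[0], S.shape[1]))
    for i, y in enumerate(Y):
        beta, _res = _nnls(S, y)
        if log_weighting:
            # IRLS: weights 1/(fitted + 1)^2 approximate log-normal error;
            # the +1 floor keeps zero-count genes from dominating
            for _ in range(3):
                d = 1.0 / (S @ beta + 1.0)
                beta, _res = _nnls(S * d[:, None], y * d)
        P[i] = _simplex(beta)
    return ProportionMatrix(P=P, spot_ids=spot_ids, type_names=list(sig.type_names))


def _nnls_columns(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """NNLS of each column of V onto W; returns K x n_cols coefficients."""
    H = np.empty((W.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        H[:, j], _ = _nnls(W, V[:, j])
    return H


def nmf_objective(V, W, H) -> float:
    return float(0.5 * np.sum((V - W @ H) ** 2))


def seeded_nmf_deconvolve(reference: SCDataset, spots, sig: SignatureMatrix,
                          cfg: NMFConfig = NMFConfig()) -> ProportionMatrix:
    """Signature-seeded NMF regression for spot proportions.

    The reference (genes x cells, library-size normalized, restricted to the
    signature genes) is factorized as V ~ W H by Frobenius multiplicative
    updates with W initialized from the signature columns and H from NNLS of
    the reference onto W, so topic k stays identified with cell type k.
    Because multiplicative updates let topics drift from their seeds, spots
    are not read off W directly: each spot's NNLS topic loadings are matched
    against the per-type mean topic profiles of the reference cells (a second
    NNLS), which restores the topic-to-type identification.  The factorization
    objective is non-increasing over updates.
    """
    raw = reference.raw().astype(float)
    totals = raw.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("reference contains an all-zero cell")
    norm = raw * (_TARGET_SUM / totals)[:, None]
    pos = {gid: j for j, gid in enumerate(reference.gene_ids)}
    missing = [gid for gid in sig.gene_ids if gid not in pos]
    if missing:
        raise ValueError(f"reference lacks signature genes: {missing[:10]}")
    V = norm[:, [pos[gid] for gid in sig.gene_ids]].T  # genes x cells
    W = np.maximum(sig.S.copy(), _EPS)
    H = np.maximum(_nnls_columns(V, W), _EPS)
    objectives = [nmf_objective(V, W, H)]
    for _ in range(cfg.n_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        objectives.append(nmf_objective(V, W, H))

    # per-type topic profiles: mean simplex-normalized topic loading of the
    # reference cells of each type, in signature type order
    labels = reference.cell_table["cell_type"].to_numpy()
    Hn = H / H.sum(axis=0, keepdims=True)
    Q = np.stack([Hn[:, labels == t].mean(axis=1) for t in sig.type_names]).T

    Y, spot_ids = _align_spots(spots, sig)
    P = np.empty((Y.shape[0], len(sig.type_names)))
    for i, y in enumerate(Y):
        gamma, _ = _nnls(W, y)
        gsum = gamma.sum()
        if gsum <= 0:
            P[i] = np.full(P.shape[1], 1.0 / P.shape[1])
            warnings.warn("all-zero topic loading; returning a uniform row")
            continue
        beta, _ = _nnls(Q, gamma / gsum)
        P[i] = _simplex(beta)
    out = ProportionMatrix(P=P, spot_ids=spot_ids, type_names=list(sig.type_names))
    out.objectives = objectives
    return out


def score_deconvolution(pred: ProportionMatrix, truth: ProportionMatrix) -> float:
    """MSE over all spot x type proportion entries (type order must agree)."""
    if list(pred.type_names) != list(truth.type_names):
        raise ValueError(f"type order mismatch: {pred.type_names} vs {truth.type_names}")
    if pred.P.shape != truth.P.shape:
        raise ValueError("proportion shapes differ")
    return float(np.mean((pred.P - truth.P) ** 2))
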