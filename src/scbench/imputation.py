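"""Simulated-dropout benchmarking and two imputers scored by masked MSE.

Dropouts are simulated by zeroing a fraction of the nonzero raw counts; the
original values are held out and never touched by training.  Evaluation is
on the library-size-normalized, log1p scale: the truth matrix is the
transform of the unmasked counts, and the mean squared error is taken over
the masked positions only.  A per-gene-mean imputer provides the floor any
model has to beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .data import MaskedDataset, SCDataset
from .graphs import cell_gene_graph, normalize_adjacency
from .metrics import masked_mse

_TARGET_SUM = 1e4


@dataclass(frozen=True)
class ImputerConfig:
    seed: int = 0
    lr: float = 5e-3          # block-MLP learning rate
    epochs: int = 300         # block-MLP epochs
    block_size: int = 256
    n_predictors: int = 5     # top-|r| predictor genes per target
    hidden: int = 64          # block-MLP hidden width
    graph_hidden: int = 128   # graph-AE hidden width
    latent_dim: int = 64      # graph-AE embedding dimension
    graph_lr: float = 1e-2
    graph_epochs: int = 300


def mask_nonzero_entries(ds: SCDataset, fraction: float, seed: int = 0) -> MaskedDataset:
    """Simulate dropouts: zero floor(fraction * nnz) random nonzero raw entries."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    raw = ds.raw()
    rows, cols = np.nonzero(raw)
    nnz = len(rows)
    if nnz == 0:
        raise ValueError("matrix has no nonzero entries to mask")
    n_mask = max(1, int(np.floor(fraction * nnz)))
    rng = np.random.default_rng(seed)
    take = rng.choice(nnz, size=n_mask, replace=False)
    mask = np.zeros(raw.shape, dtype=bool)
    mask[rows[take], cols[take]] = True
    held_out = {(int(i), int(j)): float(raw[i, j]) for i, j in zip(rows[take], cols[take])}
    base = ds.copy()
    new_raw = raw.copy()
    new_raw[mask] = 0.0
    base.X = new_raw.copy()
    base.layers = {"raw": new_raw.copy()}
    base.with_log("mask_nonzero_entries", fraction=fraction, seed=seed)
    return MaskedDataset(base=base, mask=mask, held_out=held_out)


def _normalized_log(raw: np.ndarray) -> np.ndarray:
    totals = raw.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("all-zero cell; masking fraction too aggressive for this data")
    return np.log1p(raw * (_TARGET_SUM / totals)[:, None])


def working_matrix(mds: MaskedDataset) -> np.ndarray:
    """Masked counts on the evaluation scale (normalized + log1p)."""
    return _normalized_log(mds.base.raw())


def truth_matrix(mds: MaskedDataset) -> np.ndarray:
    """Held-out counts restored, on the evaluation scale.

    The per-cell normalization factors of the *working* (masked) matrix are
    reused so that truth and working values agree exactly at every unmasked
    entry; only the masked positions differ.
    """
    raw = mds.base.raw()
    totals = raw.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("all-zero cell; masking fraction too aggressive for this data")
    restored = raw.copy()
    for (i, j), v in mds.held_out.items():
        restored[i, j] = v
    return np.log1p(restored * (_TARGET_SUM / totals)[:, None])


def score_imputation(mds: MaskedDataset, imputed: np.ndarray) -> float:
    """MSE between imputed values and the held-out truth at masked positions."""
    return masked_mse(truth_matrix(mds), imputed, mds.mask)


class ImputationModel:
    def __init__(self, kind, impute_fn):
        self.kind = kind
        self._impute = impute_fn
        self.trained = True

    def impute(self) -> np.ndarray:
        """Full cells x genes non-negative matrix on the evaluation scale."""
        return self._impute()

    def score(self, mds: MaskedDataset) -> float:
        return score_imputation(mds, self.impute())


def baseline_gene_mean_impute(mds: MaskedDataset) -> np.ndarray:
    """Every entry of gene g replaced by the mean of g's observed unmasked values."""
    W = working_matrix(mds)
    obs = ~mds.mask
    out = np.zeros(W.shape)
    for j in range(W.shape[1]):
        col = W[obs[:, j], j]
        out[:, j] = col.mean() if col.size else 0.0
    return out


def _masked_correlations(W: np.ndarray, valid: np.ndarray, target: int) -> np.ndarray:
    """|Pearson r| of the target gene with every gene, pairwise-complete rows."""
    rows = valid[:, target]
    Wt = W[rows]
    Vt = valid[rows]
    y = Wt[:, target]
    n = Vt.sum(axis=0).astype(float)
    sy = (y[:, None] * Vt).sum(axis=0)
    sx = (Wt * Vt).sum(axis=0)
    sxy = (Wt * (y[:, None] * Vt)).sum(axis=0)
    sxx = (Wt ** 2 * Vt).sum(axis=0)
    syy = ((y ** 2)[:, None] * Vt).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        r = cov / np.sqrt(vx * vy)
    r[~np.isfinite(r)] = 0.0
    r[n < 3] = 0.0
    return np.abs(r)


def fit_block_mlp_imputer(mds: MaskedDataset,
                          cfg: ImputerConfig = ImputerConfig()) -> ImputationModel:
    """Parallel per-block MLPs predicting target genes from correlated genes.

    Genes are partitioned into deterministic blocks; each block's predictor
    set is the union of every target's top-|r| correlated other genes
    (correlations on pairwise-unmasked data only).  One single-hidden-layer
    net per block is trained with value-weighted squared error; masked
    positions carry zero weight, so held-out values are never fit.
    """
    W = working_matrix(mds)
    n, g = W.shape
    if g < cfg.n_predictors + 1:
        raise ValueError(f"need more than {cfg.n_predictors} genes for prediction")
    valid = ~mds.mask
    rng = np.random.default_rng(cfg.seed)
    blocks = [list(range(s, min(s + cfg.block_size, g)))
              for s in range(0, g, cfg.block_size)]
    nets = []
    for block in blocks:
        predictors = set()
        for t in block:
            r = _masked_correlations(W, valid, t)
            r[t] = -1.0
            top = np.argsort(-r, kind="stable")[:cfg.n_predictors]
            predictors.update(int(j) for j in top)
        predictors = sorted(predictors)
        Xin = W[:, predictors]
        Y = W[:, block]
        weight = Y * valid[:, block]  # value-weighted, masked entries excluded
        W1 = ad.glorot(rng, len(predictors), cfg.hidden)
        b1 = ad.param(np.zeros(cfg.hidden))
        W2 = ad.glorot(rng, cfg.hidden, len(block))
        b2 = ad.param(np.zeros(len(block)))
        opt = ad.Adam([W1, b1, W2, b2], lr=cfg.lr)
        for _ in range(cfg.epochs):
            opt.zero_grad()
            h = ad.relu(ad.matmul(ad.Tensor(Xin), W1) + b1)
            pred = ad.relu(ad.matmul(h, W2) + b2)
            loss = ad.tsum(ad.power(pred - ad.Tensor(Y), 2.0) * weight)
            loss = loss * (1.0 / max(weight.sum(), 1.0))
            loss.backward()
            opt.step()
        nets.append((block, predictors, W1.value.copy(), b1.value.copy(),
                     W2.value.copy(), b2.value.copy()))

    def impute():
        out = np.zeros((n, g))
        for block, predictors, w1, bb1, w2, bb2 in nets:
            h = np.maximum(W[:, predictors] @ w1 + bb1, 0.0)
            out[:, block] = np.maximum(h @ w2 + bb2, 0.0)
        return out

    return ImputationModel("block_mlp_imputer", impute)


def fit_graph_ae_imputer(mds: MaskedDataset,
                         cfg: ImputerConfig = ImputerConfig()) -> ImputationModel:
    """Graph autoencoder imputer on the cell-gene graph of the masked counts.

    Two propagation layers embed cells and genes; the reconstruction is
    softplus(z_c . z_g + b_c + b_g) on the evaluation scale (the cell and
    gene biases absorb library-size and mean-expression effects).  The
    squared-error loss averages over the observed unmasked nonzero entries
    plus an equal-count sample of observed zeros, resampled each epoch.
    """
    W = working_matrix(mds)
    n, g = W.shape
    graph = normalize_adjacency(cell_gene_graph(mds.base), mode="sym",
                                add_self_loops=True)
    A = graph.adj
    H0 = np.vstack([W, np.eye(g)])
    rng = np.random.default_rng(cfg.seed)
    W1 = ad.glorot(rng, g, cfg.graph_hidden)
    W2 = ad.glorot(rng, cfg.graph_hidden, cfg.latent_dim)
    b_cell = ad.param(np.zeros(n))
    # gene bias starts at the observed per-gene mean: the embedding inner
    # products then only have to learn deviations from it
    b_gene = ad.param(np.array([W[~mds.mask[:, j], j].mean() for j in range(g)]))
    opt = ad.Adam([W1, W2, b_cell, b_gene], lr=cfg.graph_lr)

    observed_pos = (W > 0) & ~mds.mask
    pi, pj = np.nonzero(observed_pos)
    targets = W[pi, pj]
    zero_pos = (mds.base.raw() == 0) & ~mds.mask
    zi, zj = np.nonzero(zero_pos)
    n_pos = len(pi)
    for _ in range(cfg.graph_epochs):
        opt.zero_grad()
        H1 = ad.relu(ad.spmm(A, ad.matmul(ad.Tensor(H0), W1)))
        Z = ad.spmm(A, ad.matmul(H1, W2))
        zc = ad.take_rows(Z, pi)
        zg = ad.take_rows(Z, n + pj)
        ip = ad.tsum(zc * zg, axis=1) + ad.take_rows(b_cell, pi) + ad.take_rows(b_gene, pj)
        pred = ad.softplus(ip)
        sq = ad.power(pred - ad.Tensor(targets), 2.0)
        n_zero = min(n_pos, len(zi))
        if n_zero:
            take = rng.choice(len(zi), size=n_zero, replace=False)
            z0c = ad.take_rows(Z, zi[take])
            z0g = ad.take_rows(Z, n + zj[take])
            ip0 = (ad.tsum(z0c * z0g, axis=1) + ad.take_rows(b_cell, zi[take])
                   + ad.take_rows(b_gene, zj[take]))
            sq0 = ad.power(ad.softplus(ip0), 2.0)
            loss = (ad.tsum(sq) + ad.tsum(sq0)) * (1.0 / (n_pos + n_zero))
        else:
            loss = ad.tmean(sq)
        loss.backward()
        opt.step()

    H1 = np.maximum(A @ (H0 @ W1.value), 0.0)
    Z = A @ (H1 @ W2.value)
    Zc, Zg = Z[:n], Z[n:]

    def impute():
        ip = Zc @ Zg.T + b_cell.value[:, None] + b_gene.value[None, :]
        return np.where(ip > 30, ip, np.log1p(np.exp(np.minimum(ip, 30))))

    return ImputationModel("graph_ae_imputer", impute)
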