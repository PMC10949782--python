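"""Supervised cell-type annotation models scored by accuracy.

Three classifiers share the fit-predict-score contract: a multinomial
logistic regression trained by minibatch SGD with an L2 penalty, a
multilayer perceptron (default hidden sizes 100-50-25), and a transductive
graph classifier that propagates features over the joint train+test
cell-gene graph and reads off a linear softmax head on the cell embeddings,
training on the labeled cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .data import SCDataset
from .graphs import cell_gene_graph, normalize_adjacency
from .metrics import accuracy


@dataclass(frozen=True)
class AnnotatorConfig:
    seed: int = 0
    lr: float = 0.05
    epochs: int = 100
    batch_size: int = 64
    l2: float = 1e-4
    hidden: tuple = (100, 50, 25)
    class_weighted: bool = False  # inverse-frequency loss weights


class AnnotatorModel:
    """Fitted annotator with a closed label vocabulary."""

    def __init__(self, kind, vocabulary, proba_fn):
        self.kind = kind
        self.vocabulary = list(vocabulary)
        self._proba = proba_fn
        self.trained = True

    def predict_proba(self, ds: SCDataset) -> np.ndarray:
        P = self._proba(ds)
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, ds: SCDataset) -> np.ndarray:
        P = self.predict_proba(ds)
        return np.asarray(self.vocabulary)[P.argmax(axis=1)]

    def score(self, ds: SCDataset) -> float:
        """Accuracy against cell_table['cell_type'].

        Cells whose true label was never seen in training are excluded (with
        a warning recording the count); accuracy is closed-set.
        """
        truth = ds.cell_table["cell_type"].to_numpy()
        known = np.isin(truth, self.vocabulary)
        if not known.all():
            warnings.warn(f"excluding {int((~known).sum())} cells with labels "
                          "outside the training vocabulary")
        if not known.any():
            raise ValueError("no cells with a label seen in training")
        pred = self.predict(ds)
        return accuracy(truth[known], pred[known])


def _prepare_labels(train: SCDataset):
    labels = train.cell_table["cell_type"].to_numpy()
    vocab = sorted(set(labels))
    if len(vocab) < 2:
        raise ValueError("need at least 2 cell types to train an annotator")
    counts = {v: int((labels == v).sum()) for v in vocab}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 cells, got {counts}")
    y = np.searchsorted(vocab, labels)
    return y, vocab


def _class_weights(y: np.ndarray, K: int, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones(len(y))
    freq = np.bincount(y, minlength=K) / len(y)
    return 1.0 / (freq[y] * K)


def _standardizer(X: np.ndarray):
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return lambda A: (A - mu) / sd


def _train_softmax_net(X, y, K, hidden, cfg: AnnotatorConfig):
    """Minibatch SGD training of an MLP (empty hidden = logistic regression)."""
    rng = np.random.default_rng(cfg.seed)
    dims = [X.shape[1], *hidden, K]
    Ws = [ad.glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
    bs = [ad.param(np.zeros(b)) for b in dims[1:]]
    w_cell = _class_weights(y, K, cfg.class_weighted)

    def forward(A):
        h = ad.Tensor(A) if not isinstance(A, ad.Tensor) else A
        for i, (W, b) in enumerate(zip(Ws, bs)):
            h = ad.matmul(h, W) + b
            if i < len(Ws) - 1:
                h = ad.relu(h)
        return h

    n = X.shape[0]
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = 1.0
    opt = ad.Adam(Ws + bs, lr=cfg.lr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = forward(X[idx])
            logp = ad.log_softmax(logits)
            ce = -ad.tsum(logp * (onehot[idx] * w_cell[idx, None])) * (1.0 / len(idx))
            reg = ad.Tensor(0.0)
            for W in Ws:
                reg = reg + ad.tsum(ad.power(W, 2.0))
            loss = ce + cfg.l2 * reg
            loss.backward()
            opt.step()

    def proba(A):
        logits = forward(A).value
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    return proba


def fit_logreg_annotator(train: SCDataset, cfg: AnnotatorConfig = AnnotatorConfig()) -> AnnotatorModel:
    """Multinomial logistic regression by minibatch SGD with L2 penalty."""
    y, vocab = _prepare_labels(train)
    std = _standardizer(train.dense())
    proba = _train_softmax_net(std(train.dense()), y, len(vocab), (), cfg)
    return AnnotatorModel("logreg", vocab, lambda ds: proba(std(ds.dense())))


def fit_mlp_annotator(train: SCDataset, cfg: AnnotatorConfig = AnnotatorConfig()) -> AnnotatorModel:
    """Fully connected softmax classifier (hidden sizes cfg.hidden)."""
    y, vocab = _prepare_labels(train)
    std = _standardizer(train.dense())
    proba = _train_softmax_net(std(train.dense()), y, len(vocab), cfg.hidden, cfg)
    return AnnotatorModel("mlp", vocab, lambda ds: proba(std(ds.dense())))


def fit_gnn_annotator(train: SCDataset, test_unlabeled: SCDataset,
                      cfg: AnnotatorConfig = AnnotatorConfig()) -> AnnotatorModel:
    """Transductive classifier on the joint train+test cell-gene graph.

    One weighted bipartite graph is built over all cells; two propagation
    steps over the symmetric-normalized adjacency (the first through a
    learned ReLU map) produce cell embeddings, and a linear softmax head is
    trained with cross-entropy on the labeled cells only.
    """
    if list(train.gene_ids) != list(test_unlabeled.gene_ids):
        diff = set(train.gene_ids) ^ set(test_unlabeled.gene_ids)
        raise ValueError(f"gene vocabulary mismatch: {sorted(diff)[:10]}")
    y, vocab = _prepare_labels(train)
    K = len(vocab)
    n_tr, n_te, g = train.n_cells, test_unlabeled.n_cells, train.n_genes
    joint = SCDataset(
        X=np.vstack([train.raw(), test_unlabeled.raw()]),
        cell_ids=[f"tr_{c}" for c in train.cell_ids] + [f"te_{c}" for c in test_unlabeled.cell_ids],
        gene_ids=list(train.gene_ids),
        layers={},
    )
    graph = normalize_adjacency(cell_gene_graph(joint), mode="sym", add_self_loops=True)
    A = graph.adj
    Xall = np.vstack([train.dense(), test_unlabeled.dense()])
    Xall = Xall / max(Xall.max(), 1e-12)
    H0 = np.vstack([Xall, np.eye(g)])

    rng = np.random.default_rng(cfg.seed)
    W1 = ad.glorot(rng, g, 64)
    W2 = ad.param(np.zeros((64, K)))  # zero head: uniform output at init
    b2 = ad.param(np.zeros(K))
    onehot = np.zeros((n_tr, K))
    onehot[np.arange(n_tr), y] = 1.0
    w_cell = _class_weights(y, K, cfg.class_weighted)
    opt = ad.Adam([W1, W2, b2], lr=1e-2)
    train_idx = np.arange(n_tr)
    for _ in range(cfg.epochs):
        opt.zero_grad()
        H1 = ad.relu(ad.spmm(A, ad.matmul(ad.Tensor(H0), W1)))
        E = ad.spmm(A, H1)
        logits = ad.matmul(ad.take_rows(E, train_idx), W2) + b2
        logp = ad.log_softmax(logits)
        loss = -ad.tsum(logp * (onehot * w_cell[:, None])) * (1.0 / n_tr)
        loss.backward()
        opt.step()

    H1 = np.maximum(A @ (H0 @ W1.value), 0.0)
    E = A @ H1
    logits = E[:n_tr + n_te] @ W2.value + b2.value
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    P = e / e.sum(axis=1, keepdims=True)
    by_id = {cid: P[n_tr + i] for i, cid in enumerate(test_unlabeled.cell_ids)}
    by_id.update({cid: P[i] for i, cid in enumerate(train.cell_ids)})

    def proba(ds: SCDataset):
        missing = [c for c in ds.cell_ids if c not in by_id]
        if missing:
            raise KeyError(f"transductive model has no embedding for cells {missing[:5]}")
        return np.stack([by_id[c] for c in ds.cell_ids])

    return AnnotatorModel("gnn_annotator", vocab, proba)
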