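"""Clustering models under the fit-predict-score contract.

Two model families are provided:

* ``fit_zinb_dec`` — a zero-inflated negative binomial (ZINB) autoencoder
  whose latent space is refined by deep-embedded-clustering (DEC)
  self-training: Student-t soft assignments q_ij against cluster centroids
  are sharpened into a target distribution p_ij and the KL(P||Q) term is
  minimized jointly with the ZINB reconstruction likelihood.  Passing a
  :class:`ConstraintSet` adds a pairwise must-link / cannot-link penalty to
  the joint loss (the constrained variant of the same architecture).
* ``fit_graph_ae_cluster`` — a graph autoencoder on the weighted bipartite
  cell-gene graph: two propagation layers with learned linear maps embed all
  nodes, the decoder reconstructs edge weights from cell-gene inner
  products, and cells are clustered by Lloyd's algorithm on their embedding.

All training is full-batch Adam on the package's own autodiff engine and is
bit-deterministic for a fixed config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln as _gammaln
from sklearn.cluster import KMeans

from . import _autodiff as ad
from .data import SCDataset
from .graphs import cell_gene_graph, normalize_adjacency
from .metrics import ari
from .transforms import default_pipeline

_EPS = 1e-10


@dataclass(frozen=True)
class ConstraintSet:
    """Must-link / cannot-link cell index pairs (unordered, disjoint sets)."""

    must_link: frozenset
    cannot_link: frozenset

    def __post_init__(self):
        ml = frozenset(tuple(sorted(p)) for p in self.must_link)
        cl = frozenset(tuple(sorted(p)) for p in self.cannot_link)
        for a, b in ml | cl:
            if a == b:
                raise ValueError("constraint pair members must be distinct")
        if ml & cl:
            raise ValueError("a pair appears as both must-link and cannot-link")
        object.__setattr__(self, "must_link", ml)
        object.__setattr__(self, "cannot_link", cl)


@dataclass
class ZinbParams:
    """Per-entry mean mu, per-gene dispersion theta, per-entry dropout pi."""

    mu: np.ndarray
    theta: np.ndarray
    pi: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    hidden: tuple = (256, 64)
    latent_dim: int = 32
    lr: float = 1e-3
    pretrain_epochs: int = 200
    epochs: int = 100
    gamma: float = 1.0          # weight of the KL(P||Q) self-training term
    lam: float = 1.0            # weight of the pairwise-constraint term
    refresh_interval: int = 10  # epochs between target-distribution refreshes
    tol: float = 1e-3           # stop when fewer labels change at a refresh
    alpha: float = 1.0          # Student-t degrees of freedom
    kmeans_restarts: int = 20


# -- DEC algebra ---------------------------------------------------------

def soft_assignments(Z: np.ndarray, centroids: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment q_ij of cells to centroids; rows on the simplex."""
    Z = np.asarray(Z, float)
    M = np.asarray(centroids, float)
    d2 = ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    q = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """DEC sharpening target p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j')."""
    Q = np.asarray(Q, float)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        warnings.warn("empty cluster in target_distribution; stabilized")
        f = np.maximum(f, _EPS)
    W = Q ** 2 / f
    return W / W.sum(axis=1, keepdims=True)


def zinb_nll(x, params: ZinbParams) -> float:
    """Mean ZINB negative log-likelihood over all entries.

    NB(x; mu, theta) = Gamma(x+theta) / (Gamma(theta) x!) (theta/(theta+mu))^theta
    (mu/(theta+mu))^x, zero-inflated by dropout probability pi at x = 0.
    """
    x = np.asarray(x, float)
    mu = np.broadcast_to(np.asarray(params.mu, float), x.shape)
    theta = np.broadcast_to(np.asarray(params.theta, float), x.shape)
    pi = np.broadcast_to(np.asarray(params.pi, float), x.shape)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(theta)) and np.all(np.isfinite(pi))):
        raise ValueError("non-finite ZINB parameters")
    if np.any(mu <= 0) or np.any(theta <= 0) or np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("require mu, theta > 0 and pi in [0, 1]")
    log_nb = (_gammaln(x + theta) - _gammaln(theta) - _gammaln(x + 1)
              + theta * np.log(theta / (theta + mu))
              + x * np.log(mu / (theta + mu)))
    nll_pos = -np.log1p(-pi + _EPS) - log_nb
    nb0 = (theta / (theta + mu)) ** theta
    nll_zero = -np.log(pi + (1 - pi) * nb0 + _EPS)
    return float(np.mean(np.where(x == 0, nll_zero, nll_pos)))


def pairwise_constraint_loss(Q: np.ndarray, constraints: ConstraintSet) -> float:
    """Soft-assignment agreement penalty for must-link / cannot-link pairs.

    L = -sum_ML log(q_a . q_b) - sum_CL log(1 - q_a . q_b), eps-clamped.
    """
    Q = np.asarray(Q, float)
    n = Q.shape[0]
    loss = 0.0
    for a, b in sorted(constraints.must_link):
        if not (0 <= a < n and 0 <= b < n):
            raise IndexError(f"constraint index out of range: ({a}, {b})")
        loss -= np.log(max(float(Q[a] @ Q[b]), _EPS))
    for a, b in sorted(constraints.cannot_link):
        if not (0 <= a < n and 0 <= b < n):
            raise IndexError(f"constraint index out of range: ({a}, {b})")
        loss -= np.log(max(1.0 - float(Q[a] @ Q[b]), _EPS))
    return float(loss)


# -- autodiff building blocks -------------------------------------------

def _transpose(t: ad.Tensor) -> ad.Tensor:
    out = ad.Tensor(t.value.T, parents=(t,))
    if out.requires_grad:
        out._backward = lambda g: ad._accum(t, g.T)
    return out


def _soft_assign_t(Z: ad.Tensor, M: ad.Tensor, alpha: float) -> ad.Tensor:
    z2 = ad.tsum(ad.power(Z, 2.0), axis=1, keepdims=True)
    m2 = ad.tsum(ad.power(M, 2.0), axis=1, keepdims=True)
    d2 = z2 - 2.0 * ad.matmul(Z, _transpose(M)) + _transpose(m2)
    q = ad.power(1.0 + d2 * (1.0 / alpha), -(alpha + 1.0) / 2.0)
    return q / ad.tsum(q, axis=1, keepdims=True)


def _zinb_nll_t(x: np.ndarray, mu: ad.Tensor, theta: ad.Tensor, pi: ad.Tensor) -> ad.Tensor:
    """Differentiable mean ZINB NLL (x constant)."""
    log_nb = (ad.gammaln(ad.Tensor(x) + theta) - ad.gammaln(theta)
              - ad.Tensor(_gammaln(x + 1.0))
              + theta * (ad.log(theta, _EPS) - ad.log(theta + mu, _EPS))
              + ad.Tensor(x) * (ad.log(mu, _EPS) - ad.log(theta + mu, _EPS)))
    zero_mask = (x == 0).astype(float)
    pos_mask = 1.0 - zero_mask
    nll_pos = -ad.log(1.0 - pi, _EPS) - log_nb
    nb0 = ad.exp(ad.mul(theta, ad.log(theta, _EPS) - ad.log(theta + mu, _EPS)))
    nll_zero = -ad.log(pi + (1.0 - pi) * nb0, _EPS)
    total = ad.tsum(nll_zero * zero_mask) + ad.tsum(nll_pos * pos_mask)
    return total * (1.0 / x.size)


def _constraint_loss_t(Q: ad.Tensor, constraints: ConstraintSet) -> ad.Tensor:
    pairs_ml = sorted(constraints.must_link)
    pairs_cl = sorted(constraints.cannot_link)
    terms = []
    if pairs_ml:
        a = np.array([p[0] for p in pairs_ml])
        b = np.array([p[1] for p in pairs_ml])
        s = ad.tsum(ad.take_rows(Q, a) * ad.take_rows(Q, b), axis=1)
        terms.append(-ad.tsum(ad.log(s, _EPS)))
    if pairs_cl:
        a = np.array([p[0] for p in pairs_cl])
        b = np.array([p[1] for p in pairs_cl])
        s = ad.tsum(ad.take_rows(Q, a) * ad.take_rows(Q, b), axis=1)
        terms.append(-ad.tsum(ad.log(1.0 - s, _EPS)))
    if not terms:
        return ad.Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    n_pairs = len(pairs_ml) + len(pairs_cl)
    return total * (1.0 / n_pairs)


def _lloyd(Z: np.ndarray, K: int, restarts: int, seed: int) -> tuple:
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(Z)
    return labels, km.cluster_centers_


def _ensure_preprocessed(ds: SCDataset, model_name: str) -> SCDataset:
    if any(name == "normalize_total" for name, _ in ds.log):
        return ds
    warnings.warn(f"dataset looks raw; applying the default {model_name} pipeline")
    return default_pipeline(model_name).apply(ds)


# -- models --------------------------------------------------------------

class ClusteringModel:
    """Fitted clustering model: latent encoder + centroids + Student-t head."""

    def __init__(self, kind, K, alpha, encode_fn, centroids, labels_, history):
        self.kind = kind
        self.K = K
        self.alpha = alpha
        self._encode = encode_fn
        self.centroids = centroids
        self.labels_ = labels_
        self.history = history

    def embed(self, ds: SCDataset) -> np.ndarray:
        return self._encode(ds)

    def predict(self, ds: SCDataset = None) -> np.ndarray:
        if ds is None:
            return self.labels_
        Q = soft_assignments(self.embed(ds), self.centroids, self.alpha)
        return np.argmax(Q, axis=1)

    def score(self, ds: SCDataset) -> float:
        """ARI of the prediction against the dataset's cell_type labels."""
        return ari(ds.cell_table["cell_type"].to_numpy(), self.predict(ds))


class _ZinbAE:
    """Encoder/decoder parameter bundle for the ZINB autoencoder."""

    def __init__(self, n_genes, cfg: TrainConfig, rng):
        dims = [n_genes, *cfg.hidden, cfg.latent_dim]
        self.enc_W = [ad.glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.enc_b = [ad.param(np.zeros(b)) for b in dims[1:]]
        rdims = list(reversed(dims))
        self.dec_W = [ad.glorot(rng, a, b) for a, b in zip(rdims[:-2], rdims[1:-1])]
        self.dec_b = [ad.param(np.zeros(b)) for b in rdims[1:-1]]
        h = rdims[-2]
        self.W_mu = ad.glorot(rng, h, n_genes)
        self.b_mu = ad.param(np.zeros(n_genes))
        self.W_pi = ad.glorot(rng, h, n_genes)
        self.b_pi = ad.param(np.zeros(n_genes))
        self.log_theta = ad.param(np.zeros(n_genes))  # per-gene dispersion

    def params(self):
        return (self.enc_W + self.enc_b + self.dec_W + self.dec_b
                + [self.W_mu, self.b_mu, self.W_pi, self.b_pi, self.log_theta])

    def encode(self, X: np.ndarray) -> ad.Tensor:
        h = ad.Tensor(X)
        for i, (W, b) in enumerate(zip(self.enc_W, self.enc_b)):
            h = ad.matmul(h, W) + b
            if i < len(self.enc_W) - 1:
                h = ad.relu(h)
        return h

    def decode(self, Z: ad.Tensor, size_factors: np.ndarray):
        h = Z
        for W, b in zip(self.dec_W, self.dec_b):
            h = ad.relu(ad.matmul(h, W) + b)
        mu = ad.exp(ad.matmul(h, self.W_mu) + self.b_mu) * size_factors[:, None] + _EPS
        pi = ad.sigmoid(ad.matmul(h, self.W_pi) + self.b_pi)
        theta = ad.softplus(self.log_theta) + 1e-4
        return mu, theta, pi


def fit_zinb_dec(ds: SCDataset, K: int, cfg: TrainConfig = TrainConfig(),
                 constraints: ConstraintSet = None) -> ClusteringModel:
    """ZINB autoencoder + DEC self-training (optionally pairwise-constrained).

    Stage 1 pretrains the autoencoder on the ZINB reconstruction likelihood of
    the raw counts (with per-cell size factors).  Stage 2 initializes K
    centroids by Lloyd's algorithm on the latent embedding.  Stage 3 jointly
    minimizes reconstruction + gamma * KL(P||Q) (+ lam * constraint loss),
    refreshing the sharpened target P every ``refresh_interval`` epochs and
    stopping when fewer than a ``tol`` fraction of labels change at a refresh.
    """
    ds = _ensure_preprocessed(ds, "zinb_dec")
    if K < 1:
        raise ValueError("K must be >= 1")
    if ds.n_cells < K:
        raise ValueError(f"need at least K={K} cells, got {ds.n_cells}")
    raw = ds.raw()
    totals = raw.sum(axis=1)
    size_factors = totals / np.median(totals)
    X = ds.dense()
    mu_in, sd_in = X.mean(axis=0), X.std(axis=0)
    sd_in = np.where(sd_in > 0, sd_in, 1.0)
    Xs = (X - mu_in) / sd_in

    rng = np.random.default_rng(cfg.seed)
    net = _ZinbAE(ds.n_genes, cfg, rng)
    opt = ad.Adam(net.params(), lr=cfg.lr)
    history = {"pretrain_nll": [], "joint_loss": []}

    for _ in range(cfg.pretrain_epochs):
        opt.zero_grad()
        Z = net.encode(Xs)
        mu, theta, pi = net.decode(Z, size_factors)
        loss = _zinb_nll_t(raw, mu, theta, pi)
        history["pretrain_nll"].append(float(loss.value))
        loss.backward()
        opt.step()

    Z0 = net.encode(Xs).value
    if K == 1:
        centroids = Z0.mean(axis=0, keepdims=True)
        labels = np.zeros(ds.n_cells, dtype=int)
    else:
        labels, centroids = _lloyd(Z0, K, cfg.kmeans_restarts, cfg.seed)
    M = ad.param(centroids.astype(np.float64))
    opt = ad.Adam(net.params() + [M], lr=cfg.lr)

    P = None
    for epoch in range(cfg.epochs):
        if epoch % cfg.refresh_interval == 0:
            Q_now = soft_assignments(net.encode(Xs).value, M.value, cfg.alpha)
            new_labels = Q_now.argmax(axis=1)
            if P is not None:
                changed = np.mean(new_labels != labels)
                labels = new_labels
                if changed < cfg.tol:
                    break
            labels = new_labels
            P = target_distribution(Q_now)
        opt.zero_grad()
        Z = net.encode(Xs)
        mu, theta, pi = net.decode(Z, size_factors)
        recon = _zinb_nll_t(raw, mu, theta, pi)
        Q = _soft_assign_t(Z, M, cfg.alpha)
        kl = ad.tsum(ad.Tensor(P) * (ad.Tensor(np.log(P + _EPS)) - ad.log(Q, _EPS)))
        kl = kl * (1.0 / ds.n_cells)
        loss = recon + cfg.gamma * kl
        if constraints is not None:
            loss = loss + cfg.lam * _constraint_loss_t(Q, constraints)
        history["joint_loss"].append(float(loss.value))
        loss.backward()
        opt.step()

    final_labels = soft_assignments(net.encode(Xs).value, M.value, cfg.alpha).argmax(axis=1)

    def encode_fn(d: SCDataset, _net=net, _mu=mu_in, _sd=sd_in):
        Xd = (d.dense() - _mu) / _sd
        return _net.encode(Xd).value

    kind = "zinb_dec_constrained" if constraints is not None else "zinb_dec"
    return ClusteringModel(kind, K, cfg.alpha, encode_fn, M.value.copy(),
                           final_labels, history)


def fit_graph_ae_cluster(ds: SCDataset, K: int,
                         cfg: TrainConfig = TrainConfig()) -> ClusteringModel:
    """Graph autoencoder on the cell-gene graph, clustered by Lloyd's algorithm.

    Two propagation layers over the symmetric-normalized bipartite graph embed
    cells and genes; the decoder reconstructs (mean-scaled) edge weights from
    cell-gene inner products with a squared-error loss over observed edges
    plus an equally sized resampled set of non-edges.
    """
    ds = _ensure_preprocessed(ds, "graph_ae_cluster")
    if K < 1:
        raise ValueError("K must be >= 1")
    if ds.n_cells < K:
        raise ValueError(f"need at least K={K} cells, got {ds.n_cells}")
    n, g = ds.shape
    graph = normalize_adjacency(cell_gene_graph(ds), mode="sym", add_self_loops=True)
    A = graph.adj
    X = ds.dense()
    Xs = X / max(X.max(), 1e-12)
    H0 = np.vstack([Xs, np.eye(g)])  # cells carry expression, genes identity

    rng = np.random.default_rng(cfg.seed)
    W1 = ad.glorot(rng, g, cfg.hidden[0])
    W2 = ad.glorot(rng, cfg.hidden[0], cfg.latent_dim)
    opt = ad.Adam([W1, W2], lr=cfg.lr)

    raw = ds.raw()
    ci, gi = np.nonzero(raw)
    w = raw[ci, gi] / raw.sum(axis=1)[ci]
    w_scale = w.mean()
    targets = w / w_scale
    n_edges = len(ci)
    zeros_ci, zeros_gi = np.nonzero(raw == 0)
    history = {"recon_loss": []}

    for _ in range(cfg.epochs):
        opt.zero_grad()
        H1 = ad.relu(ad.spmm(A, ad.matmul(ad.Tensor(H0), W1)))
        Z = ad.spmm(A, ad.matmul(H1, W2))
        zc = ad.take_rows(Z, ci)
        zg = ad.take_rows(Z, n + gi)
        pred = ad.tsum(zc * zg, axis=1)
        loss = ad.tmean(ad.power(pred - ad.Tensor(targets), 2.0))
        if len(zeros_ci):
            take = rng.choice(len(zeros_ci), size=min(n_edges, len(zeros_ci)),
                              replace=False)
            z0c = ad.take_rows(Z, zeros_ci[take])
            z0g = ad.take_rows(Z, n + zeros_gi[take])
            pred0 = ad.tsum(z0c * z0g, axis=1)
            loss = loss + ad.tmean(ad.power(pred0, 2.0))
        history["recon_loss"].append(float(loss.value))
        loss.backward()
        opt.step()

    H1 = np.maximum(A @ (H0 @ W1.value), 0.0)
    Z = A @ (H1 @ W2.value)
    Zc = Z[:n]
    if K == 1:
        labels = np.zeros(n, dtype=int)
        centroids = Zc.mean(axis=0, keepdims=True)
    else:
        labels, centroids = _lloyd(Zc, K, cfg.kmeans_restarts, cfg.seed)

    def encode_fn(d: SCDataset, _W1=W1.value.copy(), _W2=W2.value.copy()):
        gr = normalize_adjacency(cell_gene_graph(d), mode="sym", add_self_loops=True)
        Xd = d.dense()
        Xds = Xd / max(Xd.max(), 1e-12)
        H0d = np.vstack([Xds, np.eye(d.n_genes)])
        H1d = np.maximum(gr.adj @ (H0d @ _W1), 0.0)
        return (gr.adj @ (H1d @ _W2))[:d.n_cells]

    return ClusteringModel("graph_ae_cluster", K, cfg.alpha, encode_fn,
                           centroids, labels, history)
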