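"""Synthetic single-cell fixtures: labeled counts, spot mixtures, constraints.

The count simulator follows the standard generative picture of droplet
scRNA-seq: per-gene baseline means are log-normal, each cell type up- or
down-regulates its own disjoint set of differential genes by a fixed
log-fold-change, counts are negative-binomial at a target sequencing depth,
and technical dropout zeroes entries uniformly at random.  Spot mixtures for
deconvolution draw Dirichlet proportions per spot and Poisson counts around
the proportion-weighted type profiles, so the ground truth is known exactly.

Every generator is a pure function of its spec (bitwise reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .data import SCDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the labeled count generator.

    depth is the expected total counts per cell; lfc_scale the natural-log
    fold change applied to each type's differential genes; dropout_rate the
    uniform probability of zeroing an entry (technical dropout).
    """

    n_cells: int = 400
    n_genes: int = 200
    K: int = 4
    type_proportions: tuple = None
    de_fraction: float = 0.1
    lfc_scale: float = 2.0
    base_mean_log_mu: float = 1.0
    base_mean_log_sd: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.1
    depth: float = 2000.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        p = self.type_proportions
        p = np.full(self.K, 1.0 / self.K) if p is None else np.asarray(p, float)
        if len(p) != self.K or np.any(p <= 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("type_proportions must be a length-K simplex vector")
        return p

    def validate(self):
        if min(self.n_cells, self.n_genes, self.K) < 1:
            raise ValueError("n_cells, n_genes, K must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion <= 0 or self.depth <= 0 or self.lfc_scale < 0:
            raise ValueError("dispersion, depth must be positive; lfc_scale >= 0")
        if not 0 <= self.de_fraction <= 1.0 / self.K:
            raise ValueError("de_fraction must allow disjoint per-type gene sets")
        self.proportions()


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of the spot-mixture generator."""

    n_spots: int = 100
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    depth: float = 1e4
    seed: int = 0

    def validate(self):
        if self.n_spots < 1 or self.depth <= 0:
            raise ValueError("n_spots and depth must be positive")
        if np.any(np.asarray(self.dirichlet_alpha) <= 0):
            raise ValueError("dirichlet_alpha must be positive")


def type_mean_profiles(spec: SyntheticSpec) -> np.ndarray:
    """Expected count profiles (K x genes), each row scaled to spec.depth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=spec.base_mean_log_mu, sigma=spec.base_mean_log_sd,
                         size=spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    perm = rng.permutation(spec.n_genes)
    profiles = np.empty((spec.K, spec.n_genes))
    for t in range(spec.K):
        genes = perm[t * n_de:(t + 1) * n_de]
        signs = rng.choice([-1.0, 1.0], size=n_de)
        factors = np.ones(spec.n_genes)
        factors[genes] = np.exp(signs * spec.lfc_scale)
        mu = base * factors
        profiles[t] = mu * (spec.depth / mu.sum())
    return profiles


def simulate_counts(spec: SyntheticSpec) -> SCDataset:
    """Labeled negative-binomial count matrix with uniform dropout."""
    profiles = type_mean_profiles(spec)
    rng = np.random.default_rng(spec.seed + 1)  # sampling stream, separate from profiles
    labels = rng.choice(spec.K, size=spec.n_cells, p=spec.proportions())
    mu = profiles[labels]
    lam = rng.gamma(shape=spec.dispersion, scale=mu / spec.dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0
    cell_ids = [f"cell{i}" for i in range(spec.n_cells)]
    gene_ids = [f"g{j:04d}" for j in range(spec.n_genes)]
    cell_table = pd.DataFrame(
        {"cell_type": [f"type{t}" for t in labels]}, index=cell_ids)
    ds = SCDataset(X=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                   layers={"raw": counts.copy()}, cell_table=cell_table)
    return ds.with_log("simulate_counts", seed=spec.seed, K=spec.K,
                       lfc_scale=spec.lfc_scale, dropout_rate=spec.dropout_rate)


def simulate_mixtures(reference: SCDataset, mspec: MixtureSpec):
    """Spot mixtures with known proportions from a labeled reference.

    Returns (spots dataset, truth ProportionMatrix, reference).  Each spot's
    expected profile is the beta-weighted combination of the reference type
    mean profiles scaled to depth; observed counts are Poisson.
    """
    from .deconvolution import ProportionMatrix

    mspec.validate()
    types = sorted(reference.cell_table["cell_type"].unique())
    if len(types) < 2:
        raise ValueError("reference must contain at least 2 cell types")
    if len(mspec.dirichlet_alpha) != len(types):
        raise ValueError("dirichlet_alpha length must equal the number of types")
    raw = reference.raw()
    labels = reference.cell_table["cell_type"].to_numpy()
    profiles = np.stack([raw[labels == t].mean(axis=0) for t in types])
    rng = np.random.default_rng(mspec.seed)
    beta = rng.dirichlet(np.asarray(mspec.dirichlet_alpha, float), size=mspec.n_spots)
    expected = beta @ profiles
    expected *= mspec.depth / expected.sum(axis=1, keepdims=True)
    counts = rng.poisson(expected).astype(np.float64)
    spot_ids = [f"spot{i}" for i in range(mspec.n_spots)]
    side = int(np.ceil(np.sqrt(mspec.n_spots)))
    cell_table = pd.DataFrame(
        {"x_coord": [i % side for i in range(mspec.n_spots)],
         "y_coord": [i // side for i in range(mspec.n_spots)]}, index=spot_ids)
    for j, t in enumerate(types):
        cell_table[f"prop_{t}"] = beta[:, j]
    spots = SCDataset(X=counts, cell_ids=spot_ids, gene_ids=list(reference.gene_ids),
                      layers={"raw": counts.copy()}, cell_table=cell_table)
    spots.with_log("simulate_mixtures", seed=mspec.seed, n_spots=mspec.n_spots,
                   depth=mspec.depth)
    truth = ProportionMatrix(P=beta, spot_ids=spot_ids, type_names=list(types))
    return spots, truth, reference


def sample_constraints(labels, n_must: int, n_cannot: int, seed: int = 0):
    """Uniformly sampled must-link / cannot-link pairs from true labels."""
    from .clustering import ConstraintSet

    labels = np.asarray(labels)
    n = len(labels)
    same = [(i, j) for i in range(n) for j in range(i + 1, n) if labels[i] == labels[j]]
    diff = [(i, j) for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j]]
    if n_must > len(same):
        raise ValueError(f"at most {len(same)} must-link pairs available")
    if n_cannot > len(diff):
        raise ValueError(f"at most {len(diff)} cannot-link pairs available")
    rng = np.random.default_rng(seed)
    ml = [same[k] for k in rng.choice(len(same), size=n_must, replace=False)] if n_must else []
    cl = [diff[k] for k in rng.choice(len(diff), size=n_cannot, replace=False)] if n_cannot else []
    return ConstraintSet(must_link=frozenset(ml), cannot_link=frozenset(cl))


# -- named fixtures (registered in scbench.data) -------------------------

BLOBS4_SPEC = SyntheticSpec(seed=0)                                   # easy: lfc 2, dropout 0.1
HARD4_SPEC = SyntheticSpec(lfc_scale=1.0, dropout_rate=0.3, seed=0)   # hard: lfc 1, dropout 0.3
MIX4_REF_SPEC = SyntheticSpec(dropout_rate=0.0, seed=7)
MIX4_SPEC = MixtureSpec(n_spots=100, dirichlet_alpha=(1.0,) * 4, depth=1e4, seed=0)


def blobs4_fixture() -> SCDataset:
    return simulate_counts(BLOBS4_SPEC)


def hard4_fixture() -> SCDataset:
    return simulate_counts(HARD4_SPEC)


@lru_cache(maxsize=1)
def _mix4():
    return simulate_mixtures(simulate_counts(MIX4_REF_SPEC), MIX4_SPEC)


def mix4_spots_fixture() -> SCDataset:
    return _mix4()[0].copy()


def mix4_reference_fixture() -> SCDataset:
    return _mix4()[2].copy()


def mix4_truth():
    """Known spot proportions of the 'synth_mix4' fixture."""
    return _mix4()[1]
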