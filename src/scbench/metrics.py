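"""Task-aligned evaluation metrics.

Clustering is scored with the Adjusted Rand Index, annotation with accuracy,
imputation with mean squared error on the held-out masked entries, and
deconvolution with MSE on the proportion matrix.  ARI and NMI are computed
directly from the contingency table so the degenerate-partition conventions
are explicit: ARI of two identical degenerate partitions is 1 (else 0 when
the chance denominator vanishes), and NMI is 0 whenever either labeling has
zero entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MetricReport:
    task: str
    values: dict = field(default_factory=dict)
    n_items: int = 0

    def to_json(self) -> str:
        return json.dumps({"task": self.task, "values": self.values,
                           "n_items": self.n_items})


def _contingency(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must have equal 1-d shape, got {a.shape} vs {b.shape}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    C = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(C, (ai, bi), 1)
    return C


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand Index; 1 for identical partitions, ~0 for chance."""
    C = _contingency(labels_true, labels_pred)
    n = C.sum()
    if n < 2:
        raise ValueError("need at least 2 items")

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(C).sum()
    a = comb2(C.sum(axis=1)).sum()
    b = comb2(C.sum(axis=0)).sum()
    total = comb2(n)
    expected = a * b / total
    max_index = (a + b) / 2.0
    if max_index == expected:
        # the chance denominator vanishes only when BOTH partitions are all
        # singletons or both are a single cluster, i.e. identical partitions
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(labels_true, labels_pred, average_method: str = "arithmetic") -> float:
    """Normalized mutual information, natural logs.

    Normalization uses the arithmetic mean of the two label entropies by
    default (geometric available as an option).  Zero entropy on either side
    gives 0 by convention.
    """
    C = _contingency(labels_true, labels_pred).astype(np.float64)
    n = C.sum()
    if n < 2:
        raise ValueError("need at least 2 items")
    pi = C.sum(axis=1) / n
    pj = C.sum(axis=0) / n
    hi = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    hj = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if hi == 0.0 or hj == 0.0:
        return 0.0
    P = C / n
    nz = P > 0
    mi = np.sum(P[nz] * np.log(P[nz] / np.outer(pi, pj)[nz]))
    if average_method == "arithmetic":
        denom = (hi + hj) / 2.0
    elif average_method == "geometric":
        denom = np.sqrt(hi * hj)
    else:
        raise ValueError("average_method must be 'arithmetic' or 'geometric'")
    return float(np.clip(mi / denom, 0.0, 1.0))


def accuracy(labels_true, labels_pred) -> float:
    """Fraction of exact label matches."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("need at least 1 item")
    return float(np.mean(t == p))


def masked_mse(truth, pred, mask=None) -> float:
    """Mean squared error over masked entries (all entries when mask absent)."""
    T = np.asarray(truth, dtype=np.float64)
    P = np.asarray(pred, dtype=np.float64)
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {P.shape}")
    if mask is None:
        mask = np.ones(T.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != T.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("mask selects no entries")
    d = T[mask] - P[mask]
    return float(np.mean(d * d))


def rmse(truth, pred) -> float:
    return float(np.sqrt(masked_mse(truth, pred)))
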