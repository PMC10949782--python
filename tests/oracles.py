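"""Independent brute-force oracles shared by the metric and solver tests."""

import math
from collections import Counter
from itertools import chain, combinations

import numpy as np


def ari_pair_counting(a, b):
    """ARI via explicit pair counting (2(ad-bc) closed form)."""
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(len(a)), 2):
        s, t = a[i] == a[j], b[i] == b[j]
        n11 += s and t
        n10 += s and not t
        n01 += t and not s
        n00 += not s and not t
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def nmi_counter(a, b):
    """NMI via dict-based joint counting, arithmetic-mean normalization."""
    n = len(a)
    pa = Counter(a)
    pb = Counter(b)
    pab = Counter(zip(a, b))
    ha = -sum(c / n * math.log(c / n) for c in pa.values())
    hb = -sum(c / n * math.log(c / n) for c in pb.values())
    if ha == 0 or hb == 0:
        return 0.0
    mi = sum(c / n * math.log(c * n / (pa[u] * pb[v]))
             for (u, v), c in pab.items())
    return mi / ((ha + hb) / 2)


def growth_strings(n, max_labels):
    """All canonical label vectors (restricted growth strings) of length n."""
    out = []

    def rec(prefix, used):
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for lab in range(min(used + 1, max_labels)):
            rec(prefix + [lab], max(used, lab + 1))

    rec([], 0)
    return out


def brute_force_nnls(A, y):
    """Optimal beta >= 0 by enumerating every active set (small problems)."""
    k = A.shape[1]
    best, best_obj = np.zeros(k), float(np.sum(y ** 2))
    for subset in chain.from_iterable(combinations(range(k), r)
                                      for r in range(1, k + 1)):
        sub = list(subset)
        coef, *_ = np.linalg.lstsq(A[:, sub], y, rcond=None)
        if np.any(coef < -1e-12):
            continue
        beta = np.zeros(k)
        beta[sub] = np.clip(coef, 0, None)
        obj = float(np.sum((y - A @ beta) ** 2))
        if obj < best_obj - 1e-12:
            best, best_obj = beta, obj
    return best, best_obj
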