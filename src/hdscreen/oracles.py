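"""Plain-loop reference implementations used as test oracles.

Each function here recomputes a pipeline quantity with the most direct
(and slow) algorithm available — explicit loops, O(n^2) pairwise
comparisons, exhaustive threshold enumeration — deliberately sharing no
code with the production paths it checks.  Intended for test suites on
small inputs (n <= ~1,000); nothing in the library calls these.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "bundle_by_label",
    "argmax_cosine",
    "pairwise_auc",
    "topk_enrichment",
    "tpr_at_fpr",
]


def bundle_by_label(samples, labels, classes) -> np.ndarray:
    """Sum sample rows per class with an explicit loop."""
    samples = np.asarray(samples)
    protos = np.zeros((len(classes), samples.shape[1]), dtype=np.int64)
    for k, c in enumerate(classes):
        for row, lab in zip(samples, labels):
            if lab == c:
                protos[k] += row.astype(np.int64)
    return protos


def _cosine(a, b) -> float:
    num = sum(float(x) * float(y) for x, y in zip(a, b))
    na = math.sqrt(sum(float(x) ** 2 for x in a))
    nb = math.sqrt(sum(float(y) ** 2 for y in b))
    return num / (na * nb)


def argmax_cosine(prototypes, query) -> int:
    """Index of the most cosine-similar prototype; first index wins ties."""
    best_idx, best_sim = 0, -2.0
    for k, proto in enumerate(prototypes):
        sim = _cosine(proto, query)
        if sim > best_sim:
            best_idx, best_sim = k, sim
    return best_idx


def pairwise_auc(scores, labels) -> float:
    """AUC as the tie-corrected fraction of correctly ordered pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def topk_enrichment(scores, labels, x: float) -> float:
    """EF by counting actives in the top round(x*n) of a stable descending sort."""
    n_b = len(scores)
    a_b = sum(labels)
    n_s = int(round(x * n_b))
    order = sorted(range(n_b), key=lambda i: (-scores[i], i))
    a_s = sum(labels[i] for i in order[:n_s])
    return (a_s / n_s) / (a_b / n_b)


def tpr_at_fpr(scores, labels, fpr_target: float) -> float:
    """TPR at a fixed FPR by exhaustive threshold enumeration + interpolation.

    Enumerates every distinct score as a ">= threshold" cutoff to build
    the empirical (FPR, TPR) staircase, then linearly interpolates at
    ``fpr_target``.
    """
    n_pos = sum(1 for l in labels if l == 1)
    n_neg = sum(1 for l in labels if l == 0)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    points = [(0.0, 0.0)]
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
        points.append((fp / n_neg, tp / n_pos))
    points.append((1.0, 1.0))
    points.sort()
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return float(np.interp(fpr_target, xs, ys))
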