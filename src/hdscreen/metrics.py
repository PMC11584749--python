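"""Virtual-screening evaluation metrics.

Given a ranked screen (per-compound scores, higher = predicted more
active, plus binary activity labels) this module computes:

* the empirical ROC curve and its area (ROC-AUC), delegated to
  scikit-learn (tied scores collapse into a single step, and the
  trapezoidal area equals the tie-corrected pairwise probability
  P(score_pos > score_neg) + P(equal)/2);
* the enrichment factor EF-x% = (a_s/n_s) / (a_b/n_b): the active hit
  rate in the top x% of the ranking relative to the database-wide hit
  rate, with the cutoff n_s = round(x * n_b) and ties at the cutoff
  resolved by stable rank;
* the ROC-enrichment ER-x% = 100 * TPR at FPR = x%, read off the
  empirical ROC curve with linear interpolation between adjacent
  vertices.  Unlike EF, ER is insensitive to the active:inactive
  ratio, which matters for heavily skewed screening decks.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn import metrics as _skm

from .am import RankedScreen

__all__ = [
    "roc_curve",
    "roc_auc",
    "enrichment_factor",
    "roc_enrichment",
    "screen_report",
    "write_report",
]

ER_PRESETS = (0.1, 0.2, 0.5, 1.0)  # FPR percentages commonly reported


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError(
            "ROC-based metrics require both an active and an inactive class"
        )


def _scores_labels(screen: RankedScreen) -> tuple[np.ndarray, np.ndarray]:
    if screen.labels is None:
        raise ValueError("screen has no activity labels; metrics need labels")
    labels = np.asarray(screen.labels, dtype=np.int64)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary {0, 1}")
    return np.asarray(screen.scores, dtype=np.float64), labels


def roc_curve(screen: RankedScreen) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve as (fpr, tpr) vertex arrays from (0,0) to (1,1)."""
    scores, labels = _scores_labels(screen)
    _check_two_classes(labels)
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    # guarantee explicit (0,0) and (1,1) endpoints for interpolation
    if fpr[0] != 0.0 or tpr[0] != 0.0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
    return fpr, tpr


def roc_auc(screen: RankedScreen) -> float:
    """Area under the empirical ROC curve (trapezoidal)."""
    scores, labels = _scores_labels(screen)
    _check_two_classes(labels)
    return float(_skm.roc_auc_score(labels, scores))


def enrichment_factor(screen: RankedScreen, x: float) -> float:
    """Enrichment factor over the top-``x`` fraction of the ranking.

    ``x`` is a fraction in (0, 1]; the sample is the top
    ``n_s = round(x * n_b)`` compounds by descending score (stable on
    tied scores).  EF = sample hit rate / database hit rate; EF at
    x = 1 is exactly 1 whenever any active exists.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError(f"x must be a fraction in (0, 1], got {x}")
    scores, labels = _scores_labels(screen)
    n_b = scores.shape[0]
    a_b = int(labels.sum())
    if a_b == 0:
        raise ValueError("enrichment factor undefined: no actives in the database")
    n_s = int(round(x * n_b))
    if n_s < 1:
        raise ValueError(
            f"top fraction x={x} selects zero compounds out of {n_b}; increase x"
        )
    order = np.argsort(-scores, kind="stable")
    a_s = int(labels[order[:n_s]].sum())
    return (a_s / n_s) / (a_b / n_b)


def roc_enrichment(screen: RankedScreen, x_percent: float) -> float:
    """ROC-enrichment ER-x%: 100 * TPR at FPR = x_percent %.

    Reads the empirical ROC curve at the requested false-positive rate,
    linearly interpolating between adjacent vertices when x% falls
    between curve steps.  ER-100% is 100 by construction and ER is
    non-decreasing in x.
    """
    if not 0.0 < x_percent <= 100.0:
        raise ValueError(f"x_percent must be in (0, 100], got {x_percent}")
    fpr, tpr = roc_curve(screen)
    target = x_percent / 100.0
    return float(np.interp(target, fpr, tpr) * 100.0)


def screen_report(
    screen: RankedScreen,
    ef_fractions: tuple[float, ...] = (0.01, 0.1),
    er_percents: tuple[float, ...] = ER_PRESETS,
) -> dict[str, float]:
    """Standard metric bundle for one screen.

    Skips EF fractions whose cutoff would select zero compounds (tiny
    decks) rather than failing the whole report.
    """
    report: dict[str, float] = {"roc_auc": roc_auc(screen)}
    n_b = len(screen)
    for x in ef_fractions:
        if int(round(x * n_b)) >= 1:
            report[f"ef_{x * 100:g}pct"] = enrichment_factor(screen, x)
    for xp in er_percents:
        report[f"er_{xp:g}pct"] = roc_enrichment(screen, xp)
    report["er_interpolation"] = "linear"  # type: ignore[assignment]
    return report


def write_report(report: dict, path) -> None:
    """Write a metrics report as a machine-readable JSON key-value file."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
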