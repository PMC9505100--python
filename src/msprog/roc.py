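"""Stepwise ROC curves, exact AUCs, and replica-distribution summaries.

The validation sets are tiny (6 positives / 12 negatives in the
reference design), so the ROC is an explicit step function whose FPR and
TPR move in multiples of 1/n_neg and 1/n_pos, and the AUC is computed
exactly as the Mann-Whitney probability P(score_pos > score_neg) with
ties counted 1/2 — not by numerical integration of a smoothed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RocResult",
    "AucDistribution",
    "auc_slice",
    "auc_slab_folded",
    "summarize_distribution",
    "auc_table",
]


@dataclass
class RocResult:
    """Stepwise ROC and exact AUC for one evaluation unit."""

    fpr_steps: np.ndarray
    tpr_steps: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    unit: dict = field(default_factory=dict)


@dataclass
class AucDistribution:
    """Boxplot-style summary of one unit's replica AUC distribution."""

    aucs: np.ndarray
    median: float
    q25: float
    q75: float
    outliers: np.ndarray  # indices into ``aucs`` beyond 1.5 x IQR
    unit: dict = field(default_factory=dict)


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need both classes to build a ROC (got {n_pos} positives, {n_neg} negatives)"
        )
    return n_pos, n_neg


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray, n_pos: int, n_neg: int) -> float:
    # midranks give the tie-corrected pair count directly
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _step_curve(scores: np.ndarray, labels: np.ndarray, n_pos: int, n_neg: int):
    # thresholds descending; tied scores move the curve diagonally in one step
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp = np.concatenate([[0], np.cumsum(y)[boundaries - 1], [n_pos]])
    fp = np.concatenate([[0], (boundaries - np.cumsum(y)[boundaries - 1]), [n_neg]])
    # deduplicate the final point when the last threshold group ends the array
    pts = np.unique(np.column_stack([fp, tp]), axis=0)
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    return pts[:, 0] / n_neg, pts[:, 1] / n_pos


def auc_slice(scores, labels, unit: dict | None = None) -> RocResult:
    """Exact ROC/AUC of per-patient scores at a single slice.

    AUC is the Mann-Whitney probability (ties 1/2); the returned step
    curve integrates to the same value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = _check_binary(labels)
    auc = _mann_whitney_auc(scores, labels, n_pos, n_neg)
    fpr, tpr = _step_curve(scores, labels, n_pos, n_neg)
    return RocResult(fpr, tpr, float(auc), n_pos, n_neg, unit or {})


def auc_slab_folded(predictions: pd.DataFrame, unit: dict | None = None) -> RocResult:
    """Slab-level ROC treating every (patient, slice) pair as one instance.

    ``predictions`` must carry one row per validation patient per included
    slice of the slab, with columns ``coordinate``, ``patient_id``,
    ``true_label`` and ``score``.  With the reference validation split the
    folded problem has 6 x n_slices positives and 12 x n_slices negatives.
    """
    required = {"coordinate", "patient_id", "true_label", "score"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns {sorted(missing)}")
    counts = predictions.groupby("coordinate")["patient_id"].count()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()].index.tolist()
        raise ValueError(f"missing per-patient scores at coordinates {bad}")
    return auc_slice(
        predictions["score"].to_numpy(),
        predictions["true_label"].to_numpy(),
        unit=unit,
    )


def summarize_distribution(aucs, unit: dict | None = None) -> AucDistribution:
    """Median, quartiles and 1.5 x IQR boxplot outliers of replica AUCs.

    Quartiles use the linear-interpolation convention; an AUC is an
    outlier iff it is strictly beyond quartile +/- 1.5 x IQR.
    """
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 4:
        raise ValueError(f"need at least 4 AUC values to summarize, got {aucs.size}")
    q25, med, q75 = np.quantile(aucs, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    out = np.flatnonzero((aucs > q75 + 1.5 * iqr) | (aucs < q25 - 1.5 * iqr))
    return AucDistribution(aucs, float(med), float(q25), float(q75), out, unit or {})


def auc_table(predictions: pd.DataFrame, folded: bool = False) -> pd.DataFrame:
    """Per-unit AUC table from a long prediction table.

    Slice units are (projection, slab, coordinate, replica, model_kind);
    with ``folded=True`` slices are folded per slab instead.  Returns
    columns ``projection, slab[, coordinate], replica, model_kind, auc,
    n_pos, n_neg``.
    """
    keys = ["projection", "slab", "replica", "model_kind"]
    if not folded:
        keys.insert(2, "coordinate")
    rows = []
    for key, grp in predictions.groupby(keys, sort=True):
        r = auc_slice(grp["score"].to_numpy(), grp["true_label"].to_numpy())
        rows.append(dict(zip(keys, key), auc=r.auc, n_pos=r.n_pos, n_neg=r.n_neg))
    return pd.DataFrame(rows)
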