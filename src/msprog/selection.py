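"""Real-vs-null model comparison: admissibility band, DeLong test, selection.

Every real discriminator is paired with the null discriminator of the
same replica (trained on permuted labels, evaluated on the identical
validation patients).  A pair survives when

* the null AUC sits inside the discrete admissibility band
  0.5 +/- delta, where delta = 1/(n_pos x n_neg) is the minimal step of
  the validation ROC (0.0139 for the 6/12 reference split);
* DeLong's paired test on the two correlated ROC curves gives Z > 1.96;
* the real AUC exceeds the null AUC (improvement towards 1, never
  towards 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DegenerateComparisonError",
    "auc_granularity",
    "delong_placements",
    "delong_test",
    "build_selection_table",
    "select_significant",
]

Z_CRITICAL = 1.96


class DegenerateComparisonError(ValueError):
    """Raised when the paired AUC difference has zero variance but is non-zero."""


def auc_granularity(n_pos: int, n_neg: int) -> float:
    """Minimal AUC increment of a stepwise ROC: 1/(n_pos x n_neg)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError(f"need at least one case per class, got {n_pos}/{n_neg}")
    return 1.0 / (n_pos * n_neg)


def _psi(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Heaviside kernel matrix: 1 if pos>neg, 1/2 if equal, 0 otherwise."""
    diff = pos[:, None] - neg[None, :]
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def delong_placements(scores, labels):
    """AUC and structural components (placement values) of one model.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the mean kernel value
    of positive case i against all negatives and ``v01[j]`` the mean of
    all positives against negative case j.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative case")
    k = _psi(pos, neg)
    return float(k.mean()), k.mean(axis=1), k.mean(axis=0)


def delong_test(scores_real, scores_null, labels) -> tuple[float, float]:
    """Paired DeLong Z-test comparing two correlated AUCs.

    Both score vectors must refer to the same validation patients in the
    same order.  Returns ``(z, p)`` with z signed as AUC_real - AUC_null
    and p the two-sided normal tail.  Identical score vectors give
    (0.0, 1.0); any other zero-variance pairing raises
    :class:`DegenerateComparisonError`.
    """
    scores_real = np.asarray(scores_real, dtype=float)
    scores_null = np.asarray(scores_null, dtype=float)
    labels = np.asarray(labels)
    if not (scores_real.shape == scores_null.shape == labels.shape):
        raise ValueError("score vectors and labels must share one length (paired test)")

    auc_r, v10_r, v01_r = delong_placements(scores_real, labels)
    auc_n, v10_n, v01_n = delong_placements(scores_null, labels)
    n_pos, n_neg = v10_r.size, v01_r.size

    # 2x2 covariance of the placement values across the two models
    s10 = np.cov(np.vstack([v10_r, v10_n]), ddof=1) if n_pos > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_r, v01_n]), ddof=1) if n_neg > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
    )

    if var <= 0 or not np.isfinite(var):
        if np.allclose(v10_r, v10_n) and np.allclose(v01_r, v01_n):
            return 0.0, 1.0
        raise DegenerateComparisonError(
            "paired AUC difference has zero variance; pair is untestable"
        )
    z = (auc_r - auc_n) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def _pair_scores(real: pd.DataFrame, null: pd.DataFrame):
    merged = real.merge(
        null[["patient_id", "score"]], on="patient_id", suffixes=("_real", "_null"), validate="1:1"
    )
    return (
        merged["score_real"].to_numpy(),
        merged["score_null"].to_numpy(),
        merged["true_label"].to_numpy(),
    )


def build_selection_table(
    predictions: pd.DataFrame,
    z_crit: float = Z_CRITICAL,
    delta: float | None = None,
) -> pd.DataFrame:
    """One selection record per (projection, slab, coordinate, replica).

    ``predictions`` is the long prediction table holding both
    ``model_kind='real'`` and ``model_kind='null'`` rows.  ``delta``
    overrides the admissibility half-width; by default it is the ROC
    granularity of each unit's validation split.  Degenerate DeLong
    pairs are kept with ``z = NaN`` and ``selected = False``.
    """
    from .roc import auc_slice  # local import avoids a cycle

    records = []
    keys = ["projection", "slab", "coordinate", "replica"]
    for key, grp in predictions.groupby(keys, sort=True):
        real = grp[grp["model_kind"] == "real"]
        null = grp[grp["model_kind"] == "null"]
        if real.empty or null.empty:
            raise ValueError(f"unit {dict(zip(keys, key))} lacks a real or null model")
        s_real, s_null, y = _pair_scores(real, null)
        roc_real = auc_slice(s_real, y)
        roc_null = auc_slice(s_null, y)
        d = delta if delta is not None else auc_granularity(roc_real.n_pos, roc_real.n_neg)
        admissible = abs(roc_null.auc - 0.5) <= d + 1e-12
        try:
            z, p = delong_test(s_real, s_null, y)
        except DegenerateComparisonError:
            z, p = np.nan, np.nan
        selected = bool(
            admissible
            and np.isfinite(z)
            and z > z_crit
            and roc_real.auc > roc_null.auc
        )
        records.append(
            dict(
                zip(keys, key),
                auc_real=roc_real.auc,
                auc_null=roc_null.auc,
                delta=d,
                null_admissible=admissible,
                z=z,
                p=p,
                selected=selected,
            )
        )
    return pd.DataFrame(records)


def select_significant(records: pd.DataFrame) -> dict:
    """Summarize the selected (slice, classifier) pairs.

    Returns per-projection significant coordinate lists (one entry per
    selected slice-classifier combination, so a coordinate repeats when
    several replicas select it), the selected triples, the replicas
    significant on more than one slice, and the number of tests run (no
    multiplicity correction is applied, so users can post-correct).
    """
    sel = records[records["selected"]]
    by_projection: dict[str, list[int]] = {}
    auc_ranges: dict[str, list[float]] = {}
    for projection, grp in sel.groupby("projection"):
        by_projection[projection] = sorted(int(c) for c in grp["coordinate"])
        auc_ranges[projection] = [float(grp["auc_real"].min()), float(grp["auc_real"].max())]
    multi = (
        sel.groupby(["projection", "replica"])["coordinate"]
        .nunique()
        .loc[lambda s: s > 1]
        .reset_index()
        .rename(columns={"coordinate": "n_slices"})
    )
    return {
        "n_tests": int(len(records)),
        "n_selected": int(len(sel)),
        "significant_slices": by_projection,
        "auc_real_ranges": auc_ranges,
        "selected_triples": [
            (r.projection, int(r.coordinate), int(r.replica))
            for r in sel.itertuples()
        ],
        "multi_slice_classifiers": multi.to_dict("records"),
    }
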