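import numpy as np
import pandas as pd
import pytest

from msprog import (
    DegenerateComparisonError,
    auc_granularity,
    auc_slice,
    build_selection_table,
    delong_test,
    select_significant,
)
from msprog.selection import delong_placements


# -- independent oracle: loop-based DeLong structural components ---------


def oracle_delong(a, b, labels):
    """Direct transcription of the structural-components formulas."""
    a, b, labels = map(np.asarray, (a, b, labels))
    out = []
    for scores in (a, b):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        m, n = len(pos), len(neg)
        v10 = np.zeros(m)
        v01 = np.zeros(n)
        for i in range(m):
            for j in range(n):
                psi = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
                v10[i] += psi / n
                v01[j] += psi / m
        out.append((v10.mean(), v10, v01))
    (auc_a, v10_a, v01_a), (auc_b, v10_b, v01_b) = out
    m, n = len(v10_a), len(v01_a)

    def cov(x, y):
        return ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)

    var = (
        cov(v10_a, v10_a) + cov(v10_b, v10_b) - 2 * cov(v10_a, v10_b)
    ) / m + (cov(v01_a, v01_a) + cov(v01_b, v01_b) - 2 * cov(v01_a, v01_b)) / n
    if var <= 0:
        return np.nan, var
    return (auc_a - auc_b) / np.sqrt(var), var


def _instance(rng, n_pos=6, n_neg=12, shift=0.8):
    labels = np.array([1] * n_pos + [0] * n_neg)
    a = rng.normal(size=labels.size) + labels * shift
    b = rng.normal(size=labels.size)
    return a, b, labels


def test_granularity_closed_form():
    assert round(auc_granularity(6, 12), 4) == 0.0139
    assert auc_granularity(1, 1) == 1.0
    assert auc_granularity(10, 10) == 0.01
    with pytest.raises(ValueError):
        auc_granularity(0, 12)


def test_identical_models_give_zero_z_unit_p():
    scores = np.arange(18, dtype=float)
    labels = np.array([0] * 12 + [1] * 6)
    assert delong_test(scores, scores, labels) == (0.0, 1.0)


def test_delong_matches_loop_oracle():
    rng = np.random.default_rng(10)
    for _ in range(50):
        a, b, labels = _instance(rng, n_pos=int(rng.integers(2, 7)), n_neg=int(rng.integers(2, 13)))
        z_oracle, var_oracle = oracle_delong(a, b, labels)
        if var_oracle <= 0:  # untestable pair; covered by the degenerate test
            continue
        z, p = delong_test(a, b, labels)
        assert z == pytest.approx(z_oracle, abs=1e-10)
        assert np.sign(z) == np.sign(
            auc_slice(a, labels).auc - auc_slice(b, labels).auc
        ) or z == 0


def test_delong_internal_auc_equals_roc_module():
    rng = np.random.default_rng(11)
    for _ in range(25):
        a, _, labels = _instance(rng)
        auc, _, _ = delong_placements(a, labels)
        assert auc == pytest.approx(auc_slice(a, labels).auc, abs=1e-12)


def test_delong_variance_within_bootstrap_band():
    """DeLong sd agrees with a stratified patient-bootstrap sd (loose band)."""
    rng = np.random.default_rng(12)
    ratios = []
    for _ in range(10):
        a, b, labels = _instance(rng)
        z, _ = delong_test(a, b, labels)
        diff = auc_slice(a, labels).auc - auc_slice(b, labels).auc
        sd_delong = abs(diff / z) if z != 0 else np.nan
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        diffs = []
        for _ in range(500):
            pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
            ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
            idx = np.concatenate([pi, ni])
            yb = labels[idx]
            diffs.append(auc_slice(a[idx], yb).auc - auc_slice(b[idx], yb).auc)
        sd_boot = np.std(diffs, ddof=1)
        ratios.append(sd_delong / sd_boot)
    ratios = np.array(ratios)
    assert np.all((ratios > 0.5) & (ratios < 2.0))
    assert 0.7 < np.median(ratios) < 1.4


def test_degenerate_pair_raises():
    labels = np.array([1] * 3 + [0] * 6)
    perfect = labels.astype(float)  # AUC 1, zero-variance placements
    reversed_ = 1.0 - labels  # AUC 0, zero-variance placements
    with pytest.raises(DegenerateComparisonError):
        delong_test(perfect, reversed_, labels)


# -- selection logic ----------------------------------------------------


def _score_vectors():
    """Deterministic 6/12 validation score sets with known AUC structure.

    NEAR_NULL interleaves positives evenly among negatives (AUC exactly
    0.5); PERFECT/ANTI give the positives the top/bottom six scores (AUC
    1 and 0); FAR_NULL shifts positives upward (AUC 0.71, outside any
    reasonable admissibility band).
    """
    grid = np.round(np.linspace(0.05, 0.95, 18), 3)

    def at(pos_positions):
        neg_positions = sorted(set(range(18)) - set(pos_positions))
        return list(grid[pos_positions]) + list(grid[neg_positions])

    return {
        "NEAR_NULL": at([1, 4, 7, 10, 13, 16]),
        "PERFECT": at([12, 13, 14, 15, 16, 17]),
        "ANTI": at([0, 1, 2, 3, 4, 5]),
        "FAR_NULL": at([6, 8, 10, 12, 14, 16]),
    }


_V = _score_vectors()
NEAR_NULL, PERFECT, ANTI, FAR_NULL = (
    _V["NEAR_NULL"], _V["PERFECT"], _V["ANTI"], _V["FAR_NULL"]
)


def _prediction_frame(cases):
    """cases: list of (coordinate, real_scores, null_scores); 6 pos / 12 neg."""
    labels = [1] * 6 + [0] * 12
    rows = []
    for coord, real, null in cases:
        for kind, scores in (("real", real), ("null", null)):
            for pid, (s, y) in enumerate(zip(scores, labels)):
                rows.append(
                    {
                        "replica": 1, "projection": "axial", "slab": 2,
                        "coordinate": coord, "patient_id": f"p{pid}",
                        "true_label": y, "score": s, "model_kind": kind,
                    }
                )
    return pd.DataFrame(rows)


def test_selection_requires_band_z_and_direction():
    frame = _prediction_frame(
        [
            (40, PERFECT, NEAR_NULL),  # admissible null, real towards 1 -> selected
            (41, ANTI, NEAR_NULL),  # significant but towards 0 -> rejected
            (42, PERFECT, FAR_NULL),  # null outside the band -> rejected
        ]
    )
    records = build_selection_table(frame, delta=0.1)
    by_coord = records.set_index("coordinate")
    assert bool(by_coord.loc[40, "selected"])
    assert by_coord.loc[40, "z"] > 1.96
    assert not by_coord.loc[41, "selected"]
    assert by_coord.loc[41, "z"] < -1.96
    assert not by_coord.loc[42, "selected"]
    assert not by_coord.loc[42, "null_admissible"]


def test_default_delta_is_unit_granularity():
    frame = _prediction_frame([(40, PERFECT, NEAR_NULL)])
    records = build_selection_table(frame)
    assert records.loc[0, "delta"] == pytest.approx(1 / 72)
    assert round(records.loc[0, "delta"], 4) == 0.0139


def test_selection_invariant_under_monotone_transform():
    frame = _prediction_frame([(40, PERFECT, NEAR_NULL), (41, ANTI, NEAR_NULL)])
    warped = frame.copy()
    warped["score"] = np.exp(3.0 * warped["score"])  # strictly increasing
    a = build_selection_table(frame, delta=0.1)
    b = build_selection_table(warped, delta=0.1)
    pd.testing.assert_frame_equal(a, b)


def test_degenerate_units_kept_as_untestable():
    labels_scores = [1.0] * 6 + [0.0] * 12
    frame = _prediction_frame([(40, labels_scores, [1.0 - s for s in labels_scores])])
    records = build_selection_table(frame, delta=0.6)
    assert np.isnan(records.loc[0, "z"])
    assert not records.loc[0, "selected"]


def test_missing_null_model_is_an_error():
    frame = _prediction_frame([(40, PERFECT, NEAR_NULL)])
    with pytest.raises(ValueError, match="null"):
        build_selection_table(frame[frame["model_kind"] == "real"])


def test_select_significant_groups_and_multi_slice_classifiers():
    frame = _prediction_frame(
        [(40, PERFECT, NEAR_NULL), (41, PERFECT, NEAR_NULL), (42, ANTI, NEAR_NULL)]
    )
    records = build_selection_table(frame, delta=0.1)
    summary = select_significant(records)
    assert summary["significant_slices"]["axial"] == [40, 41]
    assert summary["n_tests"] == 3
    assert summary["n_selected"] == 2
    # replica 1 selected on two distinct slices -> reported as multi-slice
    assert summary["multi_slice_classifiers"] == [
        {"projection": "axial", "replica": 1, "n_slices": 2}
    ]
    lo, hi = summary["auc_real_ranges"]["axial"]
    assert lo == hi == 1.0
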