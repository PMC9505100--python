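"""Disability-progression labels from baseline/follow-up EDSS pairs.

The Expanded Disability Status Scale (EDSS) is a clinician-assigned
score on a 0-10 half-point grid.  Progression at follow-up is defined by
a baseline-dependent increment: >= 1.5 points from a baseline of 0,
>= 1.0 point from baselines 1.0-5.0, and >= 0.5 points from baselines of
5.5 or higher.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["progression_threshold", "progression_label", "label_table"]

logger = logging.getLogger(__name__)

_TOL = 1e-9


def _validate_edss(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 10.0:
        raise ValueError(f"{name}={value} outside the EDSS range [0, 10]")
    if abs(value * 2 - round(value * 2)) > _TOL:
        raise ValueError(f"{name}={value} is not on the 0.5-point EDSS grid")
    return value


def progression_threshold(edss_baseline: float) -> float:
    """Minimum EDSS increase that counts as progression for a baseline.

    A baseline of 0.5 falls between the defined branches (0; 1.0-5.0;
    >=5.5); it is treated like the 1.0-5.0 branch (1-point threshold) and
    a warning is logged.
    """
    b = _validate_edss(edss_baseline, "edss_baseline")
    if b == 0.0:
        return 1.5
    if b == 0.5:
        logger.warning(
            "baseline EDSS 0.5 is not covered by the progression rule; "
            "applying the 1-point threshold"
        )
        return 1.0
    if b <= 5.0:
        return 1.0
    return 0.5


def progression_label(edss_baseline: float, edss_followup: float) -> int:
    """1 if the follow-up increase meets the baseline's threshold, else 0."""
    b = _validate_edss(edss_baseline, "edss_baseline")
    f = _validate_edss(edss_followup, "edss_followup")
    return int(f - b >= progression_threshold(b) - _TOL)


def label_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Append a ``label`` column to a patient table.

    Expects columns ``edss_baseline`` and ``edss_followup``; returns a
    copy with ``label`` (1 = progressed).
    """
    for col in ("edss_baseline", "edss_followup"):
        if col not in patients.columns:
            raise ValueError(f"patient table lacks required column {col!r}")
    out = patients.copy()
    out["label"] = [
        progression_label(b, f)
        for b, f in zip(out["edss_baseline"], out["edss_followup"])
    ]
    return out
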