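"""Excessive-trabeculation criteria and cohort summaries.

Two structural criteria define excessive trabeculation (ET): a trabecular to
compact thickness ratio T/C strictly greater than 2.3 in at least one of
segments 1-16 (Petersen-type thickness criterion), or a trabecular volume
strictly exceeding 25 % of the total LV wall volume (Grothoff-type volume
criterion).  Equality is negative.  "Abnormal but ET-negative" is a
caller-supplied annotation: morphological abnormality is a qualitative call
that the two criteria alone cannot compute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import VolumeReport
from .segments import SegmentMetrics

__all__ = ["DiagnosticCriteria", "DiagnosticResult", "diagnose",
           "summarize_cohort"]


@dataclass(frozen=True)
class DiagnosticCriteria:
    tc_threshold: float = 2.3
    volume_threshold: float = 25.0     # % of LV wall volume
    tc_scope: tuple[int, int] = (1, 16)

    def __post_init__(self) -> None:
        if self.tc_threshold <= 0 or self.volume_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DiagnosticResult:
    max_TC: float
    segments_over_TC: int
    trab_fraction: float              # %
    tc_positive: bool
    volume_positive: bool
    category: str                     # normal / abnormal / excessively_trabeculated
    group_annotation: str | None = None


def diagnose(metrics: SegmentMetrics, volumes: VolumeReport,
             criteria: DiagnosticCriteria = DiagnosticCriteria(),
             abnormal: bool = False) -> DiagnosticResult:
    """Apply the ET criteria to one heart's per-segment metrics and volumes.

    Both comparisons are strict: a segment counts only if T/C > threshold,
    and the volume criterion fires only if the trabecular fraction exceeds
    (not equals) the volume threshold.  ``abnormal`` is the caller's
    qualitative annotation and only decides between the two ET-negative
    categories.
    """
    lo, hi = criteria.tc_scope
    tcs = [metrics.tc[s] for s in range(lo, hi + 1)
           if s in metrics.tc and not math.isnan(metrics.tc[s])]
    if not tcs:
        raise ValueError("no segment T/C values available")
    max_tc = max(tcs)
    n_over = sum(1 for v in tcs if v > criteria.tc_threshold)
    frac = volumes.lv_trab_fraction
    tc_pos = n_over >= 1
    vol_pos = frac > criteria.volume_threshold
    if tc_pos or vol_pos:
        category = "excessively_trabeculated"
    else:
        category = "abnormal" if abnormal else "normal"
    return DiagnosticResult(max_TC=max_tc, segments_over_TC=n_over,
                            trab_fraction=frac, tc_positive=tc_pos,
                            volume_positive=vol_pos, category=category)


def summarize_cohort(rows: list[dict]) -> pd.DataFrame:
    """Summarize per-heart diagnostic rows by group.

    ``rows`` carry, per heart: group, average_tc, summed_tc, trab_fraction,
    max_tc, segments_over_tc, volume_positive.  Returns one row per group
    with Ns, counts over thresholds and mean (SD) of the continuous
    measures.  SD of a single-heart group is reported as NaN (undefined by
    convention, sample SD needs n >= 2).
    """
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows)
    if (df.groupby("group").size() < 1).any():
        raise ValueError("every group needs at least one heart")

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "N": len(g),
            "n_tc_gt_2": int((g["max_tc"] > 2.0).sum()),
            "n_tc_gt_2.3": int((g["max_tc"] > 2.3).sum()),
            "n_vol_gt_25": int((g["trab_fraction"] > 25.0).sum()),
            "average_tc_mean": g["average_tc"].mean(),
            "average_tc_sd": g["average_tc"].std(ddof=1),
            "summed_tc_mean": g["summed_tc"].mean(),
            "summed_tc_sd": g["summed_tc"].std(ddof=1),
            "trab_fraction_mean": g["trab_fraction"].mean(),
            "trab_fraction_sd": g["trab_fraction"].std(ddof=1),
        })

    out = df.groupby("group", sort=True).apply(_agg, include_groups=False)
    return out.reset_index()
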