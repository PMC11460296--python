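"""Cohort-level statistical reporting: volumes, t-based 95% confidence
intervals, gland-volume quartile stratification, Welch volume comparison and
one-tailed paired model comparison.

Quartiles are an exact partition: cases are ranked by reference gland volume
(ties broken by case id) and split into four contiguous groups whose sizes
differ by at most one -- the empirical 25/50/75 percentile split with a
documented tie-break.  Confidence intervals are normal-theory t intervals;
no multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import EvalRecord, records_to_frame

__all__ = ["mask_volume_cm3", "ci95", "quartile_stratify", "CohortSummary",
           "summarize_cohort", "compare_volumes_unpooled",
           "compare_models_paired"]


def mask_volume_cm3(mask: np.ndarray, spacing) -> float:
    """Voxel count x voxel volume (mm^3) / 1000."""
    return float(np.asarray(mask).astype(bool).sum()
                 * np.prod(np.asarray(spacing, dtype=float)) / 1000.0)


def ci95(values: Sequence[float]) -> Tuple[float, float, float, float]:
    """(mean, lower, upper, median) using the t interval
    mean +/- t_{0.975, n-1} * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("confidence interval needs n >= 2")
    mean = float(v.mean())
    half = float(stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))
    return mean, mean - half, mean + half, float(np.median(v))


@dataclass
class CohortSummary:
    """Per-cohort descriptives plus the per-quartile Dice block."""

    n: int
    stats: Dict[str, dict] = field(default_factory=dict)      # metric -> summary
    quartiles: Dict[str, dict] = field(default_factory=dict)  # Q1..Q4 -> summary

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(level="cohort", name=k, **v) for k, v in self.stats.items()]
        rows += [dict(level="quartile", name=k, **v)
                 for k, v in self.quartiles.items()]
        return pd.DataFrame(rows)


def _summary(values) -> dict:
    mean, lo, hi, med = ci95(values)
    return {"mean": mean, "ci_lower": lo, "ci_upper": hi, "median": med,
            "n": len(values)}


def quartile_stratify(records: Sequence[EvalRecord]) -> Dict[str, dict]:
    """Split cases into Q1-Q4 by reference gland volume; per-quartile Dice
    mean/median/CI.  Requires n >= 4 gland records."""
    gl = [r for r in records if r.structure == "gland"]
    if len(gl) < 4:
        raise ValueError("quartile stratification needs at least 4 cases")
    order = sorted(range(len(gl)),
                   key=lambda i: (gl[i].reference_volume_cm3, str(gl[i].case_id)))
    groups = np.array_split(np.asarray(order), 4)
    out = {}
    for qi, grp in enumerate(groups, start=1):
        dice = [gl[i].dice for i in grp]
        vols = [gl[i].reference_volume_cm3 for i in grp]
        entry = _summary(dice) if len(dice) >= 2 else {
            "mean": float(np.mean(dice)), "ci_lower": np.nan,
            "ci_upper": np.nan, "median": float(np.median(dice)),
            "n": len(dice)}
        entry["volume_range_cm3"] = (float(min(vols)), float(max(vols)))
        entry["case_ids"] = [gl[i].case_id for i in grp]
        out[f"Q{qi}"] = entry
    return out


def summarize_cohort(records: Sequence[EvalRecord]) -> CohortSummary:
    """Full cohort summary: Dice/HD/volume descriptives per structure plus the
    gland-volume quartile block."""
    df = records_to_frame(records)
    n_cases = df["case_id"].nunique()
    summary = CohortSummary(n=int(n_cases))
    for structure, sub in df.groupby("structure"):
        summary.stats[f"dice_{structure}"] = _summary(sub["dice"].to_numpy())
        hd = sub["hausdorff_mm"].dropna().to_numpy()
        if hd.size >= 2:
            summary.stats[f"hausdorff_mm_{structure}"] = _summary(hd)
        summary.stats[f"reference_volume_cm3_{structure}"] = _summary(
            sub["reference_volume_cm3"].to_numpy())
        summary.stats[f"predicted_volume_cm3_{structure}"] = _summary(
            sub["predicted_volume_cm3"].to_numpy())
    summary.quartiles = quartile_stratify(records)
    return summary


def compare_volumes_unpooled(a: Sequence[float], b: Sequence[float]
                             ) -> Tuple[float, float]:
    """Welch (unpooled) two-sample t-test, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_models_paired(scores_a: Sequence[float], scores_b: Sequence[float],
                          alpha: float = 0.05
                          ) -> Tuple[float, float, Optional[str]]:
    """One-tailed paired t-test in the direction of the larger sample mean.

    Returns ``(t, one_tailed_p, winner)``; ``winner`` is 'a', 'b', or None
    when the difference is not significant at ``alpha`` ("statistically the
    same").  All-zero differences are a declared tie with p = 0.5.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have equal length")
    d = b - a
    if np.all(d == 0):
        return 0.0, 0.5, None
    direction = "b" if d.mean() > 0 else "a"
    if d.std(ddof=1) == 0:
        # constant nonzero difference: limit of the t statistic
        return float(np.sign(d.mean()) * np.inf), 0.0, direction
    alt = "greater" if direction == "b" else "less"
    t, p = stats.ttest_rel(b, a, alternative=alt)
    winner = direction if p < alpha else None
    return float(t), float(p), winner
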