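"""Behavioral performance measures.

Percent correct, mean RT and RT SD per condition, with a single-pass
2.5-SD reaction-time outlier rule and the 65%-correct recording-validity
criterion. Conditions: Target (oddball response), Go (response) and NoGo
(correct = withheld response); RT statistics are computed over correct,
outlier-excluded responses of one subject × visit × condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCORED_CONDITIONS = ("Target", "Go", "NoGo")


def exclude_rt_outliers(
    rts: "np.ndarray | list[float]", k: float = 2.5
) -> tuple[np.ndarray, float]:
    """Drop RTs further than ``k`` sample SDs from the mean.

    Mean and SD are computed once on the full list (single pass, no
    re-iteration). Returns (retained RTs, excluded fraction in %).
    With zero SD nothing is excluded.
    """
    x = np.asarray(rts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 reaction times")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return x, 0.0
    keep = np.abs(x - mu) <= k * sd
    return x[keep], 100.0 * (1.0 - keep.mean())


@dataclass
class ConditionSummary:
    percent_correct: float
    rt_mean: float | None = None
    rt_sd: float | None = None
    excluded_fraction: float = 0.0
    n_trials: int = 0


@dataclass
class BehavioralSummary:
    conditions: dict[str, ConditionSummary] = field(default_factory=dict)
    valid_recording: bool = True

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": c, **vars(s)} for c, s in self.conditions.items()
        ]
        return pd.DataFrame(rows)


def summarize_behavior(record: pd.DataFrame, k: float = 2.5) -> BehavioralSummary:
    """Per-condition percent correct and RT statistics for one recording.

    Percent correct uses all trials of the condition as denominator. RT
    mean/SD (sample SD, n−1) are taken over correct responses after the
    ``k``-SD outlier rule; NoGo is summarized by percent correct only. The
    recording is valid iff the overall percent correct across scored
    conditions is at least 65%.
    """
    out = BehavioralSummary()
    n_correct_total = 0
    n_total = 0
    for cond in SCORED_CONDITIONS:
        trials = record[record["condition"] == cond]
        if trials.empty:
            continue
        correct = trials["correct"].astype(bool)
        n = len(trials)
        pc = 100.0 * correct.sum() / n
        summary = ConditionSummary(percent_correct=float(pc), n_trials=n)
        if cond != "NoGo":
            rts = trials.loc[correct & trials["responded"], "rt_ms"].to_numpy(float)
            if rts.size >= 2:
                kept, frac = exclude_rt_outliers(rts, k)
                summary.rt_mean = float(kept.mean())
                summary.rt_sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
                summary.excluded_fraction = frac
            elif rts.size == 1:
                summary.rt_mean = float(rts[0])
        out.conditions[cond] = summary
        n_correct_total += int(correct.sum())
        n_total += n
    if n_total:
        out.valid_recording = (100.0 * n_correct_total / n_total) >= 65.0
    return out


def behavior_table(
    records: "list[pd.DataFrame]", k: float = 2.5
) -> pd.DataFrame:
    """Tidy per-subject×visit×condition behavioral summary table."""
    rows = []
    for rec in records:
        summary = summarize_behavior(rec, k)
        subject = rec["subject"].iloc[0] if "subject" in rec else ""
        visit = rec["visit"].iloc[0] if "visit" in rec else None
        task = rec["task"].iloc[0] if "task" in rec else ""
        for cond, s in summary.conditions.items():
            rows.append(
                {
                    "subject": subject,
                    "visit": visit,
                    "task": task,
                    "condition": cond,
                    "percent_correct": s.percent_correct,
                    "rt_mean": s.rt_mean,
                    "rt_sd": s.rt_sd,
                    "excluded_fraction": s.excluded_fraction,
                    "valid_recording": summary.valid_recording,
                }
            )
    return pd.DataFrame(rows)
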