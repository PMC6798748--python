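"""Response-quality screening.

Four per-respondent criteria, each a pass/fail flag:

* desirability — prioritized the dominant profile in the dominance task;
* stability   — priority answer on the repeat task matches its original;
* consistency — whenever exactly one profile was admitted, priority names it
  (up to a configurable number of violations);
* response time — median per-task time at or above a floor.

The thresholds are reconstructions and configurable; by default respondents
are reported, not filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ChoiceDesign, dominates
from .errors import DataError

__all__ = ["QualityReport", "assess_quality", "quality_summary", "reports_frame"]

CRITERIA = ("desirability", "stability", "consistency", "response_time")


@dataclass(frozen=True)
class QualityReport:
    respondent_id: int
    desirability_pass: bool
    stability_pass: bool
    consistency_pass: bool
    response_time_pass: bool

    @property
    def n_failed(self) -> int:
        return sum(
            not flag
            for flag in (
                self.desirability_pass,
                self.stability_pass,
                self.consistency_pass,
                self.response_time_pass,
            )
        )


def _priority_of(task_rows: pd.DataFrame) -> str:
    chosen = task_rows.loc[task_rows["priority_chosen"] == 1, "alternative"]
    if len(chosen) != 1:
        raise DataError(
            f"task {task_rows['task_id'].iloc[0]}: expected exactly one "
            "prioritized alternative"
        )
    return str(chosen.iloc[0])


def assess_quality(
    responses: pd.DataFrame,
    design: ChoiceDesign,
    min_median_ms: int = 2000,
    max_inconsistencies: int = 1,
) -> list[QualityReport]:
    """Apply the four criteria to every respondent in a long-format table.

    Each flag depends only on that respondent's rows plus the design.
    """
    tasks = {t.task_id: t for t in design.tasks}
    reports = []
    for rid, rows in responses.groupby("respondent_id", sort=True):
        dom_rows = rows[rows["task_type"] == "dominance"]
        rep_rows = rows[rows["task_type"] == "repeat"]
        if dom_rows.empty or rep_rows.empty:
            raise DataError(
                f"respondent {rid}: block lacks a dominance or repeat task"
            )

        # desirability: which alternative of the dominance task is dominant?
        dom_task = tasks[int(dom_rows["task_id"].iloc[0])]
        if dominates(dom_task.profile_a, dom_task.profile_b, design.attributes):
            dominant = "A"
        elif dominates(dom_task.profile_b, dom_task.profile_a, design.attributes):
            dominant = "B"
        else:
            raise DataError(
                f"task {dom_task.task_id} is labelled dominance but neither "
                "profile dominates"
            )
        desirability = _priority_of(dom_rows) == dominant

        # stability: repeat priority equals the original task's priority
        stability = True
        for tid, grp in rep_rows.groupby("task_id"):
            src = tasks[int(tid)].repeat_of
            orig = rows[rows["task_id"] == src]
            if orig.empty:
                raise DataError(
                    f"respondent {rid}: repeat task {tid} references task "
                    f"{src} which the respondent never answered"
                )
            if _priority_of(grp) != _priority_of(orig):
                stability = False

        # consistency: exactly-one-admitted tasks must prioritize the admitted
        violations = 0
        for tid, grp in rows.groupby("task_id"):
            admits = grp.set_index("alternative")["admit"]
            if int(admits.sum()) == 1:
                admitted = str(admits.idxmax())
                if _priority_of(grp) != admitted:
                    violations += 1
        consistency = violations <= max_inconsistencies

        # response time: one time per task (constant across the two rows)
        per_task = rows.groupby("task_id")["response_time_ms"].first()
        response_time = float(np.median(per_task)) >= min_median_ms

        reports.append(
            QualityReport(int(rid), desirability, stability, consistency, response_time)
        )
    return reports


def reports_frame(reports: Sequence[QualityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in reports],
            "desirability": [r.desirability_pass for r in reports],
            "stability": [r.stability_pass for r in reports],
            "consistency": [r.consistency_pass for r in reports],
            "response_time": [r.response_time_pass for r in reports],
            "n_failed": [r.n_failed for r in reports],
        }
    )


def quality_summary(reports: Sequence[QualityReport]) -> dict:
    """Sample-level pass rates."""
    if not reports:
        raise DataError("no quality reports to summarize")
    n = len(reports)
    frame = reports_frame(reports)
    return {
        "n_respondents": n,
        "proportion_all_pass": float((frame["n_failed"] == 0).sum()) / n,
        "max_failures_observed": int(frame["n_failed"].max()),
        "pass_rates": {
            crit: float(frame[crit].sum()) / n for crit in CRITERIA
        },
    }
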