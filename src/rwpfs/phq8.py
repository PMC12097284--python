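"""PHQ-8 trajectory statistics and the progressed-vs-nonprogressed contrast.

The PHQ-8 is an eight-item depression questionnaire scored 0-24.  Two
trajectory summaries are computed per patient over the study period: *peak
reduction*, the largest decrease between any two chronologically ordered
scores (0 when no decrease exists), and *cumulative decline*, the sum of all
positive decreases across ordered score pairs.  Patients need at least two
in-window scores to be eligible.  Group means are compared with a pooled
(Student) two-sample t test — the degrees of freedom n_a + n_b - 2 match the
published convention.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .ehr import CohortBundle
from .survival import SurvivalRecord


class Phq8Series(BaseModel):
    patient_id: str
    scores: list[tuple[dt.date, int]] = Field(min_length=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Phq8Series":
        dates = [d for d, _ in self.scores]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("PHQ-8 dates must be strictly increasing")
        if any(not 0 <= s <= 24 for _, s in self.scores):
            raise ValueError("PHQ-8 scores must lie in [0, 24]")
        return self


class GroupComparison(BaseModel):
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _df(self) -> "GroupComparison":
        if self.df != self.n_a + self.n_b - 2:
            raise ValueError("pooled t test requires df = n_a + n_b - 2")
        return self


def _pairwise_drops(values: Sequence[int], consecutive_only: bool):
    if consecutive_only:
        return (values[i] - values[i + 1] for i in range(len(values) - 1))
    return (
        values[i] - values[j]
        for i in range(len(values))
        for j in range(i + 1, len(values))
    )


def peak_reduction(series: Phq8Series, consecutive_only: bool = False) -> float:
    """Largest decrease between any two ordered scores, floored at zero."""
    if len(series.scores) < 2:
        raise ValueError("peak_reduction requires at least two scores")
    values = [s for _, s in series.scores]
    return float(max(0, max(_pairwise_drops(values, consecutive_only))))


def cumulative_decline(series: Phq8Series, consecutive_only: bool = False) -> float:
    """Sum of all positive decreases across ordered score pairs."""
    if len(series.scores) < 2:
        raise ValueError("cumulative_decline requires at least two scores")
    values = [s for _, s in series.scores]
    return float(sum(d for d in _pairwise_drops(values, consecutive_only) if d > 0))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Pooled-variance two-sample t test (two-sided) between value groups."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    a_arr, b_arr = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a_arr, b_arr, equal_var=True)
    if np.isnan(p):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return GroupComparison(
        n_a=len(a), n_b=len(b),
        mean_a=float(a_arr.mean()), sd_a=float(a_arr.std(ddof=1)),
        mean_b=float(b_arr.mean()), sd_b=float(b_arr.std(ddof=1)),
        t_statistic=float(t), df=len(a) + len(b) - 2, p_value=float(p),
    )


def compare_groups_from_summary(
    n_a: int, mean_a: float, sd_a: float,
    n_b: int, mean_b: float, sd_b: float,
) -> GroupComparison:
    """Pooled t test from group summaries (n, mean, sd) alone."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    return GroupComparison(
        n_a=n_a, n_b=n_b, mean_a=mean_a, sd_a=sd_a, mean_b=mean_b, sd_b=sd_b,
        t_statistic=float(t), df=n_a + n_b - 2, p_value=float(p),
    )


def eligible_series(
    bundle: CohortBundle,
    min_scores: int = 2,
    window: Optional[tuple[dt.date, dt.date]] = None,
) -> list[Phq8Series]:
    """Per-patient PHQ-8 series with at least ``min_scores`` in-window scores."""
    lo, hi = window if window else (bundle.study_start, bundle.study_end)
    per: dict[str, list[tuple[dt.date, int]]] = {}
    for rec in bundle.phq8_records:
        if lo <= rec.record_date <= hi:
            per.setdefault(rec.patient_id, []).append((rec.record_date, rec.score))
    out = []
    for pid in sorted(per):
        scores = sorted(per[pid])
        # same-day duplicates are collapsed to the highest score
        dedup: list[tuple[dt.date, int]] = []
        for d, s in scores:
            if dedup and dedup[-1][0] == d:
                dedup[-1] = (d, max(dedup[-1][1], s))
            else:
                dedup.append((d, s))
        if len(dedup) >= min_scores:
            out.append(Phq8Series(patient_id=pid, scores=dedup))
    return out


def split_by_progression(
    values: Mapping[str, float],
    records: Sequence[SurvivalRecord],
) -> tuple[list[float], list[float]]:
    """(nonprogressed, progressed) value lists keyed on rwPFS event status."""
    progressed = {r.patient_id for r in records if r.event}
    known = {r.patient_id for r in records}
    non, prog = [], []
    for pid in sorted(values):
        if pid not in known:
            continue
        (prog if pid in progressed else non).append(values[pid])
    return non, prog
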