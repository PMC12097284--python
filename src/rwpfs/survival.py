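"""Survival-record assembly and Kaplan-Meier rwPFS / rwOS estimation.

Real-world progression-free survival (rwPFS) runs from the therapy index
date to the earliest of the first text-captured progression (ignoring
captures inside the first 30 days of therapy, which cannot reflect treatment
effect) and the advancement to a new therapy line; death, loss to follow-up
(last encounter) and the end of the study period censor.  Real-world overall
survival (rwOS) runs from the index date to death.  Durations are reported
in months using the mean Gregorian month of 30.4375 days — the single
conversion constant for the whole package.

Curve fitting is delegated to lifelines' product-limit estimator; the curve
object additionally carries the Greenwood variance, from which medians and
their 95% confidence intervals are derived via the log(-log) (Kalbfleisch-
Prentice) pointwise bands intersected with 0.5.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import defaultdict
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from pydantic import BaseModel, Field, model_validator

from .ehr import CohortBundle, NoteType
from .progression import ProgressionCapture
from .structured import CohortMember, LineAdvancementEvent, TherapyConfig, detect_line_advancement

#: days per month; the only place this conversion lives
MONTH_DAYS = 30.4375

_Z95 = 1.959963984540054


def days_to_months(days: float) -> float:
    return days / MONTH_DAYS


class EventType(str, Enum):
    nlp_progression = "nlp_progression"
    line_advancement = "line_advancement"
    death_event = "death_event"
    none = "none"


class EventSource(str, Enum):
    clinical_document = "clinical_document"
    radiology_report = "radiology_report"
    structured = "structured"
    none = "none"


class CensorType(str, Enum):
    last_encounter = "last_encounter"
    death = "death"
    end_of_study = "end_of_study"
    none = "none"


class SourceFilter(str, Enum):
    pooled = "pooled"
    radiology_only = "radiology_only"
    clinical_only = "clinical_only"


class SurvivalRecord(BaseModel):
    patient_id: str
    index_date: dt.date
    duration_months: float = Field(ge=0.0)
    event: bool
    event_type: EventType = EventType.none
    event_source: EventSource = EventSource.none
    censor_type: CensorType = CensorType.none

    @model_validator(mode="after")
    def _consistent(self) -> "SurvivalRecord":
        if self.event == (self.censor_type is not CensorType.none):
            raise ValueError("record must be either an event or censored, not both")
        return self


class KMCurve(BaseModel):
    """Product-limit curve evaluated at the distinct event times."""

    event_times: list[float]
    survival: list[float]
    variance: list[float]  # Greenwood variance of S at each event time
    at_risk: list[int]
    n_total: int

    @model_validator(mode="after")
    def _shape(self) -> "KMCurve":
        k = len(self.event_times)
        if not (len(self.survival) == len(self.variance) == len(self.at_risk) == k):
            raise ValueError("curve arrays must have equal length")
        if any(b > a + 1e-12 for a, b in zip(self.survival, self.survival[1:])):
            raise ValueError("survival must be non-increasing")
        return self


class MedianEstimate(BaseModel):
    """Median survival in months with 95% CI; None encodes not-reached."""

    median_months: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


class LogRankResult(BaseModel):
    statistic: float = Field(ge=0.0)
    p_value: float = Field(ge=0.0, le=1.0)


# --------------------------------------------------------------------------
# record assembly

_CENSOR_PRIORITY = {
    CensorType.death: 0,
    CensorType.last_encounter: 1,
    CensorType.end_of_study: 2,
}


def assemble_rwpfs_record(
    patient_id: str,
    index_date: dt.date,
    captures: Sequence[ProgressionCapture],
    advancement: Optional[LineAdvancementEvent],
    death_date: Optional[dt.date],
    last_encounter: Optional[dt.date],
    study_end: Optional[dt.date],
    *,
    early_exclusion_days: int = 30,
) -> SurvivalRecord:
    """Build one patient's rwPFS record from candidate events and censors.

    The candidate event is the earlier of the first capture dated strictly
    more than ``early_exclusion_days`` after the index (earlier captures are
    dropped, not the patient) and the line-advancement date; the candidate
    censor date is the earliest of death, last encounter and study end
    (ties resolve death > last_encounter > end_of_study).  A tie between
    event and censor dates counts as an event; a same-day progression /
    advancement tie counts as progression.
    """
    if index_date is None:
        raise ValueError("rwPFS assembly requires an index date")
    cutoff = index_date + dt.timedelta(days=early_exclusion_days)
    event_candidates: list[tuple[dt.date, int, EventType, EventSource]] = []
    qualifying = [
        cap for cap in captures
        if cap.patient_id == patient_id and cap.capture_date > cutoff
    ]
    if qualifying:
        first = min(qualifying, key=lambda c: (c.capture_date, c.note_id))
        event_candidates.append((
            first.capture_date, 0, EventType.nlp_progression,
            EventSource(first.note_type.value),
        ))
    if advancement is not None:
        event_candidates.append((
            advancement.advancement_date, 1, EventType.line_advancement,
            EventSource.structured,
        ))

    censor_candidates = [
        (d, _CENSOR_PRIORITY[t], t)
        for d, t in ((death_date, CensorType.death),
                     (last_encounter, CensorType.last_encounter),
                     (study_end, CensorType.end_of_study))
        if d is not None
    ]
    if not censor_candidates:
        raise ValueError(f"patient {patient_id}: nothing to censor on")
    censor_date, _, censor_type = min(censor_candidates)

    if event_candidates:
        event_date, _, etype, esource = min(event_candidates)
        if event_date <= censor_date:
            return SurvivalRecord(
                patient_id=patient_id, index_date=index_date,
                duration_months=days_to_months((event_date - index_date).days),
                event=True, event_type=etype, event_source=esource,
            )
    duration = max((censor_date - index_date).days, 0)
    return SurvivalRecord(
        patient_id=patient_id, index_date=index_date,
        duration_months=days_to_months(duration),
        event=False, censor_type=censor_type,
    )


def assemble_rwos_record(
    patient_id: str,
    index_date: dt.date,
    death_date: Optional[dt.date],
    last_encounter: Optional[dt.date],
    study_end: Optional[dt.date],
) -> SurvivalRecord:
    """One patient's rwOS record: death is the event, follow-up censors."""
    if index_date is None:
        raise ValueError("rwOS assembly requires an index date")
    censor_candidates = [
        (d, prio, t)
        for d, prio, t in ((last_encounter, 0, CensorType.last_encounter),
                           (study_end, 1, CensorType.end_of_study))
        if d is not None
    ]
    if not censor_candidates:
        raise ValueError(f"patient {patient_id}: nothing to censor on")
    censor_date, _, censor_type = min(censor_candidates)
    if death_date is not None and (study_end is None or death_date <= study_end):
        return SurvivalRecord(
            patient_id=patient_id, index_date=index_date,
            duration_months=days_to_months((death_date - index_date).days),
            event=True, event_type=EventType.death_event,
            event_source=EventSource.structured,
        )
    return SurvivalRecord(
        patient_id=patient_id, index_date=index_date,
        duration_months=days_to_months(max((censor_date - index_date).days, 0)),
        event=False, censor_type=censor_type,
    )


# --------------------------------------------------------------------------
# estimation

def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Fit the product-limit estimator and attach Greenwood variances."""
    if not records:
        raise ValueError("km_fit requires at least one record")
    durations = np.array([r.duration_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index[mask].to_numpy(dtype=float)
    d = table.loc[mask, "observed"].to_numpy(dtype=float)
    n = table.loc[mask, "at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(n > d, d / (n * (n - d)), np.inf)
    cum = np.cumsum(increments)
    variance = np.where(np.isfinite(cum), surv**2 * cum, 0.0)
    return KMCurve(
        event_times=times.tolist(),
        survival=surv.tolist(),
        variance=variance.tolist(),
        at_risk=n.astype(int).tolist(),
        n_total=len(records),
    )


def _loglog_bands(surv: float, var: float) -> tuple[float, float]:
    """Pointwise 95% band for S(t) on the log(-log) scale."""
    if surv >= 1.0:
        return 1.0, 1.0
    if surv <= 0.0:
        return 0.0, 0.0
    se = math.sqrt(max(var, 0.0)) / abs(surv * math.log(surv))
    lower = surv ** math.exp(_Z95 * se)
    upper = surv ** math.exp(-_Z95 * se)
    return lower, upper


def median_survival(curve: KMCurve) -> MedianEstimate:
    """Median (first time S <= 0.5) and its 95% CI from log(-log) bands.

    The CI bounds are the first times the lower / upper pointwise bands drop
    to 0.5; a bound (or the median itself) that never crosses is reported as
    None, mirroring "median not reached".
    """
    median = ci_low = ci_high = None
    for t, s, v in zip(curve.event_times, curve.survival, curve.variance):
        lo, hi = _loglog_bands(s, v)
        if ci_low is None and lo <= 0.5:
            ci_low = t
        if median is None and s <= 0.5:
            median = t
        if ci_high is None and hi <= 0.5:
            ci_high = t
    return MedianEstimate(median_months=median, ci_low=ci_low, ci_high=ci_high)


def log_rank(
    a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank chi-square test with one degree of freedom."""
    if not a or not b:
        raise ValueError("log_rank requires two nonempty groups")
    result = logrank_test(
        np.array([r.duration_months for r in a]),
        np.array([r.duration_months for r in b]),
        event_observed_A=np.array([r.event for r in a], dtype=bool),
        event_observed_B=np.array([r.event for r in b], dtype=bool),
    )
    return LogRankResult(
        statistic=max(float(result.test_statistic), 0.0),
        p_value=min(max(float(result.p_value), 0.0), 1.0),
    )


# --------------------------------------------------------------------------
# cohort-level assembly

def _per_patient_inputs(bundle: CohortBundle):
    last_enc: dict[str, dt.date] = {}
    for e in bundle.encounters:
        cur = last_enc.get(e.patient_id)
        if cur is None or e.encounter_date > cur:
            last_enc[e.patient_id] = e.encounter_date
    deaths = {d.patient_id: d.death_date for d in bundle.deaths}
    orders = defaultdict(list)
    for o in bundle.drug_orders:
        orders[o.patient_id].append(o)
    return last_enc, deaths, orders


def build_rwpfs_records(
    bundle: CohortBundle,
    members: Sequence[CohortMember],
    captures: Sequence[ProgressionCapture],
    therapy: TherapyConfig,
    source_filter: SourceFilter | str = SourceFilter.pooled,
    *,
    early_exclusion_days: int = 30,
) -> list[SurvivalRecord]:
    """Assemble rwPFS records for a cohort, optionally restricting sources.

    ``radiology_only`` / ``clinical_only`` keep captures from the selected
    note type; line advancement (structured data) is always retained.
    """
    source_filter = SourceFilter(source_filter)
    if source_filter is SourceFilter.radiology_only:
        captures = [c for c in captures if c.note_type is NoteType.radiology_report]
    elif source_filter is SourceFilter.clinical_only:
        captures = [c for c in captures if c.note_type is NoteType.clinical_document]
    caps_by_pid: dict[str, list[ProgressionCapture]] = defaultdict(list)
    for c in captures:
        caps_by_pid[c.patient_id].append(c)
    last_enc, deaths, orders = _per_patient_inputs(bundle)
    records = []
    for m in members:
        advancement = detect_line_advancement(orders[m.patient_id], m.index_date, therapy)
        records.append(assemble_rwpfs_record(
            m.patient_id, m.index_date, caps_by_pid.get(m.patient_id, []),
            advancement, deaths.get(m.patient_id), last_enc.get(m.patient_id),
            bundle.study_end, early_exclusion_days=early_exclusion_days,
        ))
    return records


def build_rwos_records(
    bundle: CohortBundle, members: Sequence[CohortMember]
) -> list[SurvivalRecord]:
    last_enc, deaths, _ = _per_patient_inputs(bundle)
    return [
        assemble_rwos_record(
            m.patient_id, m.index_date, deaths.get(m.patient_id),
            last_enc.get(m.patient_id), bundle.study_end,
        )
        for m in members
    ]


def stratified_rwpfs(
    bundle: CohortBundle,
    members: Sequence[CohortMember],
    captures: Sequence[ProgressionCapture],
    therapy: TherapyConfig,
    source_filter: SourceFilter | str = SourceFilter.pooled,
) -> tuple[list[SurvivalRecord], KMCurve, MedianEstimate]:
    """rwPFS restricted to one unstructured source (or pooled)."""
    if not members:
        raise ValueError("stratified_rwpfs requires a nonempty cohort")
    records = build_rwpfs_records(bundle, members, captures, therapy, source_filter)
    curve = km_fit(records)
    return records, curve, median_survival(curve)


class SubgroupResult(BaseModel):
    records: list[SurvivalRecord]
    curve: Optional[KMCurve] = None
    median: Optional[MedianEstimate] = None


def subgroup_rwpfs(
    records: Sequence[SurvivalRecord],
    flags: Mapping[str, tuple[bool, bool]],
) -> dict[tuple[bool, bool], SubgroupResult]:
    """Partition records by (prior_systemic, concomitant_systemic) and fit.

    Empty subgroups are reported as empty results rather than errors; the
    four partitions always sum to the input size.
    """
    groups: dict[tuple[bool, bool], list[SurvivalRecord]] = {
        (a, b): [] for a in (False, True) for b in (False, True)
    }
    for r in records:
        if r.patient_id not in flags:
            raise ValueError(f"no subgroup flags for patient {r.patient_id}")
        groups[tuple(flags[r.patient_id])].append(r)
    out = {}
    for key, recs in groups.items():
        if recs:
            curve = km_fit(recs)
            out[key] = SubgroupResult(
                records=recs, curve=curve, median=median_survival(curve))
        else:
            out[key] = SubgroupResult(records=recs)
    return out


def event_breakdown(records: Sequence[SurvivalRecord]) -> dict[str, int]:
    """Counts of event and censor categories; values sum to len(records)."""
    out = {
        "nlp_progression_clinical": 0,
        "nlp_progression_radiology": 0,
        "line_advancement": 0,
        "death_event": 0,
        "censor_last_encounter": 0,
        "censor_death": 0,
        "censor_end_of_study": 0,
    }
    for r in records:
        if r.event:
            if r.event_type is EventType.nlp_progression:
                key = ("nlp_progression_radiology"
                       if r.event_source is EventSource.radiology_report
                       else "nlp_progression_clinical")
            elif r.event_type is EventType.line_advancement:
                key = "line_advancement"
            else:
                key = "death_event"
        else:
            key = f"censor_{r.censor_type.value}"
        out[key] += 1
    return out
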