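"""Validation metrics, confusion-matrix recovery, ablations, sensitivity.

Patient-level validation compares each patient's first automated progression
capture against a manually abstracted first progression date with a
temporality-aware confusion matrix: a capture counts as a true positive only
within a +/-30-day window of the manual date; captures more than 30 days
early are false positives, captures more than 30 days late are false
negatives.  From the integer counts the usual metrics follow in closed form.

:func:`recover_confusion_matrices` inverts rounded published metrics back to
the integer confusion matrices consistent with them (an exhaustive, exact
enumeration using rational arithmetic and half-up rounding) — the oracle
used to check metric bookkeeping against printed validation tables.

The module also hosts the five-point ablation runner (each ablation disables
one selection condition of the capture pipeline) and the two rwPFS
sensitivity analyses: random removal of progression-event rows, and death
treated as an event instead of a censoring reason.
"""

from __future__ import annotations

import datetime as dt
import math
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .annotate import AnnotatorConfig
from .ehr import CohortBundle
from .progression import extract_progression_captures
from .structured import CohortMember, TherapyConfig
from .survival import (
    CensorType,
    EventSource,
    EventType,
    KMCurve,
    LogRankResult,
    MedianEstimate,
    SurvivalRecord,
    build_rwpfs_records,
    km_fit,
    log_rank,
    median_survival,
)


class ManualAnnotation(BaseModel):
    patient_id: str
    manual_first_progression_date: Optional[dt.date] = None


class ConfusionCounts(BaseModel):
    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    tn: int = Field(ge=0)
    fn: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class MetricsReport(BaseModel):
    """Fractions in [0,1]; a metric with a zero denominator is None."""

    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    precision: Optional[float] = None
    accuracy: Optional[float] = None
    f1: Optional[float] = None


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


class AblationPoint(str, Enum):
    temporal_model = "temporal_model"
    subject_model = "subject_model"
    certainty_model = "certainty_model"
    all_three_models = "all_three_models"
    postprocessing = "postprocessing"


def classify_patient(
    auto_date: Optional[dt.date],
    manual_date: Optional[dt.date],
    window_days: int = 30,
) -> Outcome:
    """Temporality-aware patient classification against the manual date.

    TP: both dates present and within the window.  FP: automated capture
    with no manual event, or automated capture more than ``window_days``
    before the manual date.  FN: manual event missed, or captured more than
    ``window_days`` late.  TN: no event either way.  Exhaustive and mutually
    exclusive; classification uses the single first automated capture.
    """
    if window_days < 0:
        raise ValueError("window_days must be nonnegative")
    if auto_date is None and manual_date is None:
        return Outcome.TN
    if auto_date is not None and manual_date is None:
        return Outcome.FP
    if auto_date is None:
        return Outcome.FN
    delta = (auto_date - manual_date).days
    if abs(delta) <= window_days:
        return Outcome.TP
    return Outcome.FP if delta < 0 else Outcome.FN


def confusion_from_dates(
    auto_dates: Mapping[str, Optional[dt.date]],
    manual_dates: Mapping[str, Optional[dt.date]],
    window_days: int = 30,
) -> ConfusionCounts:
    """Aggregate per-patient classifications over a shared patient set."""
    if set(auto_dates) != set(manual_dates):
        raise ValueError("automated and manual annotations cover different patients")
    counts = {o: 0 for o in Outcome}
    for pid, auto in auto_dates.items():
        counts[classify_patient(auto, manual_dates[pid], window_days)] += 1
    return ConfusionCounts(
        tp=counts[Outcome.TP], fp=counts[Outcome.FP],
        tn=counts[Outcome.TN], fn=counts[Outcome.FN],
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Closed-form metrics; zero-denominator metrics are None, never 0."""
    if c.total == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return MetricsReport(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        precision=ratio(c.tp, c.tp + c.fp),
        accuracy=ratio(c.tp + c.tn, c.total),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


# --------------------------------------------------------------------------
# confusion-matrix recovery from rounded printed metrics

def round_half_up(value: Fraction, decimals: int) -> Fraction:
    """Exact half-up rounding of a rational to ``decimals`` places."""
    scale = Fraction(10) ** decimals
    scaled = value * scale
    floor = scaled.numerator // scaled.denominator
    if (scaled - floor) >= Fraction(1, 2):
        floor += 1
    return Fraction(floor, 1) / scale


def _rounds_to(num: int, den: int, target: Fraction, decimals: int) -> bool:
    if den == 0:
        return False
    return round_half_up(Fraction(100 * num, den), decimals) == target


def _target(value) -> Fraction:
    # accept "97.4", 97.4, Fraction; go through str to dodge binary floats
    return Fraction(str(value))


def recover_confusion_matrices(
    n: int,
    metrics: Mapping[str, float | str],
    decimals: int | Mapping[str, int] = 1,
) -> list[ConfusionCounts]:
    """All integer confusion matrices of size ``n`` matching rounded metrics.

    ``metrics`` maps any subset of {sensitivity, specificity, precision,
    accuracy, f1} to printed percentage values (e.g. ``97.4``); ``decimals``
    is the printed precision, uniform or per metric.  Rounding is exact
    half-up on rationals.  Returns every solution (empty if inconsistent);
    sensitivity/specificity windows prune the enumeration so even n=1000 is
    fast.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    known = {k: _target(v) for k, v in metrics.items()}
    dec = (dict.fromkeys(known, decimals) if isinstance(decimals, int)
           else {k: decimals[k] for k in known})

    def window(key: str) -> Optional[tuple[Fraction, Fraction]]:
        if key not in known:
            return None
        half = Fraction(1, 2 * 10 ** dec[key])
        return known[key] - half, known[key] + half

    sens_w, spec_w = window("sensitivity"), window("specificity")
    solutions: list[ConfusionCounts] = []
    for p in range(n + 1):  # positives = tp + fn
        negs = n - p
        if "sensitivity" in known:
            if p == 0:
                continue  # sensitivity undefined, cannot match a printed value
            lo, hi = sens_w
            tp_lo = math.ceil(lo * p / 100)
            tp_hi = math.floor(hi * p / 100)
            if hi * p / 100 == tp_hi:  # window is half-open on the right
                tp_hi -= 1
            tp_range = range(max(tp_lo, 0), min(tp_hi, p) + 1)
        else:
            tp_range = range(p + 1)
        if "specificity" in known:
            if negs == 0:
                continue
            lo, hi = spec_w
            tn_lo = math.ceil(lo * negs / 100)
            tn_hi = math.floor(hi * negs / 100)
            if hi * negs / 100 == tn_hi:
                tn_hi -= 1
            tn_range = range(max(tn_lo, 0), min(tn_hi, negs) + 1)
        else:
            tn_range = range(negs + 1)
        for tp in tp_range:
            fn = p - tp
            for tn in tn_range:
                fp = negs - tn
                if "precision" in known and not _rounds_to(
                        tp, tp + fp, known["precision"], dec["precision"]):
                    continue
                if "accuracy" in known and not _rounds_to(
                        tp + tn, n, known["accuracy"], dec["accuracy"]):
                    continue
                if "f1" in known and not _rounds_to(
                        2 * tp, 2 * tp + fp + fn, known["f1"], dec["f1"]):
                    continue
                solutions.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    return solutions


# --------------------------------------------------------------------------
# ablation runner

_ABLATION_FLAGS: dict[AblationPoint, dict[str, bool]] = {
    AblationPoint.temporal_model: {"skip_temporality": True},
    AblationPoint.subject_model: {"skip_subject": True},
    AblationPoint.certainty_model: {"skip_certainty": True},
    AblationPoint.all_three_models: {
        "skip_temporality": True, "skip_subject": True, "skip_certainty": True},
    AblationPoint.postprocessing: {"skip_postprocessing": True},
}


class AblationResult(BaseModel):
    point: Optional[AblationPoint] = None
    counts: ConfusionCounts
    metrics: MetricsReport
    median: MedianEstimate
    records: list[SurvivalRecord]


def first_capture_dates(
    captures,
    patient_ids: Iterable[str],
    study_end: Optional[dt.date] = None,
) -> dict[str, Optional[dt.date]]:
    """First capture date per patient (None when absent).

    ``study_end`` clips captures documented after the observation window, so
    post-study documentation does not count against the validation.
    """
    firsts: dict[str, Optional[dt.date]] = {pid: None for pid in patient_ids}
    for c in captures:
        if c.patient_id not in firsts:
            continue
        if study_end is not None and c.capture_date > study_end:
            continue
        cur = firsts[c.patient_id]
        if cur is None or c.capture_date < cur:
            firsts[c.patient_id] = c.capture_date
    return firsts


def run_ablation(
    bundle: CohortBundle,
    members: Sequence[CohortMember],
    config: AnnotatorConfig,
    therapy: TherapyConfig,
    point: Optional[AblationPoint],
    manual: Mapping[str, Optional[dt.date]],
    window_days: int = 30,
) -> AblationResult:
    """Rerun the capture pipeline with one component disabled.

    ``point=None`` runs the full pipeline (the comparison baseline).  Model
    ablations drop the corresponding label filter entirely; the
    postprocessing ablation drops both deduplication and section exclusion.
    Returns patient-level metrics against ``manual`` plus the rwPFS median
    recomputed from the ablated capture set.
    """
    if point is not None and not isinstance(point, AblationPoint):
        point = AblationPoint(point)
    flags = _ABLATION_FLAGS[point] if point is not None else {}
    captures = extract_progression_captures(bundle, config, **flags)
    pids = [m.patient_id for m in members]
    missing = [p for p in pids if p not in manual]
    if missing:
        raise ValueError(f"manual annotations missing for {len(missing)} patients")
    auto = first_capture_dates(captures, pids, study_end=bundle.study_end)
    counts = confusion_from_dates(auto, {p: manual[p] for p in pids}, window_days)
    records = build_rwpfs_records(bundle, members, captures, therapy)
    return AblationResult(
        point=point,
        counts=counts,
        metrics=compute_metrics(counts),
        median=median_survival(km_fit(records)),
        records=records,
    )


# --------------------------------------------------------------------------
# sensitivity analyses

def remove_event_rows(
    records: Sequence[SurvivalRecord],
    fraction: float,
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Remove a share of event rows uniformly at random; censored rows stay."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    event_idx = [i for i, r in enumerate(records) if r.event]
    k = int(round(fraction * len(event_idx)))
    chosen = rng.choice(len(event_idx), size=k, replace=False)
    dropped = {event_idx[j] for j in chosen.tolist()}
    return [r for i, r in enumerate(records) if i not in dropped]


def sensitivity_missingness(
    records: Sequence[SurvivalRecord],
    fractions: Sequence[float] = (0.10, 0.20, 0.30),
    repetitions: int = 1,
    seed: int = 0,
) -> dict[float, list[MedianEstimate]]:
    """Median rwPFS after removing a share of progression-event rows.

    For each fraction and repetition, that share of event rows (rounded to
    the nearest count) is removed uniformly at random — rows are dropped
    from the source data, not converted to censored — and the Kaplan-Meier
    median refitted.  Censored rows are never touched.  Seeded and
    bit-reproducible: each (fraction, repetition) cell derives its own
    generator from the seed.
    """
    results: dict[float, list[MedianEstimate]] = {}
    for fi, frac in enumerate(fractions):
        if not 0.0 <= frac < 1.0:
            raise ValueError("fractions must lie in [0, 1)")
        estimates = []
        for rep in range(repetitions):
            rng = np.random.default_rng(np.random.SeedSequence((seed, fi, rep)))
            subset = remove_event_rows(records, frac, rng)
            estimates.append(median_survival(km_fit(subset)))
        results[frac] = estimates
    return results


def sensitivity_death_handling(
    records: Sequence[SurvivalRecord],
) -> tuple[list[SurvivalRecord], list[SurvivalRecord], LogRankResult]:
    """rwPFS with death as censoring versus death as an event.

    The censored variant is the input (the package default); the event
    variant flips every death-censored row into a ``death_event`` row at the
    same duration.  Returns both variants and their log-rank comparison.
    """
    censored_variant = list(records)
    event_variant = []
    for r in records:
        if not r.event and r.censor_type is CensorType.death:
            event_variant.append(r.model_copy(update={
                "event": True,
                "event_type": EventType.death_event,
                "event_source": EventSource.structured,
                "censor_type": CensorType.none,
            }))
        else:
            event_variant.append(r)
    return censored_variant, event_variant, log_rank(censored_variant, event_variant)
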