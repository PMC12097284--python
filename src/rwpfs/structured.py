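"""Cohort attrition and structured-data event derivation.

Implements the structured half of the workflow: identifying disease evidence
(ICD prefixes plus NLP-positive disease sentences), anchoring the index date
at the start of concurrent exposure to the first-line regimen (palbociclib +
letrozole by default), detecting advancement to a new line of therapy after
a washout, and applying the sequential cohort attrition filters (female
adult, breast-cancer and metastasis evidence, HR+/HER2-, therapy initiation
inside the study period, ECOG < 3 near the index date).
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .annotate import AnnotatorConfig, annotate_note
from .ehr import CohortBundle, DiagnosisRecord, DrugOrder, EcogRecord, Patient, Sex, ReceptorStatus
from .progression import exclude_history_sections, filter_relevant

DEFAULT_SECOND_LINE_DRUGS: frozenset[str] = frozenset({
    "tamoxifen", "fulvestrant", "elacestrant", "paclitaxel", "carboplatin",
    "abemaciclib", "docetaxel", "cyclophosphamide", "capecitabine",
    "ribociclib", "alpelisib", "everolimus", "doxorubicin", "epirubicin",
    "5-fluorouracil", "olaparib", "talazoparib", "ixabepilone", "raloxifene",
    "toremifene",
})

DEFAULT_DRUG_SYNONYMS: dict[str, str] = {
    "5-fu": "5-fluorouracil",
    "fluorouracil": "5-fluorouracil",
    "taxol": "paclitaxel",
    "taxotere": "docetaxel",
    "ibrance": "palbociclib",
    "femara": "letrozole",
}


class AttritionCriteria(BaseModel):
    """Thresholds and code prefixes for the cohort attrition cascade."""

    breast_icd_prefixes: list[str] = Field(default_factory=lambda: ["174", "C50"])
    metastasis_icd_prefixes: list[str] = Field(
        default_factory=lambda: ["197", "198", "C78", "C79"])
    #: strict "greater than" sentence-count threshold for NLP disease evidence
    min_positive_disease_sentences: int = Field(default=4, ge=0)
    required_hr_status: ReceptorStatus = ReceptorStatus.positive
    required_her2_status: ReceptorStatus = ReceptorStatus.negative
    max_ecog: int = Field(default=2, ge=0, le=5)
    ecog_window_days: int = Field(default=60, ge=0)
    min_age: int = Field(default=18, ge=0)


class TherapyConfig(BaseModel):
    """First-line regimen definition and line-advancement parameters."""

    regimen_drugs: list[str] = Field(
        default_factory=lambda: ["palbociclib", "letrozole"], min_length=1)
    concurrency_window_days: int = Field(default=30, ge=0)
    advancement_washout_days: int = Field(default=60, ge=0)
    second_line_candidates: list[str] = Field(
        default_factory=lambda: sorted(DEFAULT_SECOND_LINE_DRUGS))
    drug_synonyms: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_DRUG_SYNONYMS))

    def canonical(self, drug_name: str) -> str:
        name = drug_name.strip().lower()
        return self.drug_synonyms.get(name, name)


class LineAdvancementEvent(BaseModel):
    patient_id: str
    advancement_date: dt.date
    drug_name: str


class AttritionReport(BaseModel):
    """Ordered (criterion, patients remaining) counts; non-increasing."""

    steps: list[tuple[str, int]]

    @model_validator(mode="after")
    def _monotone(self) -> "AttritionReport":
        counts = [c for _, c in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("attrition counts must be non-increasing")
        return self


class CohortMember(BaseModel):
    """A patient surviving attrition, with the index date and therapy flags."""

    patient_id: str
    index_date: dt.date
    prior_systemic: bool = False
    concomitant_systemic: bool = False


def normalize_code(code: str) -> str:
    """Normalize an ICD code for prefix matching: uppercase, dots removed."""
    return code.upper().replace(".", "").strip()


def _code_matches(code: str, prefixes: Sequence[str]) -> bool:
    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in prefixes)


def first_disease_evidence(
    diagnoses: Iterable[DiagnosisRecord],
    prefixes: Sequence[str],
    mention_dates: Iterable[dt.date],
    threshold: int,
) -> Optional[dt.date]:
    """Earliest date the disease is evidenced by codes or NLP sentences.

    Two routes: the first diagnosis code starting with any prefix, or the day
    the running count of positive disease sentences first *exceeds*
    ``threshold`` (i.e. the (threshold+1)-th sentence).  Returns the earlier
    of the two, or None if neither criterion is met.
    """
    code_dates = [d.diagnosis_date for d in diagnoses if _code_matches(d.code, prefixes)]
    candidates: list[dt.date] = []
    if code_dates:
        candidates.append(min(code_dates))
    dates = sorted(mention_dates)
    if len(dates) > threshold:
        candidates.append(dates[threshold])
    return min(candidates) if candidates else None


def disease_sentence_dates(
    bundle: CohortBundle,
    config: AnnotatorConfig,
) -> dict[str, list[dt.date]]:
    """Dates of positive disease-confirmation sentences per patient.

    Runs the annotator with the disease lexicon and keeps sentences that are
    affirmative, about the patient, current, and outside excluded sections —
    the "positive model confirmation" analogue of the progression filter.
    """
    out: dict[str, list[dt.date]] = defaultdict(list)
    for note in bundle.notes:
        mentions = annotate_note(note, config, patterns=config.disease_patterns)
        mentions = filter_relevant(mentions, config)
        mentions = exclude_history_sections(mentions, config)
        for m in mentions:
            out[m.patient_id].append(m.note_date)
    return dict(out)


def find_therapy_initiation(
    orders: Iterable[DrugOrder],
    metastasis_date: dt.date,
    config: TherapyConfig,
) -> Optional[dt.date]:
    """Date concurrent exposure to the full regimen starts, if it does.

    Only orders strictly after the metastasis diagnosis count.  Each regimen
    drug contributes its first qualifying order date; if every drug has one
    and the spread between the earliest and latest of those dates is within
    the concurrency window, the latest of them (start of overlap) is the
    index date.  Otherwise None.
    """
    if metastasis_date is None:
        raise ValueError("find_therapy_initiation requires a metastasis date")
    regimen = {config.canonical(d) for d in config.regimen_drugs}
    firsts: dict[str, dt.date] = {}
    for o in orders:
        drug = config.canonical(o.drug_name)
        if drug in regimen and o.order_date > metastasis_date:
            if drug not in firsts or o.order_date < firsts[drug]:
                firsts[drug] = o.order_date
    if set(firsts) != regimen:
        return None
    lo, hi = min(firsts.values()), max(firsts.values())
    if (hi - lo).days > config.concurrency_window_days:
        return None
    return hi


def detect_line_advancement(
    orders: Iterable[DrugOrder],
    index_date: dt.date,
    config: TherapyConfig,
) -> Optional[LineAdvancementEvent]:
    """Earliest addition of a *new* second-line candidate after the washout.

    "New" means the drug has no order at any earlier date, so a candidate
    ordered inside the washout disqualifies all its later orders.  Ties on
    the same day break on the alphabetically first drug name.
    """
    if index_date is None:
        raise ValueError("detect_line_advancement requires an index date")
    cutoff = index_date + dt.timedelta(days=config.advancement_washout_days)
    candidates = {config.canonical(d) for d in config.second_line_candidates}
    firsts: dict[str, tuple[dt.date, str]] = {}
    for o in orders:
        drug = config.canonical(o.drug_name)
        if drug not in candidates:
            continue
        if drug not in firsts or o.order_date < firsts[drug][0]:
            firsts[drug] = (o.order_date, o.patient_id)
    hits = [
        (date, drug, pid) for drug, (date, pid) in firsts.items() if date >= cutoff
    ]
    if not hits:
        return None
    date, drug, pid = min(hits, key=lambda h: (h[0], h[1]))
    return LineAdvancementEvent(patient_id=pid, advancement_date=date, drug_name=drug)


def nearest_ecog(
    records: Iterable[EcogRecord],
    index_date: dt.date,
    window_days: int,
) -> Optional[EcogRecord]:
    """The ECOG record closest to the index within +/- window_days.

    Equidistant before/after ties resolve to the earlier record.
    """
    in_window = [
        r for r in records
        if abs((r.record_date - index_date).days) <= window_days
    ]
    if not in_window:
        return None
    return min(
        in_window,
        key=lambda r: (abs((r.record_date - index_date).days), r.record_date, r.score),
    )


def derive_therapy_flags(
    orders: Iterable[DrugOrder],
    index_date: dt.date,
    config: TherapyConfig,
) -> tuple[bool, bool]:
    """(prior_systemic, concomitant_systemic) flags from candidate drug orders.

    Prior: any systemic candidate ordered before the index.  Concomitant:
    any candidate ordered between the index and the end of the advancement
    washout (such an order is, by construction, not a line advancement).
    """
    candidates = {config.canonical(d) for d in config.second_line_candidates}
    washout_end = index_date + dt.timedelta(days=config.advancement_washout_days)
    prior = concomitant = False
    for o in orders:
        if config.canonical(o.drug_name) not in candidates:
            continue
        if o.order_date < index_date:
            prior = True
        elif index_date <= o.order_date < washout_end:
            concomitant = True
    return prior, concomitant


def _age_at(patient: Patient, when: dt.date) -> int:
    # birth_year is the only deidentified age anchor available
    return when.year - patient.birth_year


def apply_attrition(
    bundle: CohortBundle,
    criteria: AttritionCriteria,
    therapy: TherapyConfig,
    *,
    disease_mentions: Optional[Mapping[str, list[dt.date]]] = None,
    annotator_config: Optional[AnnotatorConfig] = None,
) -> tuple[list[CohortMember], AttritionReport]:
    """Apply the sequential cohort filters and report remaining counts.

    ``disease_mentions`` (dates of positive disease sentences per patient)
    may be precomputed; otherwise it is derived with ``annotator_config``
    (falling back to default lexicons).  The report starts with the full
    bundle count followed by one row per filter, in order; counts are
    monotone non-increasing by construction.  Output is independent of input
    record order.
    """
    if disease_mentions is None:
        disease_mentions = disease_sentence_dates(
            bundle, annotator_config or AnnotatorConfig()
        )

    orders_by_pid: dict[str, list[DrugOrder]] = defaultdict(list)
    for o in bundle.drug_orders:
        orders_by_pid[o.patient_id].append(o)
    dx_by_pid: dict[str, list[DiagnosisRecord]] = defaultdict(list)
    for d in bundle.diagnoses:
        dx_by_pid[d.patient_id].append(d)
    ecog_by_pid: dict[str, list[EcogRecord]] = defaultdict(list)
    for r in bundle.ecog_records:
        ecog_by_pid[r.patient_id].append(r)

    index_dates: dict[str, Optional[dt.date]] = {}
    for p in bundle.patients:
        index_dates[p.patient_id] = (
            find_therapy_initiation(orders_by_pid[p.patient_id],
                                    p.metastasis_date, therapy)
            if p.metastasis_date is not None else None
        )

    def age_ref(p: Patient) -> dt.date:
        return index_dates[p.patient_id] or bundle.study_start

    filters = [
        ("female_age_ge_18", lambda p: p.sex is Sex.female
         and _age_at(p, age_ref(p)) >= criteria.min_age),
        ("breast_cancer_evidence", lambda p: first_disease_evidence(
            dx_by_pid[p.patient_id], criteria.breast_icd_prefixes,
            disease_mentions.get(p.patient_id, []),
            criteria.min_positive_disease_sentences) is not None),
        ("metastasis_evidence", lambda p: p.metastasis_date is not None
         or any(_code_matches(d.code, criteria.metastasis_icd_prefixes)
                for d in dx_by_pid[p.patient_id])),
        ("hr_positive", lambda p: p.hr_status is criteria.required_hr_status),
        ("her2_negative", lambda p: p.her2_status is criteria.required_her2_status),
        ("therapy_initiation_in_study", lambda p: index_dates[p.patient_id] is not None
         and bundle.study_start <= index_dates[p.patient_id] <= bundle.study_end),
        ("ecog_lt_3_near_index", lambda p: (
            (rec := nearest_ecog(ecog_by_pid[p.patient_id],
                                 index_dates[p.patient_id],
                                 criteria.ecog_window_days)) is not None
            and rec.score <= criteria.max_ecog)),
    ]

    remaining = sorted(bundle.patients, key=lambda p: p.patient_id)
    steps: list[tuple[str, int]] = [("all_patients", len(remaining))]
    for label, keep in filters:
        remaining = [p for p in remaining if keep(p)]
        steps.append((label, len(remaining)))

    members = []
    for p in remaining:
        idx = index_dates[p.patient_id]
        prior, conc = derive_therapy_flags(orders_by_pid[p.patient_id], idx, therapy)
        members.append(CohortMember(
            patient_id=p.patient_id, index_date=idx,
            prior_systemic=prior, concomitant_systemic=conc,
        ))
    return members, AttritionReport(steps=steps)
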