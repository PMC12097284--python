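"""Seeded synthetic EHR generator with known ground truth.

The generator emulates the statistical and textual structure the progression
workflow assumes, so every pipeline stage is testable without access to any
proprietary EHR source: an HR-positive / HER2-negative metastatic breast
cancer cohort started on palbociclib + letrozole, with progression times
drawn from a distribution whose median is configurable (20 months by
default), routine encounters generating short sectioned clinical notes,
progression documented as template sentences in a clinical note (and, with a
configurable lag, a radiology report), distractor sentences — negated,
hedged, family-subject, past-history — at configurable rates, verbatim
copy-forwarding of progression sentences into later notes, optional
second-line drug orders after progression, death and loss-to-follow-up
censoring, and PHQ-8 score series whose decline differs by progression
status.

Notes are deliberately minimal but structurally faithful (headers, sections,
sentence-level confounders); no attempt is made at clinically realistic
prose.  Every draw descends from per-patient, per-record-type random streams
derived from the master seed, so output is bit-reproducible and adding
patients never perturbs earlier patients' records.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Literal, Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .ehr import (
    ClinicalNote,
    CodeSystem,
    CohortBundle,
    DeathRecord,
    DiagnosisRecord,
    DrugOrder,
    EcogRecord,
    EncounterRecord,
    NoteType,
    Patient,
    Phq8Record,
    ReceptorStatus,
    Sex,
)
from .evaluation import ConfusionCounts, MetricsReport, compute_metrics, confusion_from_dates
from .survival import MONTH_DAYS

LN2 = math.log(2.0)

# progression sentence templates; slot 0 is an anatomy word
PROGRESSION_TEMPLATES = (
    "Imaging shows disease progression in the {anat}.",
    "There is progression of disease involving the {anat}.",
    "Disease has progressed with new {adj} lesions.",
    "Interval progression of disease in the {anat}.",
)
RADIOLOGY_TEMPLATE = "Interval progression of disease with new {adj} metastases."
NEGATED_TEMPLATES = (
    "No evidence of disease progression.",
    "No interval progression of disease.",
)
HEDGED_TEMPLATES = (
    "Possible disease progression in the {anat}.",
    "Findings suspicious for progression of disease.",
)
FAMILY_TEMPLATES = (
    "Mother had progressive breast cancer.",
    "Her sister was treated for progressive disease.",
)
HISTORY_CUE_TEMPLATES = (
    "History of disease progression treated with radiation.",
    "Disease progression previously noted and managed.",
)
PAST_HISTORY_SENTENCE = "Disease progression in the {anat} noted at an outside facility."
DISEASE_TEMPLATES = (
    "Known metastatic breast cancer.",
    "Assessment consistent with metastatic breast cancer.",
    "Ongoing management of invasive ductal carcinoma.",
)
ANATOMY = ("liver", "lungs", "bones", "brain", "pleura")
ADJECTIVE = ("hepatic", "pulmonary", "osseous", "cerebral", "nodal")

SECOND_LINE_POOL = (
    "capecitabine", "everolimus", "abemaciclib", "ribociclib",
    "5-fluorouracil", "olaparib", "cyclophosphamide",
)


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 316 patients, a true median
    progression-free time of 20 months, a 2015-2021 study window with
    enrollment in its first two years, and moderate documentation noise.
    """

    n_patients: int = Field(default=316, ge=1)
    true_median_pfs_months: float = Field(default=20.0, gt=0)
    pfs_distribution: Literal["exponential", "weibull"] = "exponential"
    weibull_shape: float = Field(default=1.5, gt=0)
    #: median overall survival; may be math.inf for "no deaths"
    median_os_months: float = Field(default=84.0, gt=0)
    #: median time to loss of follow-up (drop-out from the EHR network)
    median_dropout_months: float = Field(default=60.0, gt=0)
    enrollment_start: dt.date = dt.date(2015, 1, 1)
    enrollment_end: dt.date = dt.date(2016, 12, 31)
    study_start: dt.date = dt.date(2015, 1, 1)
    study_end: dt.date = dt.date(2021, 12, 31)
    encounter_interval_days: int = Field(default=45, ge=1)
    copy_forward_probability: float = Field(default=0.3, ge=0.0, le=1.0)
    #: chance a post-progression note re-describes the progression in new words
    redocumentation_probability: float = Field(default=0.5, ge=0.0, le=1.0)
    negated_sentence_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    hedged_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    family_history_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    past_history_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    #: share of progressions with an in-network radiology report
    radiology_coverage: float = Field(default=0.55, ge=0.0, le=1.0)
    #: radiology documentation offset (days) added to the true progression date
    radiology_lag_days: int = 0
    #: chance the clinical documentation lags the progression by 30-75 days
    #: (outside imaging, documentation gaps) instead of the usual 0-14 days
    doc_delay_probability: float = Field(default=0.2, ge=0.0, le=1.0)
    second_line_probability: float = Field(default=0.5, ge=0.0, le=1.0)
    phq8_visit_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _windows(self) -> "SimulationConfig":
        if self.enrollment_start > self.enrollment_end:
            raise ValueError("enrollment window is inverted")
        if self.study_start >= self.study_end:
            raise ValueError("study window is inverted")
        return self


class GroundTruthRecord(BaseModel):
    patient_id: str
    index_date: dt.date
    true_progression_date: Optional[dt.date] = None
    true_death_date: Optional[dt.date] = None
    true_line_advancement_date: Optional[dt.date] = None


class GroundTruth(BaseModel):
    records: list[GroundTruthRecord]

    def by_patient(self) -> dict[str, GroundTruthRecord]:
        return {r.patient_id: r for r in self.records}


def _rng(seed: int, patient_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, patient_idx, stream)))


def _draw_pfs_days(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    if cfg.pfs_distribution == "exponential":
        months = rng.exponential(cfg.true_median_pfs_months / LN2)
    else:
        scale = cfg.true_median_pfs_months / LN2 ** (1.0 / cfg.weibull_shape)
        months = scale * rng.weibull(cfg.weibull_shape)
    return max(1, int(round(months * MONTH_DAYS)))


def _draw_exp_days(median_months: float, rng: np.random.Generator) -> Optional[int]:
    if math.isinf(median_months):
        return None
    return max(1, int(round(rng.exponential(median_months / LN2) * MONTH_DAYS)))


def _note(pid: str, seq: int, day: dt.date, body_sentences: list[str],
          past_history: Optional[str] = None,
          note_type: NoteType = NoteType.clinical_document) -> ClinicalNote:
    if note_type is NoteType.radiology_report:
        text = "Findings:\n{}\nImpression:\n{}\n".format(*body_sentences)
    else:
        text = "Assessment:\n" + " ".join(body_sentences) + "\n"
        if past_history:
            text += "Past History:\n" + past_history + "\n"
    return ClinicalNote(
        note_id=f"{pid}-n{seq:03d}", patient_id=pid, note_date=day,
        note_type=note_type, text=text,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, GroundTruth]:
    """Generate a synthetic bundle plus its ground truth.

    Deterministic under ``config.seed``.  Ground-truth progression dates are
    those observable within each patient's follow-up (before death, drop-out
    and the administrative study end); every such progression is documented
    by at least one affirmative sentence in some note.
    """
    cfg = config
    patients, notes, orders, encounters = [], [], [], []
    deaths, diagnoses, ecog, phq8 = [], [], [], []
    truth_records = []
    enroll_days = (cfg.enrollment_end - cfg.enrollment_start).days

    for i in range(cfg.n_patients):
        pid = f"P{i:04d}"
        g = _rng(cfg.seed, i, 0)       # demographics / anatomy
        sv = _rng(cfg.seed, i, 1)      # survival times
        nt = _rng(cfg.seed, i, 2)      # note content
        pq = _rng(cfg.seed, i, 3)      # PHQ-8
        dr = _rng(cfg.seed, i, 4)      # drug orders

        birth_year = int(g.integers(1935, 1980))
        mets = cfg.enrollment_start + dt.timedelta(int(g.integers(0, enroll_days + 1)))
        primary_dx = mets - dt.timedelta(int(g.integers(60, 400)))
        anat_i = int(g.integers(0, len(ANATOMY)))

        patients.append(Patient(
            patient_id=pid, birth_year=birth_year, sex=Sex.female,
            metastasis_date=mets, hr_status=ReceptorStatus.positive,
            her2_status=ReceptorStatus.negative,
        ))
        if i % 2 == 0:
            diagnoses.append(DiagnosisRecord(
                patient_id=pid, code="C50.9", code_system=CodeSystem.ICD10,
                diagnosis_date=primary_dx))
            diagnoses.append(DiagnosisRecord(
                patient_id=pid, code="C79.9", code_system=CodeSystem.ICD10,
                diagnosis_date=mets))
        else:
            diagnoses.append(DiagnosisRecord(
                patient_id=pid, code="174.9", code_system=CodeSystem.ICD9,
                diagnosis_date=primary_dx))
            diagnoses.append(DiagnosisRecord(
                patient_id=pid, code="198.5", code_system=CodeSystem.ICD9,
                diagnosis_date=mets))

        letro_day = mets + dt.timedelta(int(dr.integers(5, 21)))
        palbo_day = letro_day + dt.timedelta(int(dr.integers(0, 11)))
        index = max(letro_day, palbo_day)
        orders.append(DrugOrder(patient_id=pid, drug_name="letrozole",
                                order_date=letro_day))
        orders.append(DrugOrder(patient_id=pid, drug_name="palbociclib",
                                order_date=palbo_day))

        ecog.append(EcogRecord(
            patient_id=pid, score=int(g.integers(0, 3)),
            record_date=index - dt.timedelta(int(g.integers(0, 31)))))

        T = _draw_pfs_days(cfg, sv)                       # true PFS, days from index
        os_days = _draw_exp_days(cfg.median_os_months, sv)
        drop_days = _draw_exp_days(cfg.median_dropout_months, sv) or 10**6
        admin_days = (cfg.study_end - index).days
        horizon = min(x for x in (os_days, drop_days, admin_days) if x is not None)
        # notes/encounters continue past the analytic study end for active patients
        ehr_horizon = min(x for x in (os_days, drop_days, admin_days + 180)
                          if x is not None)

        progressed = T <= horizon
        died = os_days is not None and os_days == horizon and os_days <= admin_days \
            and os_days <= drop_days
        true_prog = index + dt.timedelta(T) if progressed else None
        death_date = index + dt.timedelta(os_days) if died else None

        doc_day = None
        rad_day = None
        prog_sentence = None
        template_i = 0
        if progressed:
            if nt.random() < cfg.doc_delay_probability:
                delay = int(nt.integers(30, 76))
            else:
                delay = int(nt.integers(0, 15))
            doc_day = min(T + delay, horizon)
            if nt.random() < cfg.radiology_coverage:
                rad = T + cfg.radiology_lag_days + int(nt.integers(0, 8))
                if 0 <= rad <= ehr_horizon:
                    rad_day = rad
            template_i = int(nt.integers(0, len(PROGRESSION_TEMPLATES)))
            prog_sentence = PROGRESSION_TEMPLATES[template_i].format(
                anat=ANATOMY[anat_i], adj=ADJECTIVE[anat_i])

        # regimen refills until the end of exposure, for realistic order counts
        refill_end = min(ehr_horizon, (T if progressed else ehr_horizon) + 30)
        for k in range(1, min(refill_end // 28, 12) + 1):
            orders.append(DrugOrder(patient_id=pid, drug_name="palbociclib",
                                    order_date=index + dt.timedelta(28 * k)))
            if k % 2 == 0:
                orders.append(DrugOrder(patient_id=pid, drug_name="letrozole",
                                        order_date=index + dt.timedelta(28 * k)))

        advancement_date = None
        if progressed and dr.random() < cfg.second_line_probability:
            sl_day = T + int(dr.integers(10, 41))
            if sl_day >= 60 and sl_day <= ehr_horizon:
                drug = SECOND_LINE_POOL[int(dr.integers(0, len(SECOND_LINE_POOL)))]
                advancement_date = index + dt.timedelta(sl_day)
                orders.append(DrugOrder(patient_id=pid, drug_name=drug,
                                        order_date=advancement_date))

        # encounters and routine notes on a fixed cadence from the index
        encounter_days = list(range(0, ehr_horizon + 1, cfg.encounter_interval_days))
        if died and os_days not in encounter_days:
            encounter_days.append(os_days)  # terminal admission on the death date
        encounter_days.sort()
        seq = 0
        redoc_count = 0
        for e_day in encounter_days:
            day = index + dt.timedelta(e_day)
            encounters.append(EncounterRecord(patient_id=pid, encounter_date=day))
            sentences = ["Patient seen in routine oncology follow-up.",
                         DISEASE_TEMPLATES[seq % len(DISEASE_TEMPLATES)]]
            past_hist = None
            pre_progression = doc_day is None or e_day < doc_day
            if pre_progression:
                if nt.random() < cfg.negated_sentence_rate:
                    sentences.append(
                        NEGATED_TEMPLATES[int(nt.integers(0, len(NEGATED_TEMPLATES)))])
                if nt.random() < cfg.hedged_rate:
                    sentences.append(
                        HEDGED_TEMPLATES[int(nt.integers(0, len(HEDGED_TEMPLATES)))]
                        .format(anat=ANATOMY[anat_i]))
            if nt.random() < cfg.family_history_rate:
                sentences.append(
                    FAMILY_TEMPLATES[int(nt.integers(0, len(FAMILY_TEMPLATES)))])
            if nt.random() < cfg.past_history_rate:
                sentences.append(
                    HISTORY_CUE_TEMPLATES[int(nt.integers(0, len(HISTORY_CUE_TEMPLATES)))])
            if nt.random() < cfg.past_history_rate:
                past_hist = PAST_HISTORY_SENTENCE.format(anat=ANATOMY[anat_i])
            if doc_day is not None and e_day > doc_day:
                if nt.random() < cfg.copy_forward_probability:
                    sentences.append(prog_sentence)  # verbatim copy-forward
                if nt.random() < cfg.redocumentation_probability:
                    redoc_count += 1
                    alt = (template_i + redoc_count) % len(PROGRESSION_TEMPLATES)
                    sentences.append(PROGRESSION_TEMPLATES[alt].format(
                        anat=ANATOMY[anat_i], adj=ADJECTIVE[anat_i]))
            notes.append(_note(pid, seq, day, sentences, past_hist))
            seq += 1

        if progressed:
            notes.append(_note(pid, seq, index + dt.timedelta(doc_day),
                               [prog_sentence, DISEASE_TEMPLATES[0]]))
            seq += 1
            if rad_day is not None:
                notes.append(_note(
                    pid, seq, index + dt.timedelta(rad_day),
                    ["Comparison with prior imaging was performed.",
                     RADIOLOGY_TEMPLATE.format(adj=ADJECTIVE[anat_i])],
                    note_type=NoteType.radiology_report))
                seq += 1

        if died:
            deaths.append(DeathRecord(patient_id=pid, death_date=death_date))

        if pq.random() < cfg.phq8_visit_rate and len(encounter_days) >= 2:
            k = int(pq.integers(2, 7))
            visit_days = encounter_days[::2][:k] if len(encounter_days[::2]) >= 2 \
                else encounter_days[:k]
            baseline = int(pq.integers(8, 21))
            drift = (float(pq.uniform(0.2, 1.5)) if progressed
                     else float(pq.uniform(1.5, 3.5)))
            for j, v_day in enumerate(visit_days):
                score = baseline - drift * j + float(pq.normal(0.0, 1.0))
                phq8.append(Phq8Record(
                    patient_id=pid,
                    score=int(np.clip(round(score), 0, 24)),
                    record_date=index + dt.timedelta(v_day)))

        truth_records.append(GroundTruthRecord(
            patient_id=pid, index_date=index,
            true_progression_date=true_prog,
            true_death_date=death_date,
            true_line_advancement_date=advancement_date,
        ))

    bundle = CohortBundle(
        patients=patients, notes=notes, drug_orders=orders,
        encounters=encounters, deaths=deaths, diagnoses=diagnoses,
        ecog_records=ecog, phq8_records=phq8,
        study_start=cfg.study_start, study_end=cfg.study_end,
    )
    return bundle, GroundTruth(records=truth_records)


def evaluate_against_truth(
    auto_dates: Mapping[str, Optional[dt.date]],
    truth: GroundTruth,
    window_days: int = 30,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Patient-level validation of pipeline captures against simulated truth.

    ``auto_dates`` maps every simulated patient to the first automated
    capture date (or None); the simulator's true progression dates play the
    role the manually abstracted dates play on real data.
    """
    manual = {r.patient_id: r.true_progression_date for r in truth.records}
    counts = confusion_from_dates(auto_dates, manual, window_days)
    return counts, compute_metrics(counts)
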