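import datetime as dt

import pytest

from rwpfs import (
    AnnotatedMention,
    AnnotatorConfig,
    Certainty,
    ClinicalNote,
    CohortBundle,
    MentionLabels,
    NoteType,
    Patient,
    ReceptorStatus,
    Sex,
    SimulationConfig,
    Subject,
    Temporality,
    simulate_cohort,
)

D = dt.date


@pytest.fixture(scope="session")
def config() -> AnnotatorConfig:
    return AnnotatorConfig()


@pytest.fixture(scope="session")
def sim316():
    """Default-condition synthetic cohort (one seed, full study size)."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sim_small():
    """Small synthetic cohort for cheap structural tests."""
    return simulate_cohort(SimulationConfig(n_patients=40, seed=11))


def make_patient(pid: str = "P1", **kw) -> Patient:
    defaults = dict(
        patient_id=pid, birth_year=1960, sex=Sex.female,
        metastasis_date=D(2015, 6, 1), hr_status=ReceptorStatus.positive,
        her2_status=ReceptorStatus.negative,
    )
    defaults.update(kw)
    return Patient(**defaults)


def make_note(pid: str, nid: str, day: dt.date, text: str,
              note_type: NoteType = NoteType.clinical_document) -> ClinicalNote:
    return ClinicalNote(note_id=nid, patient_id=pid, note_date=day,
                        note_type=note_type, text=text)


def make_mention(
    pid: str = "P1",
    nid: str = "n1",
    day: dt.date = D(2016, 1, 1),
    sentence: str = "Imaging shows disease progression in the liver.",
    certainty: Certainty = Certainty.YES,
    subject: Subject = Subject.PATIENT,
    temporality: Temporality = Temporality.CURRENT,
    confs: tuple[float, float, float] = (1.0, 1.0, 1.0),
    header: str | None = "Assessment",
    note_type: NoteType = NoteType.clinical_document,
) -> AnnotatedMention:
    from rwpfs import normalize_sentence

    return AnnotatedMention(
        patient_id=pid, note_id=nid, note_date=day, note_type=note_type,
        section_header=header, sentence=sentence,
        normalized_sentence=normalize_sentence(sentence),
        labels=MentionLabels(
            certainty=certainty, subject=subject, temporality=temporality,
            certainty_conf=confs[0], subject_conf=confs[1],
            temporality_conf=confs[2],
        ),
        matched_pattern="disease progression",
    )


def tiny_bundle(patients, notes=(), **kw) -> CohortBundle:
    defaults = dict(study_start=D(2015, 1, 1), study_end=D(2021, 12, 31))
    defaults.update(kw)
    return CohortBundle(patients=list(patients), notes=list(notes), **defaults)
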