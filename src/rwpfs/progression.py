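"""Selection conditions turning annotated mentions into progression captures.

Three conditions make a mention a credible, current, patient-level
progression event: (1) relevance — labels YES/PATIENT/CURRENT, each with
confidence at or above the configured threshold; (2) section exclusion —
sentences filed under past-history sections are unlikely to describe events
at documentation time; (3) copy-forward deduplication — clinicians paste
prior note text into new notes, so only the first chronological instance of
each normalized sentence per patient is kept.  The composition maps
surviving mentions to :class:`ProgressionCapture` records, one per retained
sentence, dated by the source note.

Each condition can be skipped independently (the ablation machinery relies
on this); removing a condition can only enlarge the capture set.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

from pydantic import BaseModel

from .annotate import (
    AnnotatedMention,
    AnnotatorConfig,
    Certainty,
    Subject,
    Temporality,
    annotate_note,
)
from .ehr import CohortBundle, NoteType


class ProgressionCapture(BaseModel):
    """A deduplicated patient-level progression event with provenance."""

    patient_id: str
    capture_date: dt.date
    note_id: str
    note_type: NoteType
    sentence: str
    normalized_sentence: str


def filter_relevant(
    mentions: Iterable[AnnotatedMention],
    config: AnnotatorConfig,
    *,
    require_certainty: bool = True,
    require_subject: bool = True,
    require_temporality: bool = True,
) -> list[AnnotatedMention]:
    """Keep mentions labeled YES / PATIENT / CURRENT at high confidence.

    Each ``require_*`` flag controls one label's condition (value and
    confidence together); disabling a flag reproduces the corresponding
    model-ablation behaviour.  Idempotent.
    """
    thr = config.min_confidence
    kept = []
    for m in mentions:
        lab = m.labels
        if require_certainty and not (
            lab.certainty is Certainty.YES and lab.certainty_conf >= thr
        ):
            continue
        if require_subject and not (
            lab.subject is Subject.PATIENT and lab.subject_conf >= thr
        ):
            continue
        if require_temporality and not (
            lab.temporality is Temporality.CURRENT and lab.temporality_conf >= thr
        ):
            continue
        kept.append(m)
    return kept


def _normalize_header(header: str) -> str:
    return " ".join(header.lower().split()).rstrip(":").strip()


def exclude_history_sections(
    mentions: Iterable[AnnotatedMention],
    config: AnnotatorConfig,
) -> list[AnnotatedMention]:
    """Drop mentions filed under excluded (past-history) section headers.

    Matching is case-insensitive on the whitespace-normalized header;
    mentions with no section header are retained, since the exclusion is
    defined only for identified sections.
    """
    excluded = {_normalize_header(h) for h in config.excluded_section_headers}
    return [
        m for m in mentions
        if m.section_header is None
        or _normalize_header(m.section_header) not in excluded
    ]


def deduplicate_copy_forward(
    mentions: Iterable[AnnotatedMention],
) -> list[AnnotatedMention]:
    """Per patient, keep only the earliest instance of each normalized sentence.

    Date ties break on the lexicographically smallest note_id, making the
    result independent of input order.  Idempotent; scope is per patient, so
    identical sentences in different patients' records are both kept.
    """
    best: dict[tuple[str, str], AnnotatedMention] = {}
    for m in mentions:
        key = (m.patient_id, m.normalized_sentence)
        cur = best.get(key)
        if cur is None or (m.note_date, m.note_id) < (cur.note_date, cur.note_id):
            best[key] = m
    return sorted(
        best.values(),
        key=lambda m: (m.patient_id, m.note_date, m.note_id, m.normalized_sentence),
    )


def extract_progression_captures(
    bundle: CohortBundle,
    config: AnnotatorConfig,
    *,
    skip_certainty: bool = False,
    skip_subject: bool = False,
    skip_temporality: bool = False,
    skip_postprocessing: bool = False,
) -> list[ProgressionCapture]:
    """Full text pipeline: annotate, filter, exclude sections, deduplicate.

    The ``skip_*`` keywords disable individual selection conditions for
    ablation studies; ``skip_postprocessing`` disables both the section
    exclusion and the copy-forward deduplication.  Output is sorted by
    (patient_id, capture_date, note_id); captures are always a subset of the
    annotator's mentions.
    """
    mentions: list[AnnotatedMention] = []
    for note in bundle.notes:
        mentions.extend(annotate_note(note, config))
    mentions = filter_relevant(
        mentions,
        config,
        require_certainty=not skip_certainty,
        require_subject=not skip_subject,
        require_temporality=not skip_temporality,
    )
    if not skip_postprocessing:
        mentions = exclude_history_sections(mentions, config)
        mentions = deduplicate_copy_forward(mentions)
    captures = [
        ProgressionCapture(
            patient_id=m.patient_id,
            capture_date=m.note_date,
            note_id=m.note_id,
            note_type=m.note_type,
            sentence=m.sentence,
            normalized_sentence=m.normalized_sentence,
        )
        for m in mentions
    ]
    captures.sort(key=lambda c: (c.patient_id, c.capture_date, c.note_id))
    return captures
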