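"""Rule-based sentence-level annotation of progression mentions.

The production systems this package emulates run transformer ensembles that
label candidate sentences with *certainty* (is the finding asserted, negated
or hedged), *subject* (patient vs family member) and *temporality* (current
finding vs past history).  Here the same output contract is implemented by a
deterministic cue-lexicon annotator in the NegEx/ConText tradition: a
configurable set of case-insensitive regular expressions proposes candidate
sentences, and cue phrases decide the three labels.  Any model-backed
substitute that emits :class:`AnnotatedMention` values with calibrated
confidences can be dropped in; the downstream pipeline is written against the
contract, not this implementation.

Notes are first segmented into sections (pre-populated spans are trusted;
otherwise headers are detected from colon-terminated or all-caps lines),
sections are split into sentences with a small abbreviation-protected
splitter, and each sentence that matches a progression pattern yields exactly
one mention.
"""

from __future__ import annotations

import datetime as dt
import re
import string
from enum import Enum
from functools import lru_cache
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .ehr import ClinicalNote, NoteType, Section

PREAMBLE_HEADER = "preamble"

DEFAULT_PROGRESSION_PATTERNS: tuple[str, ...] = (
    r"disease\s+progression",
    r"progression\s+of\s+(?:the\s+)?disease",
    r"progressive\s+(?:disease|breast\s+cancer|carcinoma)",
    r"disease\s+has\s+progressed",
    r"interval\s+progression",
    r"progression\s+(?:in|of|involving)\s+the\s+\w+",
    r"new\s+(?:hepatic|pulmonary|osseous|cerebral|nodal)\s+metastas[ei]s",
    r"new\s+\w+\s+lesions",
    r"worsening\s+(?:of\s+)?(?:the\s+)?(?:metastatic\s+)?disease",
)

DEFAULT_DISEASE_PATTERNS: tuple[str, ...] = (
    r"breast\s+cancer",
    r"breast\s+carcinoma",
    r"carcinoma\s+of\s+the\s+breast",
    r"invasive\s+(?:ductal|lobular)?\s*carcinoma",
    r"breast\s+malignancy",
)

DEFAULT_NEGATION_CUES: tuple[str, ...] = (
    "no evidence of", "without", "negative for", "no new", "denies", "no", "not",
)
DEFAULT_HEDGE_CUES: tuple[str, ...] = (
    "possible", "possibly", "suspicious for", "cannot exclude",
    "cannot be excluded", "may represent", "questionable",
)
DEFAULT_FAMILY_CUES: tuple[str, ...] = (
    "mother", "father", "sister", "brother", "aunt", "grandmother",
    "family history",
)
DEFAULT_HISTORY_CUES: tuple[str, ...] = (
    "history of", "previously", "status post", "remote",
)
DEFAULT_EXCLUDED_SECTIONS: tuple[str, ...] = (
    "past history", "past medical history", "past surgical history",
)
DEFAULT_SECTION_LEXICON: tuple[str, ...] = (
    "hpi", "history of present illness", "assessment", "assessment and plan",
    "impression", "findings", "plan", "past history", "past medical history",
    "past surgical history", "family history", "review of systems",
)
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "dr", "mr", "mrs", "ms", "st", "vs", "fig", "approx", "e.g", "i.e",
)


class AnnotatorConfig(BaseModel):
    """Lexicons and thresholds driving the rule-based annotator.

    ``min_confidence`` is the relevance threshold applied downstream to each
    of the three label confidences; the reference annotator emits 1.0 for
    every decided label, so the threshold only bites for model-backed or
    simulated confidences.
    """

    progression_patterns: list[str] = Field(
        default_factory=lambda: list(DEFAULT_PROGRESSION_PATTERNS))
    disease_patterns: list[str] = Field(
        default_factory=lambda: list(DEFAULT_DISEASE_PATTERNS))
    negation_cues: list[str] = Field(
        default_factory=lambda: list(DEFAULT_NEGATION_CUES))
    hedge_cues: list[str] = Field(default_factory=lambda: list(DEFAULT_HEDGE_CUES))
    family_cues: list[str] = Field(default_factory=lambda: list(DEFAULT_FAMILY_CUES))
    history_cues: list[str] = Field(default_factory=lambda: list(DEFAULT_HISTORY_CUES))
    excluded_section_headers: list[str] = Field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_SECTIONS))
    section_header_lexicon: list[str] = Field(
        default_factory=lambda: list(DEFAULT_SECTION_LEXICON))
    abbreviations: list[str] = Field(
        default_factory=lambda: list(DEFAULT_ABBREVIATIONS))
    #: Negation cues scope rightward this many tokens; None = end of sentence.
    negation_scope_tokens: Optional[int] = None
    min_confidence: float = Field(default=0.9, ge=0.0, le=1.0)

    @field_validator("progression_patterns", "disease_patterns")
    @classmethod
    def _compiles(cls, patterns: list[str]) -> list[str]:
        for p in patterns:
            re.compile(p, re.IGNORECASE)
        return patterns

    @classmethod
    def from_file(cls, path) -> "AnnotatorConfig":
        """Load a config from a YAML or JSON file."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


class Certainty(str, Enum):
    YES = "YES"
    NO = "NO"
    MAYBE = "MAYBE"


class Subject(str, Enum):
    PATIENT = "PATIENT"
    FAMILY = "FAMILY"
    OTHER = "OTHER"


class Temporality(str, Enum):
    CURRENT = "CURRENT"
    HISTORY = "HISTORY"
    FUTURE = "FUTURE"


class MentionLabels(BaseModel):
    certainty: Certainty
    subject: Subject
    temporality: Temporality
    certainty_conf: float = Field(ge=0.0, le=1.0)
    subject_conf: float = Field(ge=0.0, le=1.0)
    temporality_conf: float = Field(ge=0.0, le=1.0)


class AnnotatedMention(BaseModel):
    patient_id: str
    note_id: str
    note_date: dt.date
    note_type: NoteType
    section_header: Optional[str] = None
    sentence: str = Field(min_length=1)
    normalized_sentence: str
    labels: MentionLabels
    matched_pattern: str


# --------------------------------------------------------------------------
# compiled-pattern caches (configs are plain data; keyed by pattern tuples)

@lru_cache(maxsize=128)
def _alternation(patterns: tuple[str, ...]) -> Optional[re.Pattern]:
    if not patterns:
        return None
    return re.compile("|".join(f"(?:{p})" for p in patterns), re.IGNORECASE)


@lru_cache(maxsize=256)
def _cue_regex(cues: tuple[str, ...]) -> Optional[re.Pattern]:
    if not cues:
        return None
    parts = sorted((re.escape(c.strip()) for c in cues if c.strip()),
                   key=len, reverse=True)
    return re.compile(r"(?<!\w)(?:" + "|".join(parts) + r")(?!\w)", re.IGNORECASE)


def normalize_sentence(sentence: str) -> str:
    """Lowercase, collapse whitespace and strip edge punctuation.

    This is the equality used to detect copy-forwarded duplicates, so
    formatting-only differences between pasted copies collapse.
    """
    collapsed = " ".join(sentence.lower().split())
    return collapsed.strip(string.punctuation + string.whitespace)


# --------------------------------------------------------------------------
# section segmentation

_HEADER_COLON = re.compile(r"[A-Za-z][A-Za-z0-9 /\-]{0,58}:")


def _is_header_line(stripped: str, lexicon: frozenset[str]) -> bool:
    if not stripped or len(stripped) > 60:
        return False
    if stripped.endswith(":") and _HEADER_COLON.fullmatch(stripped):
        return True
    if stripped.rstrip(":").strip().lower() in lexicon:
        return True
    if (stripped.isupper() and len(stripped) >= 3
            and not any(ch in stripped for ch in ".?!")):
        return True
    return False


def segment_sections(note: ClinicalNote, config: AnnotatorConfig) -> list[Section]:
    """Partition a note's text into labeled section spans.

    Pre-populated ``note.sections`` are returned as-is.  Otherwise headers
    are detected line by line (colon-terminated lines, all-caps lines, or
    lexicon matches); text before the first header forms an implicit
    ``preamble`` section.  Every character of the text belongs to exactly one
    returned span.
    """
    if note.sections:
        return list(note.sections)
    text = note.text
    if not text.strip():
        return []
    lexicon = frozenset(h.lower() for h in config.section_header_lexicon)
    headers: list[tuple[int, str]] = []  # (line start offset, header label)
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.strip()
        if _is_header_line(stripped, lexicon):
            headers.append((offset, stripped.rstrip(":").strip()))
        offset += len(line)
    if not headers:
        return [Section(header=PREAMBLE_HEADER, start=0, end=len(text))]
    sections: list[Section] = []
    first_start = headers[0][0]
    if text[:first_start].strip():
        sections.append(Section(header=PREAMBLE_HEADER, start=0, end=first_start))
    for i, (start, header) in enumerate(headers):
        end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        sections.append(Section(header=header, start=start, end=end))
    return sections


def _section_body(text: str, sec: Section) -> tuple[int, str]:
    """Return (offset, body) for a section, skipping its own header line."""
    body = text[sec.start:sec.end]
    m = re.match(r"\s*" + re.escape(sec.header) + r"\s*:?\s*", body, re.IGNORECASE)
    skip = m.end() if m and sec.header != PREAMBLE_HEADER else 0
    return sec.start + skip, body[skip:]


# --------------------------------------------------------------------------
# sentence splitting

_BOUNDARY = re.compile(r"[.?!]+(?=\s)")
_LAST_WORD = re.compile(r"([A-Za-z][\w.']*?)[.?!]+$")


def split_sentences(
    text: str,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, int]]:
    """Split text into sentence spans on terminal punctuation.

    Returns half-open character spans trimmed of surrounding whitespace;
    abbreviation-final periods (``Dr.``, ``vs.`` ...) do not split.  Spans
    jointly cover all non-whitespace text.
    """
    abbrevs = {a.lower().rstrip(".") for a in abbreviations}
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(text):
        prev = text[max(0, m.start() - 20):m.end()]
        w = _LAST_WORD.search(prev)
        if w and w.group(1).lower().rstrip(".") in abbrevs:
            continue
        cuts.append(m.end())
    spans: list[tuple[int, int]] = []
    start = 0
    for cut in cuts + [len(text)]:
        chunk = text[start:cut]
        lead = len(chunk) - len(chunk.lstrip())
        s, e = start + lead, start + len(chunk.rstrip())
        if e > s:
            spans.append((s, e))
        start = cut
    return spans


# --------------------------------------------------------------------------
# label assignment

def _within_scope(cue_end: int, match_start: int, sentence: str,
                  window_tokens: Optional[int]) -> bool:
    if window_tokens is None:
        return True
    between = sentence[cue_end:match_start]
    return len(between.split()) <= window_tokens


def assign_labels(
    sentence: str,
    config: AnnotatorConfig,
    match_start: Optional[int] = None,
) -> MentionLabels:
    """Assign certainty/subject/temporality labels to one sentence.

    A negation cue to the left of the pattern match (within the configured
    token window) yields certainty NO; a hedge cue anywhere yields MAYBE;
    otherwise YES.  Family cues set subject FAMILY, history cues set
    temporality HISTORY.  The reference implementation is fully confident
    (1.0) in every decision; graded confidences are the province of
    model-backed annotators and of the simulator.
    """
    if not sentence or not sentence.strip():
        raise ValueError("assign_labels requires a nonempty sentence")
    if match_start is None:
        pat = _alternation(tuple(config.progression_patterns))
        m = pat.search(sentence) if pat else None
        match_start = m.start() if m else len(sentence)

    certainty = Certainty.YES
    neg = _cue_regex(tuple(config.negation_cues))
    if neg and any(
        c.start() < match_start
        and _within_scope(c.end(), match_start, sentence,
                          config.negation_scope_tokens)
        for c in neg.finditer(sentence)
    ):
        certainty = Certainty.NO
    else:
        hedge = _cue_regex(tuple(config.hedge_cues))
        if hedge and hedge.search(sentence):
            certainty = Certainty.MAYBE

    family = _cue_regex(tuple(config.family_cues))
    subject = Subject.FAMILY if family and family.search(sentence) else Subject.PATIENT

    history = _cue_regex(tuple(config.history_cues))
    temporality = (Temporality.HISTORY if history and history.search(sentence)
                   else Temporality.CURRENT)

    return MentionLabels(
        certainty=certainty, subject=subject, temporality=temporality,
        certainty_conf=1.0, subject_conf=1.0, temporality_conf=1.0,
    )


def annotate_note(
    note: ClinicalNote,
    config: AnnotatorConfig,
    patterns: Optional[Sequence[str]] = None,
) -> list[AnnotatedMention]:
    """Emit one mention per sentence matching any capture pattern.

    ``patterns`` defaults to the progression lexicon; passing
    ``config.disease_patterns`` reuses the same machinery for positive
    disease-confirmation sentences.  Multiple pattern hits within a sentence
    collapse to a single mention (first match wins), so output size is
    bounded by sentence count.  Deterministic: identical (note, config) give
    identical output.
    """
    pats = tuple(patterns if patterns is not None else config.progression_patterns)
    alternation = _alternation(pats)
    if alternation is None or not note.text:
        return []
    mentions: list[AnnotatedMention] = []
    abbrevs = tuple(config.abbreviations)
    for sec in segment_sections(note, config):
        offset, body = _section_body(note.text, sec)
        if not alternation.search(body):
            continue
        for s, e in split_sentences(body, abbrevs):
            sentence = body[s:e]
            m = alternation.search(sentence)
            if m is None:
                continue
            matched = next(
                (p for p in pats if re.search(p, sentence, re.IGNORECASE)), pats[0]
            )
            mentions.append(AnnotatedMention(
                patient_id=note.patient_id,
                note_id=note.note_id,
                note_date=note.note_date,
                note_type=note.note_type,
                section_header=sec.header,
                sentence=sentence,
                normalized_sentence=normalize_sentence(sentence),
                labels=assign_labels(sentence, config, match_start=m.start()),
                matched_pattern=matched,
            ))
    return mentions
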