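"""End-to-end composition: bundle in, survival estimates out.

Chains the stages in their natural order — annotate and capture progression
sentences, apply cohort attrition, assemble survival records, fit the
Kaplan-Meier estimator — and returns everything intermediate, which is what
the command-line interface, the acceptance script and most analyses need.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel

from .annotate import AnnotatorConfig
from .ehr import CohortBundle
from .progression import ProgressionCapture, extract_progression_captures
from .structured import (
    AttritionCriteria,
    AttritionReport,
    CohortMember,
    TherapyConfig,
    apply_attrition,
)
from .survival import (
    KMCurve,
    MedianEstimate,
    SourceFilter,
    SurvivalRecord,
    build_rwos_records,
    build_rwpfs_records,
    km_fit,
    median_survival,
)


class PipelineResult(BaseModel):
    captures: list[ProgressionCapture]
    members: list[CohortMember]
    attrition: AttritionReport
    records: list[SurvivalRecord]
    curve: KMCurve
    median: MedianEstimate


def run_pipeline(
    bundle: CohortBundle,
    config: Optional[AnnotatorConfig] = None,
    criteria: Optional[AttritionCriteria] = None,
    therapy: Optional[TherapyConfig] = None,
    *,
    outcome: str = "rwpfs",
    source_filter: SourceFilter | str = SourceFilter.pooled,
) -> PipelineResult:
    """Run the full workflow on a bundle with default or supplied configs.

    ``outcome`` selects rwPFS (progression or line advancement as the event)
    or rwOS (death as the event).  The source filter restricts which note
    type may contribute progression captures.
    """
    config = config or AnnotatorConfig()
    criteria = criteria or AttritionCriteria()
    therapy = therapy or TherapyConfig()
    captures = extract_progression_captures(bundle, config)
    members, attrition = apply_attrition(
        bundle, criteria, therapy, annotator_config=config)
    if outcome == "rwpfs":
        records = build_rwpfs_records(bundle, members, captures, therapy,
                                      source_filter)
    elif outcome == "rwos":
        records = build_rwos_records(bundle, members)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    curve = km_fit(records) if records else KMCurve(
        event_times=[], survival=[], variance=[], at_risk=[], n_total=0)
    return PipelineResult(
        captures=captures, members=members, attrition=attrition,
        records=records, curve=curve, median=median_survival(curve),
    )
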