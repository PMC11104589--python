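"""Per-patient decision reports.

Renders the stage-by-stage view a clinician would see: the four per-group
DSI values, suggested diagnosis, margin and PCC at every executed stage of
the decision flow (baseline, hypothetical positive / negative PET, actual
PET), followed by the advice the flow produced.  Reports exist as
schema-stable JSON (pydantic models; the schema ships with the package) and
as plain text.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, Field

from .scenarios import PatientDecision, PatientEvaluator, StageResult

__all__ = [
    "StageReport",
    "PatientReport",
    "render_patient_report",
    "render_text",
    "report_json_schema",
]

_STAGE_TITLES = {
    "baseline": "APOE + neuropsychology + MRI",
    "hyp_pos": "with hypothetical positive amyloid-PET",
    "hyp_neg": "with hypothetical negative amyloid-PET",
    "actual": "with actual amyloid-PET",
}

ADVICE_DIAGNOSE_NOW = "diagnose now"
ADVICE_NO_PET = "PET not useful — follow-up advised"
ADVICE_ORDER_PET = "order PET"
ADVICE_STILL_UNCERTAIN = "diagnosis remains uncertain after PET — follow-up advised"


class StageReport(BaseModel):
    """DSI profile and PCC of one executed evaluation stage."""

    stage: Literal["baseline", "hyp_pos", "hyp_neg", "actual"]
    title: str
    dsi: dict[str, float]
    top_label: str
    margin: float
    pcc: float


class PatientReport(BaseModel):
    """Schema-stable per-patient decision report."""

    patient_id: str
    group: int = Field(ge=1, le=4)
    pet_performed: bool
    diagnosed: bool
    final_label: Optional[str] = None
    advice: str
    advice_trail: list[str]
    stages: list[StageReport]


def _stage_report(name: str, result: StageResult) -> StageReport:
    return StageReport(
        stage=name,
        title=_STAGE_TITLES[name],
        dsi={k: float(v) for k, v in result.profile.dsi.items()},
        top_label=result.profile.top_label,
        margin=float(result.profile.margin),
        pcc=float(result.pcc),
    )


def render_patient_report(
    decision: PatientDecision, evaluator: PatientEvaluator
) -> PatientReport:
    """Assemble the report from a decision and its (cached) evaluator.

    Only stages the decision flow actually executed appear: a directly
    certain patient (group 1) shows the baseline stage alone, a scanned
    patient (groups 3/4) shows all four stages.
    """
    stages = [
        _stage_report(name, evaluator._cache[name])
        for name in evaluator.executed_stages()
    ]
    if decision.group == 1:
        trail = [ADVICE_DIAGNOSE_NOW]
    elif decision.group == 2:
        trail = [ADVICE_NO_PET]
    elif decision.group == 3:
        trail = [ADVICE_ORDER_PET, f"diagnose {decision.final_label}"]
    else:
        trail = [ADVICE_ORDER_PET, ADVICE_STILL_UNCERTAIN]
    return PatientReport(
        patient_id=decision.patient_id,
        group=decision.group,
        pet_performed=decision.pet_performed,
        diagnosed=decision.diagnosed,
        final_label=decision.final_label,
        advice=trail[-1],
        advice_trail=trail,
        stages=stages,
    )


def render_text(report: PatientReport) -> str:
    """Human-readable rendering of a patient report."""
    lines = [f"Patient {report.patient_id} — group {report.group}"]
    for st in report.stages:
        dsi = "  ".join(f"{k}={v:.2f}" for k, v in st.dsi.items())
        lines.append(f"  [{st.title}]")
        lines.append(
            f"    DSI: {dsi}  ->  {st.top_label} "
            f"(margin {st.margin:.2f}, PCC {st.pcc:.2f})"
        )
    lines.append("  advice: " + " -> ".join(report.advice_trail))
    return "\n".join(lines)


def report_json_schema() -> dict:
    """The published JSON schema the report validates against."""
    text = resources.files("petselect").joinpath("data/patient_report.schema.json").read_text()
    return json.loads(text)
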