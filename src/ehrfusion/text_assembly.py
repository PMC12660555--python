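"""Assembly of the per-instance clinical text document.

Structured lab rows are converted to templated sentences ("tabular feature
extraction"): only abnormal results are kept and rendered as

    These are abnormal results recorded: ITEMID<id>: <value> <unit>; ...;

The assembled document concatenates, per history visit in chronological
order, the four note sections (Chief Complaint, Current Illness, Medical
History, Admission Medication) followed by that visit's lab text, with a
visit-delimiter token between visits.  A whitespace-token budget drops whole
visits oldest-first when exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ehr_data import LabResult, NOTE_SECTIONS, PredictionInstance

LAB_TEXT_PREFIX = "These are abnormal results recorded:"


@dataclass
class AssemblyConfig:
    max_tokens: int = 64
    section_order: tuple[str, ...] = NOTE_SECTIONS
    include_lab_text: bool = True           # False => "w/o LABTEXT" ablation input
    section_delimiter: str = "[SEC]"
    visit_delimiter: str = "[VISIT]"


@dataclass
class InputDocument:
    text: str
    n_source_visits: int
    truncated: bool = False


def format_lab_text(labs: list[LabResult]) -> str:
    """Render abnormal lab rows through the fixed sentence template.

    Normal results are dropped; with no abnormal results the empty string is
    returned (no spurious constant prefix enters the text stream).
    """
    entries = [f"ITEMID{l.item_id}: {l.value} {l.unit}".rstrip() for l in labs if l.abnormal]
    if not entries:
        return ""
    return f"{LAB_TEXT_PREFIX} " + "; ".join(entries) + ";"


def _visit_text(visit, config: AssemblyConfig) -> str:
    parts = []
    for section in config.section_order:
        body = visit.note_sections.get(section, "").strip()
        if body:
            parts.append(body)
    if config.include_lab_text:
        lab_text = format_lab_text(visit.labs)
        if lab_text:
            parts.append(lab_text)
    return f" {config.section_delimiter} ".join(parts)


def assemble_input_text(
    instance: PredictionInstance, config: AssemblyConfig | None = None
) -> InputDocument:
    """Concatenate the history's notes and lab text into one document.

    Visits appear in chronological order separated by the visit delimiter.
    If the whitespace-token count exceeds ``config.max_tokens`` whole visits
    are dropped oldest-first; if the most recent visit alone exceeds the
    budget it is hard-truncated to the budget.
    """
    config = config or AssemblyConfig()
    visit_texts = [_visit_text(v, config) for v in instance.history]
    kept = list(visit_texts)
    truncated = False
    while kept:
        text = f" {config.visit_delimiter} ".join(t for t in kept if t)
        if len(text.split()) <= config.max_tokens:
            break
        kept.pop(0)
        truncated = True
    else:
        text = ""
    if not kept:
        # the newest visit alone exceeded the budget: hard-truncate it
        text = " ".join(visit_texts[-1].split()[: config.max_tokens])
        truncated = True
    return InputDocument(text=text, n_source_visits=len(instance.history), truncated=truncated)
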