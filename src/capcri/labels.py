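"""The 18-class sleep/CAP label set and helpers.

Stages follow the Rechtschaffen & Kales macrostructure (W, REM, S1-S4);
within each NREM stage an epoch is either part of a CAP activation phase
(A1, A2, A3) or not (NA).  Wake and REM carry no CAP phase.  The combined
label set therefore has 2 + 4 x 4 = 18 classes.
"""

from __future__ import annotations

WAKE = "W"
REM = "R"
NREM_STAGES = ("S1", "S2", "S3", "S4")
CAP_PHASES = ("A1", "A2", "A3", "NA")
NO_PHASE = "-"

#: Canonical class order: W, REM, then phases A1, A2, A3, NA within S1..S4.
STAGE_LABELS: tuple[str, ...] = (WAKE, REM) + tuple(
    f"{s}-{p}" for s in NREM_STAGES for p in CAP_PHASES
)

LABEL_INDEX = {lab: i for i, lab in enumerate(STAGE_LABELS)}

#: Macro (layer-1) classes.
MACRO_LABELS: tuple[str, ...] = (WAKE, REM) + NREM_STAGES

LIGHT_STAGES = ("S1", "S2")
DEEP_STAGES = ("S3", "S4")

A_PHASES = ("A1", "A2", "A3")


def split_label(label: str) -> tuple[str, str]:
    """Split an 18-class label into ``(stage, cap_phase)``.

    W and REM map to phase ``"-"``.
    """
    if label in (WAKE, REM):
        return label, NO_PHASE
    stage, _, phase = label.partition("-")
    if stage not in NREM_STAGES or phase not in CAP_PHASES:
        raise ValueError(f"unknown stage label: {label!r}")
    return stage, phase


def join_label(stage: str, phase: str) -> str:
    """Combine a stage and CAP phase into an 18-class label."""
    if stage in (WAKE, REM):
        return stage
    if stage not in NREM_STAGES:
        raise ValueError(f"unknown stage: {stage!r}")
    if phase not in CAP_PHASES:
        raise ValueError(f"unknown CAP phase for {stage}: {phase!r}")
    return f"{stage}-{phase}"


def macro_label(label: str) -> str:
    """Collapse an 18-class label to its 6-class macro stage."""
    return split_label(label)[0]


def macro_group(label: str) -> str:
    """Collapse to the WAKE / LIGHT / DEEP / REM training macro-class."""
    stage = macro_label(label)
    if stage in LIGHT_STAGES:
        return "LIGHT"
    if stage in DEEP_STAGES:
        return "DEEP"
    return stage  # W or R


def is_a_phase(label: str) -> bool:
    """True when the epoch is part of a CAP activation (A) phase."""
    return split_label(label)[1] in A_PHASES


def validate_labels(labels) -> None:
    """Raise ``ValueError`` if any label is outside the 18-class set."""
    bad = sorted({str(l) for l in labels} - set(STAGE_LABELS))
    if bad:
        raise ValueError(f"labels outside the 18-class set: {bad}")
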