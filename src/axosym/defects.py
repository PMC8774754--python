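"""Ultrastructural defect calls and per-patient classification (modified
BEAT-PCD criteria), plus the axonemal-asymmetry percentage.

Per-patient classes:

* **C1** (hallmark diagnostic): ODA absent, or ODA+IDA absent, in more
  than 50% of cross-sections.
* **C2** (supporting): ODA absence (or combined ODA+IDA absence) in
  25–50% of sections (inclusive at both ends), or a central-complex
  defect above the configured section-percentage threshold.
* **none**: neither band reached.

Sections with microtubular disorganization are excluded from symmetry
assessment; their arm and central-pair calls still contribute to the
defect percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from axosym.geometry import CrossSection, SectionAssessment

__all__ = [
    "SectionDefectCall",
    "PatientDefectSummary",
    "DEFAULT_ARM_MIN",
    "DEFAULT_CENTRAL_PCT",
    "MIN_DIAGNOSTIC_SECTIONS",
    "call_section_defects",
    "classify_patient",
    "compute_aa",
    "summarize_patient",
]

#: A section is called ODA-absent (resp. IDA-absent) when at most this
#: many evaluable doublets still bear the arm.
DEFAULT_ARM_MIN = 2

#: Class-2 band for central-complex defects: percentage of sections above
#: which the patient is called C2 (no percentage is standard; configurable).
DEFAULT_CENTRAL_PCT = 25.0

#: Diagnostic-grade calls require at least this many cross-sections.
MIN_DIAGNOSTIC_SECTIONS = 50


class LowCoverageWarning(UserWarning):
    """Patient scored on fewer sections than diagnostic practice requires."""


@dataclass(frozen=True)
class SectionDefectCall:
    """Per-section ultrastructural defect flags.

    ``oda_absent``/``ida_absent`` are ``None`` when no doublet had an
    evaluable arm flag.  ``symmetry_break`` is ``None`` for sections not
    assessable for asymmetry (disorganized or incomplete).
    """

    section_id: str
    oda_absent: bool | None
    ida_absent: bool | None
    central_defect: bool
    disorganized: bool
    symmetry_break: bool | None


@dataclass(frozen=True)
class PatientDefectSummary:
    """Per-patient aggregate used for classification and reporting."""

    patient_id: str
    n_sections: int
    n_assessable_aa: int
    pct_oda_absent: float
    pct_oda_ida_absent: float
    pct_central_defect: float
    aa_pct: float
    tem_class: Literal["C1", "C2", "none"]


def call_section_defects(
    section: CrossSection,
    arm_min: int = DEFAULT_ARM_MIN,
    symmetry_break: bool | None = None,
) -> SectionDefectCall:
    """Score one section for arm and central-pair defects.

    An arm is called absent at section level when at most ``arm_min`` of
    the doublets with a known flag still bear it.  Doublets with unknown
    flags are excluded from the denominator; with no evaluable doublet at
    all the call is not-assessable (``None``).  A central-complex defect is
    any central microtubule count other than 2.
    """
    oda_flags = [d.oda_present for d in section.doublets if d.oda_present is not None]
    ida_flags = [d.ida_present for d in section.doublets if d.ida_present is not None]
    oda_absent = sum(oda_flags) <= arm_min if oda_flags else None
    ida_absent = sum(ida_flags) <= arm_min if ida_flags else None
    if section.disorganized:
        symmetry_break = None
    return SectionDefectCall(
        section_id=section.section_id,
        oda_absent=oda_absent,
        ida_absent=ida_absent,
        central_defect=section.central_pair_count != 2,
        disorganized=section.disorganized,
        symmetry_break=symmetry_break,
    )


def classify_patient(
    summary: PatientDefectSummary | None = None,
    *,
    pct_oda_absent: float | None = None,
    pct_oda_ida_absent: float | None = None,
    pct_central_defect: float | None = None,
    n_sections: int | None = None,
    central_pct_threshold: float = DEFAULT_CENTRAL_PCT,
) -> Literal["C1", "C2", "none"]:
    """Assign the TEM class from per-patient defect percentages.

    C1 iff ODA (or combined ODA+IDA) absence exceeds 50% of sections;
    else C2 iff either lies in the inclusive band [25, 50] or the
    central-defect percentage exceeds ``central_pct_threshold``;
    else none.  Exactly 50 → C2; exactly 25 → C2.
    """
    if summary is not None:
        pct_oda_absent = summary.pct_oda_absent
        pct_oda_ida_absent = summary.pct_oda_ida_absent
        pct_central_defect = summary.pct_central_defect
        n_sections = summary.n_sections
    oda = 0.0 if pct_oda_absent is None else pct_oda_absent
    both = 0.0 if pct_oda_ida_absent is None else pct_oda_ida_absent
    central = 0.0 if pct_central_defect is None else pct_central_defect
    for name, v in (("oda", oda), ("oda+ida", both), ("central", central)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"pct_{name} out of [0, 100]: {v}")
    if n_sections is not None and n_sections < MIN_DIAGNOSTIC_SECTIONS:
        warnings.warn(
            f"classification from {n_sections} sections "
            f"(diagnostic practice requires >= {MIN_DIAGNOSTIC_SECTIONS})",
            LowCoverageWarning,
            stacklevel=2,
        )
    if oda > 50.0 or both > 50.0:
        return "C1"
    if 25.0 <= oda <= 50.0 or 25.0 <= both <= 50.0 or central > central_pct_threshold:
        return "C2"
    return "none"


def compute_aa(calls: Sequence[SectionDefectCall]) -> float:
    """Axonemal asymmetry: percentage of sections with a symmetry break
    among the assessable sections (disorganized / not-assessable sections
    leave both numerator and denominator)."""
    assessable = [c for c in calls if c.symmetry_break is not None]
    if not assessable:
        raise ZeroDivisionError("no assessable sections for AA")
    if len(assessable) < MIN_DIAGNOSTIC_SECTIONS:
        warnings.warn(
            f"AA from {len(assessable)} assessable sections "
            f"(>= {MIN_DIAGNOSTIC_SECTIONS} recommended)",
            LowCoverageWarning,
            stacklevel=2,
        )
    return 100.0 * sum(c.symmetry_break for c in assessable) / len(assessable)


def _pct(flags: list[bool]) -> float:
    return 100.0 * sum(flags) / len(flags) if flags else 0.0


def summarize_patient(
    patient_id: str,
    calls: Sequence[SectionDefectCall],
    central_pct_threshold: float = DEFAULT_CENTRAL_PCT,
) -> PatientDefectSummary:
    """Aggregate section calls into the per-patient summary and class."""
    oda = [c.oda_absent for c in calls if c.oda_absent is not None]
    both = [
        c.oda_absent and c.ida_absent
        for c in calls
        if c.oda_absent is not None and c.ida_absent is not None
    ]
    pct_oda = _pct(oda)
    pct_both = _pct(both)
    pct_central = _pct([c.central_defect for c in calls])
    aa = compute_aa(calls)
    n_assessable = sum(c.symmetry_break is not None for c in calls)
    cls = classify_patient(
        pct_oda_absent=pct_oda,
        pct_oda_ida_absent=pct_both,
        pct_central_defect=pct_central,
        n_sections=len(calls),
        central_pct_threshold=central_pct_threshold,
    )
    return PatientDefectSummary(
        patient_id=patient_id,
        n_sections=len(calls),
        n_assessable_aa=n_assessable,
        pct_oda_absent=pct_oda,
        pct_oda_ida_absent=pct_both,
        pct_central_defect=pct_central,
        aa_pct=aa,
        tem_class=cls,
    )
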