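"""Patient-table ingestion, group summaries and cohort-level reports.

Works on per-patient records of the form printed in clinical PCD/TEM
summaries: participant id, group (PCD or control), compatible clinical
index (CCI, %), genetic defect, HSVA beat-pattern category, TEM defect
class (C1 / C2 / none) and axonemal asymmetry (AA, %).  Two packaged
reference tables transcribe the published 20 + 20 participant cohort.

Numeric variables are summarized as mean (sample SD) and median with
1st/3rd quartiles (linear interpolation between order statistics);
categorical variables as absolute frequency (%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "GroupSummary",
    "ingest_patient_table",
    "load_reference_cohort",
    "records_to_frame",
    "summarize",
    "range_and_overlap_report",
]

VALID_HSVA = {"Dyskinetic", "Immotile", "Normal", "N"}
VALID_TEM = {"C1", "C2", "none"}
_TEM_ALIASES = {"no": "none", "none": "none", "c1": "C1", "c2": "C2"}

NUMERIC_FIELDS = ("cci", "aa")
CATEGORICAL_FIELDS = ("gene", "hsva", "tem_class")


@dataclass(frozen=True)
class PatientRecord:
    """One study participant."""

    id: str
    group: Literal["PCD", "control"]
    cci: float
    gene: str
    hsva: str
    tem_class: Literal["C1", "C2", "none"]
    aa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.aa <= 100.0:
            raise ValueError(f"patient {self.id}: AA out of [0, 100]: {self.aa}")
        if not 0.0 <= self.cci <= 100.0:
            raise ValueError(f"patient {self.id}: CCI out of [0, 100]: {self.cci}")
        if self.hsva not in VALID_HSVA:
            raise ValueError(f"patient {self.id}: unknown HSVA token {self.hsva!r}")
        if self.tem_class not in VALID_TEM:
            raise ValueError(f"patient {self.id}: unknown TEM class {self.tem_class!r}")


@dataclass
class GroupSummary:
    """Mean (SD) / n (%) and median (1st, 3rd Q.) for one group level."""

    level: str
    n: int
    numeric: dict = field(default_factory=dict)  # field -> stats dict
    categorical: dict = field(default_factory=dict)  # field -> {level: (n, pct)}


def ingest_patient_table(path, group: str | None = None) -> list[PatientRecord]:
    """Load and validate a patient CSV.

    Expected columns: ``id, group, cci_pct, genetic_defect, hsva,
    tem_defect, aa_pct`` (``group`` may instead be supplied as an
    argument).  Malformed rows and duplicate ids raise with the offending
    row number; an empty file returns an empty list with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        warnings.warn(f"{path}: empty patient table", stacklevel=2)
        return []
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            pid = str(row.id).strip()
            grp = group if group is not None else str(row.group).strip()
            if grp not in ("PCD", "control"):
                raise ValueError(f"unknown group {grp!r}")
            tem = _TEM_ALIASES.get(str(row.tem_defect).strip().lower())
            if tem is None:
                raise ValueError(f"unknown TEM class token {row.tem_defect!r}")
            rec = PatientRecord(
                id=pid,
                group=grp,  # type: ignore[arg-type]
                cci=float(row.cci_pct),
                gene=str(row.genetic_defect).strip(),
                hsva=str(row.hsva).strip(),
                tem_class=tem,  # type: ignore[arg-type]
                aa=float(row.aa_pct),
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}, row {pos}: {exc}") from exc
        if rec.id in seen:
            raise ValueError(f"{path}, row {pos}: duplicate patient id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    return records


def load_reference_cohort() -> list[PatientRecord]:
    """The packaged 20 PCD + 20 control reference tables."""
    out: list[PatientRecord] = []
    for name in ("pcd_patients.csv", "control_patients.csv"):
        with resources.as_file(resources.files("axosym.data") / name) as p:
            out.extend(ingest_patient_table(p))
    return out


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "group": r.group,
                "cci": r.cci,
                "gene": r.gene,
                "hsva": r.hsva,
                "tem_class": r.tem_class,
                "aa": r.aa,
            }
            for r in records
        ]
    )


def _numeric_stats(values: np.ndarray) -> dict:
    n = len(values)
    if n == 0:
        return {"n": 0, "mean": None, "sd": None, "median": None, "q1": None, "q3": None}
    return {
        "n": n,
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if n > 1 else None,
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),  # linear interpolation
        "q3": float(np.percentile(values, 75)),
    }


def summarize(
    records: Iterable[PatientRecord], group_by: str = "group"
) -> dict[str, GroupSummary]:
    """Per-level summaries in the printed-table layout: mean (SD) and
    median (Q1, Q3) for CCI and AA, absolute frequency (%) for the
    categorical fields."""
    df = records_to_frame(records)
    out: dict[str, GroupSummary] = {}
    if df.empty:
        return out
    if group_by not in df.columns:
        raise KeyError(f"unknown grouping field {group_by!r}")
    for level, sub in df.groupby(group_by, sort=True):
        gs = GroupSummary(level=str(level), n=len(sub))
        for fieldname in NUMERIC_FIELDS:
            gs.numeric[fieldname] = _numeric_stats(sub[fieldname].to_numpy(float))
        for fieldname in CATEGORICAL_FIELDS:
            counts = sub[fieldname].value_counts()
            gs.categorical[fieldname] = {
                str(k): (int(v), 100.0 * v / len(sub)) for k, v in counts.items()
            }
        out[str(level)] = gs
    return out


def range_and_overlap_report(records: Iterable[PatientRecord]) -> dict:
    """Cohort-level findings: per-group AA range, control participants
    whose AA reaches the PCD range, and the fraction of PCD participants
    with no TEM defect."""
    df = records_to_frame(records)
    report: dict = {"warnings": []}
    for grp in ("PCD", "control"):
        sub = df[df.group == grp] if not df.empty else df
        if sub.empty:
            report["warnings"].append(f"group {grp!r} absent")
            report[grp] = None
            continue
        report[grp] = {"n": len(sub), "aa_min": float(sub.aa.min()), "aa_max": float(sub.aa.max())}
    if report.get("PCD") and report.get("control"):
        pcd_min = report["PCD"]["aa_min"]
        ctrl = df[(df.group == "control") & (df.aa >= pcd_min)]
        report["controls_in_pcd_range"] = sorted(ctrl.id.tolist(), key=str)
    else:
        report["controls_in_pcd_range"] = None
    if report.get("PCD"):
        pcd = df[df.group == "PCD"]
        frac = float((pcd.tem_class == "none").mean())
        report["pcd_no_defect_fraction"] = frac
        report["pcd_no_defect_pct"] = 100.0 * frac
    else:
        report["pcd_no_defect_fraction"] = None
        report["pcd_no_defect_pct"] = None
    return report
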