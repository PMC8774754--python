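"""Reading and writing section-level coordinate tables.

Two companion CSVs describe a set of cross-sections:

* doublet table — one row per peripheral doublet:
  ``section_id, doublet_index, ax, ay, bx, by, r_a, r_b, oda_present,
  ida_present`` (arm flags ``0``/``1``/``NA``);
* section table — one row per section:
  ``section_id, central_pair_count, disorganized, n_peripheral``.

Coordinates are in the mathematical frame (y up), pixel units.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from axosym.geometry import CrossSection, DoubletObservation

__all__ = ["read_sections", "write_sections"]

_DOUBLET_COLS = [
    "section_id",
    "doublet_index",
    "ax",
    "ay",
    "bx",
    "by",
    "r_a",
    "r_b",
    "oda_present",
    "ida_present",
]
_SECTION_COLS = ["section_id", "central_pair_count", "disorganized", "n_peripheral"]


def _flag_to_cell(v: bool | None) -> str:
    return "NA" if v is None else str(int(v))


def _cell_to_flag(v) -> bool | None:
    if pd.isna(v) or str(v).strip().upper() == "NA":
        return None
    return bool(int(v))


def write_sections(sections: Iterable[CrossSection], doublet_csv, section_csv) -> None:
    """Serialize sections to the doublet/section CSV pair."""
    drows, srows = [], []
    for s in sections:
        srows.append(
            {
                "section_id": s.section_id,
                "central_pair_count": s.central_pair_count,
                "disorganized": int(s.disorganized),
                "n_peripheral": len(s.doublets),
            }
        )
        for d in s.doublets:
            drows.append(
                {
                    "section_id": s.section_id,
                    "doublet_index": d.index,
                    "ax": d.a_center[0],
                    "ay": d.a_center[1],
                    "bx": d.b_center[0],
                    "by": d.b_center[1],
                    "r_a": d.r_a,
                    "r_b": d.r_b,
                    "oda_present": _flag_to_cell(d.oda_present),
                    "ida_present": _flag_to_cell(d.ida_present),
                }
            )
    # %.17g keeps the coordinate round trip bit-exact
    pd.DataFrame(drows, columns=_DOUBLET_COLS).to_csv(
        doublet_csv, index=False, float_format="%.17g"
    )
    pd.DataFrame(srows, columns=_SECTION_COLS).to_csv(section_csv, index=False)


def read_sections(doublet_csv, section_csv) -> list[CrossSection]:
    """Load sections from the doublet/section CSV pair."""
    ddf = pd.read_csv(
        doublet_csv,
        dtype={"section_id": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    sdf = pd.read_csv(section_csv, dtype={"section_id": str}, keep_default_na=False)
    missing = set(_SECTION_COLS) - set(sdf.columns)
    if missing:
        raise ValueError(f"{section_csv}: missing columns {sorted(missing)}")
    by_section: dict[str, list[DoubletObservation]] = {}
    for row in ddf.itertuples(index=False):
        by_section.setdefault(str(row.section_id), []).append(
            DoubletObservation(
                index=int(row.doublet_index),
                a_center=(float(row.ax), float(row.ay)),
                b_center=(float(row.bx), float(row.by)),
                r_a=float(row.r_a),
                r_b=float(row.r_b),
                oda_present=_cell_to_flag(row.oda_present),
                ida_present=_cell_to_flag(row.ida_present),
            )
        )
    sections = []
    for row in sdf.itertuples(index=False):
        sid = str(row.section_id)
        sections.append(
            CrossSection(
                section_id=sid,
                doublets=sorted(by_section.get(sid, []), key=lambda d: d.index),
                central_pair_count=int(row.central_pair_count),
                disorganized=bool(int(row.disorganized)),
            )
        )
    return sections
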