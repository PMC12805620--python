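"""IASLC-style grading of lung adenocarcinoma from growth-pattern percentages.

Grade 1 (well differentiated): lepidic-predominant; Grade 2
(moderately): acinar- or papillary-predominant; Grade 3 (poorly):
solid- or micropapillary-predominant, or any tumour whose high-grade
component (solid + micropapillary) reaches 20%.  Ties in predominance
are broken toward the higher-grade pattern, which can only upgrade risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tiles import PATTERNS

#: base grade of the predominant pattern
BASE_GRADE = {"lepidic": 1, "acinar": 2, "papillary": 2,
              "micropapillary": 3, "solid": 3}
HIGH_GRADE_PATTERNS = ("solid", "micropapillary")
HIGH_GRADE_CUTOFF_PCT = 20.0

GROUPING_SCHEMES = ("three_tier", "12v3", "1v23")


@dataclass(frozen=True)
class GradeAssignment:
    patient_id: str
    predominant_pattern: str
    high_grade_pct: float
    grade: int


def assign_grade(percentages: dict[str, float], patient_id: str = "?") -> GradeAssignment:
    """Grade one tumour from its growth-pattern percentages.

    ``percentages`` maps the five patterns to percents summing to 100
    (absent patterns default to 0).
    """
    pct = {p: float(percentages.get(p, 0.0)) for p in PATTERNS}
    total = sum(pct.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"pattern percentages sum to {total:g}, expected 100")
    # predominant pattern; ties go to the higher-grade pattern
    predominant = max(PATTERNS, key=lambda p: (pct[p], BASE_GRADE[p]))
    high = sum(pct[p] for p in HIGH_GRADE_PATTERNS)
    grade = BASE_GRADE[predominant]
    if high >= HIGH_GRADE_CUTOFF_PCT:
        grade = 3
    return GradeAssignment(patient_id, predominant, high, grade)


def assign_grades(features: pd.DataFrame) -> pd.DataFrame:
    """Vector version over a feature table with ``pct_{pattern}`` columns."""
    rows = []
    for pid, row in features.iterrows():
        g = assign_grade({p: row[f"pct_{p}"] for p in PATTERNS}, patient_id=str(pid))
        rows.append({"patient_id": g.patient_id,
                     "predominant_pattern": g.predominant_pattern,
                     "high_grade_pct": g.high_grade_pct,
                     "grade": g.grade})
    return pd.DataFrame(rows).set_index("patient_id")


def grade_groupings(grades, scheme: str = "12v3") -> list[str]:
    """Collapse grades 1-3 into prognostic groups.

    ``three_tier`` keeps G1/G2/G3; ``12v3`` pools G1+G2 as low vs G3 as
    high; ``1v23`` pools G2+G3 as high vs G1 as low.
    """
    if scheme not in GROUPING_SCHEMES:
        raise ValueError(f"unknown grouping scheme {scheme!r}; choose from {GROUPING_SCHEMES}")
    out = []
    for g in grades:
        if g not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3, got {g!r}")
        if scheme == "three_tier":
            out.append(f"G{g}")
        elif scheme == "12v3":
            out.append("low" if g <= 2 else "high")
        else:
            out.append("low" if g == 1 else "high")
    return out
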