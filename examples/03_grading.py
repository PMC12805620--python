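"""IASLC-style grading from growth-pattern percentages.

Grade 1/2/3 by the predominant pattern, upgraded to 3 when the
high-grade component (solid + micropapillary) reaches 20%.
"""

from gpstils import assign_grade, grade_groupings

cases = [
    {"lepidic": 70, "acinar": 20, "solid": 10},            # lepidic-predominant
    {"acinar": 50, "lepidic": 30, "solid": 20},            # upgraded at exactly 20%
    {"papillary": 60, "acinar": 30, "micropapillary": 10},
    {"solid": 100},
    {"lepidic": 50, "acinar": 50},                         # tie -> higher grade
]

grades = []
for pct in cases:
    g = assign_grade(pct)
    grades.append(g.grade)
    print(f"{pct!s:60s} -> predominant {g.predominant_pattern:10s} "
          f"high-grade {g.high_grade_pct:5.1f}%  Grade {g.grade}")

print("\nlow/high groups (G1+G2 vs G3):", grade_groupings(grades, "12v3"))
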