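"""Normalize polar soma measurements into (DV, ML) coordinates.

Builds a tiny two-section dataset by hand, runs the normalization and
prints the dimensionless positions.  DV = D sin(a)/H is the fraction of
the section height above the ventral-most point; ML = |D cos(a)|/W the
fraction of the hemicord width from the midline (folded so both sides
map onto one hemicord).
"""

import pandas as pd

from cordmapper.geometry import normalize_table

sections = pd.DataFrame([
    dict(section_id="s1", embryo_id="e1", group="control", stage="e12.5",
         axial_level="thoracic", side="right", H=200.0, W=100.0, unit="px"),
    dict(section_id="s2", embryo_id="e1", group="control", stage="e12.5",
         axial_level="thoracic", side="left", H=190.0, W=95.0, unit="px"),
])
cells = pd.DataFrame([
    dict(cell_id="c1", section_id="s1", population="dI2", markers="Foxd3",
         D=150.0, alpha_deg=60.0),
    dict(cell_id="c2", section_id="s1", population="dI2", markers="Foxd3;Brn3a",
         D=200.0, alpha_deg=90.0),   # straight dorsal: dv = 1, ml = 0
    dict(cell_id="c3", section_id="s2", population="dI2", markers="Foxd3",
         D=100.0, alpha_deg=150.0),  # left side, folded onto the hemicord
])

out = normalize_table(cells, sections)
print(out[["cell_id", "section_id", "dv", "ml", "outlier_flag"]].to_string(index=False))
print("\nEach row is one soma: dv/ml are fractions of section height and "
      "hemicord width; flags mark positions beyond 1.05 (kept, not clamped).")
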