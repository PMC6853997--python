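"""Normalization of polar soma measurements into (DV, ML) coordinates.

Each soma in a transverse hemisection is recorded as a distance D and an
angle alpha (degrees) from the ventral-most midline point of the section.
With section height H (ventral-most to dorsal-most point) and hemicord
width W (central canal to lateral edge), the dimensionless position is

    DV = D * sin(alpha) / H        ML = |D * cos(alpha)| / W

The absolute value folds left and right hemisections onto a single
positive hemicord, so angles alpha and 180 - alpha map to the same point.
Positions are pooled across sections and embryos into population samples
for the spatial statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cordmapper.errors import ReferenceError_, ValidationError

AXIAL_LEVELS = ("brachial", "thoracic", "lumbar", "unspecified")
SIDES = ("left", "right")

#: normalized coordinates above this are flagged (kept, never clamped)
DEFAULT_FLAG_THRESHOLD = 1.05


@dataclass(frozen=True)
class SectionGeometry:
    """Measured frame of one transverse hemisection.

    H and W must be positive and share one length unit (px or um) per
    dataset; ratios cancel so the unit is validated, never converted.
    """

    section_id: str
    embryo_id: str
    group: str
    stage: str = ""
    axial_level: str = "unspecified"
    side: str = "right"
    H: float = float("nan")
    W: float = float("nan")
    unit: str = "px"

    def __post_init__(self) -> None:
        if not (self.H > 0) or not (self.W > 0):
            raise ValidationError(
                f"section {self.section_id!r}: H and W must be positive "
                f"(got H={self.H}, W={self.W})"
            )
        if self.axial_level not in AXIAL_LEVELS:
            raise ValidationError(
                f"section {self.section_id!r}: axial_level must be one of "
                f"{AXIAL_LEVELS}, got {self.axial_level!r}"
            )
        if self.side not in SIDES:
            raise ValidationError(
                f"section {self.section_id!r}: side must be 'left' or 'right', "
                f"got {self.side!r}"
            )


@dataclass(frozen=True)
class RawCellMeasurement:
    """One soma's polar measurement tied to a section.

    D is the distance from the ventral-most midline point to the soma
    center (same unit as H); alpha the angle in degrees between the
    horizontal medio-lateral axis through that point and the ray to the
    soma, in [0, 180].
    """

    cell_id: str
    section_id: str
    D: float
    alpha_deg: float
    population: str = ""
    markers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValidationError(f"cell {self.cell_id!r}: D must be >= 0, got {self.D}")
        if not (0.0 <= self.alpha_deg <= 180.0):
            raise ValidationError(
                f"cell {self.cell_id!r}: alpha must lie in [0, 180] degrees, "
                f"got {self.alpha_deg}"
            )
        object.__setattr__(self, "markers", frozenset(self.markers))


@dataclass(frozen=True)
class NormalizedPosition:
    """Dimensionless (dv, ml) position with carried metadata."""

    cell_id: str
    dv: float
    ml: float
    outlier_flag: bool
    section_id: str
    embryo_id: str
    group: str
    stage: str = ""
    axial_level: str = "unspecified"
    population: str = ""
    markers: frozenset[str] = field(default_factory=frozenset)


@dataclass
class PopulationSample:
    """Pooled normalized positions for one population x group x level."""

    population: str
    group: str
    axial_level: str
    positions: list[NormalizedPosition]
    stage: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def n_sections(self) -> int:
        return len({p.section_id for p in self.positions})

    @property
    def n_embryos(self) -> int:
        return len({p.embryo_id for p in self.positions})

    @property
    def n_outliers(self) -> int:
        return sum(p.outlier_flag for p in self.positions)

    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array of (dv, ml)."""
        return np.array([[p.dv, p.ml] for p in self.positions], dtype=float)

    @classmethod
    def from_xy(
        cls,
        xy: np.ndarray,
        population: str = "",
        group: str = "",
        axial_level: str = "unspecified",
    ) -> "PopulationSample":
        """Build a sample from bare coordinates (one synthetic section)."""
        xy = np.asarray(xy, dtype=float)
        positions = [
            NormalizedPosition(
                cell_id=f"c{i}", dv=float(dv), ml=float(ml), outlier_flag=False,
                section_id="s0", embryo_id="e0", group=group,
                axial_level=axial_level, population=population,
            )
            for i, (dv, ml) in enumerate(xy)
        ]
        return cls(population=population, group=group, axial_level=axial_level,
                   positions=positions)


def normalize_position(
    raw: RawCellMeasurement,
    geom: SectionGeometry,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    angle_from: str = "horizontal",
) -> NormalizedPosition:
    """Map one polar measurement to normalized (dv, ml).

    Parameters
    ----------
    raw, geom
        The measurement and the geometry of its section; their
        ``section_id`` must match.
    flag_threshold
        Coordinates above this are flagged as out-of-range but kept.
    angle_from
        ``"horizontal"`` (default): alpha measured from the medio-lateral
        axis, so sin(alpha) gives the vertical component.  ``"vertical"``
        accepts angles measured from the dorso-ventral axis instead.
    """
    if raw.section_id != geom.section_id:
        raise ReferenceError_(
            f"cell {raw.cell_id!r} references section {raw.section_id!r} "
            f"but geometry is for {geom.section_id!r}"
        )
    if angle_from not in ("horizontal", "vertical"):
        raise ValidationError(f"angle_from must be 'horizontal' or 'vertical', got {angle_from!r}")
    a = math.radians(raw.alpha_deg)
    if angle_from == "vertical":
        a = math.pi / 2 - a
    dv = raw.D * math.sin(a) / geom.H
    ml = abs(raw.D * math.cos(a)) / geom.W
    return NormalizedPosition(
        cell_id=raw.cell_id,
        dv=dv,
        ml=ml,
        outlier_flag=bool(dv > flag_threshold or ml > flag_threshold),
        section_id=raw.section_id,
        embryo_id=geom.embryo_id,
        group=geom.group,
        stage=geom.stage,
        axial_level=geom.axial_level,
        population=raw.population,
        markers=raw.markers,
    )


def normalize_table(
    cells: pd.DataFrame,
    sections: pd.DataFrame,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    angle_from: str = "horizontal",
) -> pd.DataFrame:
    """Vectorized normalization of a cells table against a sections table.

    ``cells`` needs columns cell_id, section_id, population, markers, D,
    alpha_deg; ``sections`` needs section_id, embryo_id, group, stage,
    axial_level, side, H, W, unit.  Returns the cells table with section
    metadata joined in and dv, ml, outlier_flag columns appended.
    """
    report = validate_dataset(sections, cells)
    if report.fatal():
        raise ValidationError("dataset invalid:\n" + report.describe())
    merged = cells.merge(sections, on="section_id", how="left", validate="many_to_one")
    a = np.radians(merged["alpha_deg"].to_numpy(dtype=float))
    if angle_from == "vertical":
        a = np.pi / 2 - a
    elif angle_from != "horizontal":
        raise ValidationError(f"angle_from must be 'horizontal' or 'vertical', got {angle_from!r}")
    D = merged["D"].to_numpy(dtype=float)
    out = merged.copy()
    out["dv"] = D * np.sin(a) / merged["H"].to_numpy(dtype=float)
    out["ml"] = np.abs(D * np.cos(a)) / merged["W"].to_numpy(dtype=float)
    out["outlier_flag"] = (out["dv"] > flag_threshold) | (out["ml"] > flag_threshold)
    return out


@dataclass
class ValidationReport:
    """Problems found in a raw dataset; empty iff the dataset is clean."""

    orphan_cells: list[str] = field(default_factory=list)
    duplicate_sections: list[str] = field(default_factory=list)
    duplicate_cells: list[str] = field(default_factory=list)
    out_of_range: list[str] = field(default_factory=list)
    unit_inconsistencies: list[str] = field(default_factory=list)

    def empty(self) -> bool:
        return not (
            self.orphan_cells or self.duplicate_sections or self.duplicate_cells
            or self.out_of_range or self.unit_inconsistencies
        )

    def fatal(self) -> bool:
        # any structural problem prevents normalization
        return not self.empty()

    def describe(self) -> str:
        lines = []
        for name, items in (
            ("orphan cells (no matching section)", self.orphan_cells),
            ("duplicate section_id", self.duplicate_sections),
            ("duplicate cell_id", self.duplicate_cells),
            ("out-of-range fields", self.out_of_range),
            ("unit inconsistencies", self.unit_inconsistencies),
        ):
            if items:
                lines.append(f"{name}: {', '.join(map(str, items))}")
        return "\n".join(lines) if lines else "clean"


def validate_dataset(sections: pd.DataFrame, cells: pd.DataFrame) -> ValidationReport:
    """Check referential integrity, id uniqueness, field ranges and units.

    All problems are collected into the report; nothing is raised.
    """
    rep = ValidationReport()
    dup_sec = sections["section_id"][sections["section_id"].duplicated()].unique()
    rep.duplicate_sections = [str(s) for s in dup_sec]
    if "cell_id" in cells:
        dup_cell = cells["cell_id"][cells["cell_id"].duplicated()].unique()
        rep.duplicate_cells = [str(c) for c in dup_cell]
    known = set(sections["section_id"])
    orphans = cells.loc[~cells["section_id"].isin(known), "cell_id"]
    rep.orphan_cells = [str(c) for c in orphans]
    for _, row in sections.iterrows():
        if not (row["H"] > 0) or not (row["W"] > 0):
            rep.out_of_range.append(f"section {row['section_id']}: H/W not positive")
        if "axial_level" in row and row["axial_level"] not in AXIAL_LEVELS:
            rep.out_of_range.append(
                f"section {row['section_id']}: axial_level {row['axial_level']!r}"
            )
    bad_d = cells.loc[cells["D"] < 0, "cell_id"]
    rep.out_of_range += [f"cell {c}: D < 0" for c in bad_d]
    bad_a = cells.loc[(cells["alpha_deg"] < 0) | (cells["alpha_deg"] > 180), "cell_id"]
    rep.out_of_range += [f"cell {c}: alpha outside [0, 180]" for c in bad_a]
    if "unit" in sections and sections["unit"].nunique() > 1:
        rep.unit_inconsistencies = [
            f"mixed units in sections table: {sorted(sections['unit'].unique())}"
        ]
    return rep


def pool_samples(
    positions: Iterable[NormalizedPosition] | pd.DataFrame,
    keys: Sequence[str] = ("population", "group", "axial_level"),
) -> list[PopulationSample]:
    """Partition normalized positions into one PopulationSample per
    distinct key combination.

    Accepts either NormalizedPosition objects or a normalized table (as
    produced by :func:`normalize_table`).  Every input position lands in
    exactly one sample; out-of-range-flagged positions are included (the
    statistics see the data as measured) and counted via ``n_outliers``.
    """
    if isinstance(positions, pd.DataFrame):
        positions = [
            NormalizedPosition(
                cell_id=str(r.cell_id), dv=float(r.dv), ml=float(r.ml),
                outlier_flag=bool(r.outlier_flag),
                section_id=str(r.section_id), embryo_id=str(r.embryo_id),
                group=str(r.group), stage=str(getattr(r, "stage", "")),
                axial_level=str(getattr(r, "axial_level", "unspecified")),
                population=str(getattr(r, "population", "")),
            )
            for r in positions.itertuples(index=False)
        ]
    buckets: dict[tuple, list[NormalizedPosition]] = {}
    for p in positions:
        key = tuple(getattr(p, k) for k in keys)
        buckets.setdefault(key, []).append(p)
    samples = []
    for key, plist in buckets.items():
        kw = dict(zip(keys, key))
        first = plist[0]
        samples.append(
            PopulationSample(
                population=kw.get("population", first.population),
                group=kw.get("group", first.group),
                axial_level=kw.get("axial_level", first.axial_level),
                stage=kw.get("stage", first.stage),
                positions=plist,
            )
        )
    return samples


def polar_from_normalized(dv: float, ml: float, H: float, W: float) -> tuple[float, float]:
    """Inverse transform: (dv, ml) in the unit hemicord -> (D, alpha_deg).

    Exact inverse of :func:`normalize_position` for the right hemicord
    (alpha in [0, 90] when both coordinates are non-negative).
    """
    y = dv * H
    x = ml * W
    D = math.hypot(x, y)
    alpha = math.degrees(math.atan2(y, x)) if D > 0 else 0.0
    return D, alpha
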