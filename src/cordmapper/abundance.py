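"""Scalar quantifications: cell counts, co-labeling proportions and
ISH signal intensity.

The replication unit is the embryo: per-section values are averaged
within each embryo first, then means +/- SEM are taken over embryos
(the study design is 3 embryos x 5 sections per axial level).  Two-group
comparisons use a pooled-variance Student's t-test or an exact
Mann-Whitney U; the automatic rule applies Shapiro-Wilk normality and a
variance-ratio F pretest at 0.05 and falls back to Mann-Whitney when
either fails.  ISH intensity is the mean pixel value inside a fixed-area
rectangular ROI minus the mean of an adjacent background ROI, in
arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cordmapper.errors import ConfigError, DataError, DegenerateDataError

DEFAULT_ROI_AREA = 13_500  # px^2, fixed rectangle area for ISH measurements
SIGNIFICANCE_THRESHOLD = 0.05


# ---------------------------------------------------------------- counts

@dataclass
class GroupSummary:
    """Mean +/- SEM of counts for one group x axial level."""

    group: str
    axial_level: str
    unit_means: dict[str, float]  # per-embryo (or per-section) means
    mean: float
    sem: float
    n_units: int
    single_unit_flag: bool = False  # SEM is 0 by convention when n_units == 1


def summarize_counts(
    records: pd.DataFrame,
    unit: str = "embryo",
) -> list[GroupSummary]:
    """Mean +/- SEM per group x axial level.

    ``records`` needs columns embryo_id, group, axial_level, section_id,
    count.  With ``unit="embryo"`` (default, matching the study design)
    each embryo's sections are averaged first and SEM is taken over
    embryo means; ``unit="section"`` treats sections directly (power
    studies only).
    """
    if unit not in ("embryo", "section"):
        raise ConfigError(f"unit must be 'embryo' or 'section', got {unit!r}")
    out: list[GroupSummary] = []
    for (group, level), sub in records.groupby(["group", "axial_level"], sort=True):
        if unit == "embryo":
            means = sub.groupby("embryo_id")["count"].mean()
        else:
            means = sub.set_index("section_id")["count"].astype(float)
        n = len(means)
        sem = float(means.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            GroupSummary(
                group=str(group), axial_level=str(level),
                unit_means={str(k): float(v) for k, v in means.items()},
                mean=float(means.mean()), sem=sem, n_units=n,
                single_unit_flag=(n == 1),
            )
        )
    return out


@dataclass
class CountComparisonResult:
    """Two-group comparison of per-unit count (or intensity) values."""

    test_used: str  # "student_t" or "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    threshold: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    fold_change: float | None = None
    fold_change_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "threshold": self.threshold,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "fold_change": self.fold_change,
            "fold_change_defined": self.fold_change_defined,
        }


def _choose_test(a: np.ndarray, b: np.ndarray) -> str:
    """Automatic test selection: Shapiro-Wilk in both groups and a
    two-sided variance-ratio F pretest, all at 0.05.  Normal-looking
    data with comparable variances get Student's t; anything else gets
    Mann-Whitney.  Groups too small for Shapiro (n < 3) or with zero
    variance fall back to Mann-Whitney."""
    for g in (a, b):
        if len(g) < 3 or np.ptp(g) == 0:
            return "mann_whitney"
        if stats.shapiro(g).pvalue < 0.05:
            return "mann_whitney"
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    d1, d2 = len(a) - 1, len(b) - 1
    p_var = 2 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return "student_t" if p_var >= 0.05 else "mann_whitney"


def compare_counts(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
    threshold: float = SIGNIFICANCE_THRESHOLD,
    welch: bool = False,
) -> CountComparisonResult:
    """Two-sided two-group test on per-unit values.

    ``method`` is "auto" (pretest cascade, see :func:`_choose_test`),
    "student_t" (pooled-variance, or Welch with ``welch=True``) or
    "mann_whitney" (exact for n <= 8 per group, tie-corrected normal
    approximation above).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "auto":
        method = _choose_test(a, b)
    if method == "student_t":
        if len(a) < 2 or len(b) < 2:
            raise DegenerateDataError("Student's t needs >= 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise DegenerateDataError(
                "all values identical in both groups; t statistic undefined"
            )
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(stat), float(p)
    elif method == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise DegenerateDataError("Mann-Whitney needs >= 1 value per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            # every observation tied: no evidence either way
            return CountComparisonResult(
                test_used=method, statistic=len(a) * len(b) / 2, p_value=1.0,
                significant=False, threshold=threshold,
                mean_a=float(a.mean()), mean_b=float(b.mean()),
                n_a=len(a), n_b=len(b),
            )
        mw_method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        try:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        except ValueError:
            # exact method refuses ties; fall back to tie-corrected normal
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    else:
        raise ConfigError(f"unknown method {method!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return CountComparisonResult(
        test_used=method, statistic=stat, p_value=p,
        significant=bool(p <= threshold), threshold=threshold,
        mean_a=mean_a, mean_b=mean_b, n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------- co-labeling

def colabel_counts(
    cells: pd.DataFrame,
    markers_required: set[str],
    markers_reference: set[str],
) -> pd.DataFrame:
    """Per-section proportion of reference-population cells that also
    carry the required markers.

    ``cells`` needs columns section_id and markers (semicolon-joined
    string or set).  For each section,

        proportion = #{cells with markers >= required | reference} /
                     #{cells with markers >= reference}

    where ``required`` implicitly includes the reference set (e.g. the
    fraction of Foxd3+ dI2 cells that are also Pou2f2+ uses
    reference={Foxd3}, required={Pou2f2}).  Sections with an empty
    reference population get proportion NaN and are excluded from means.
    """
    if not markers_required or not markers_reference:
        raise ConfigError("marker sets must be non-empty")

    def _markers(v) -> frozenset:
        if isinstance(v, (set, frozenset)):
            return frozenset(v)
        if isinstance(v, str):
            return frozenset(m for m in v.split(";") if m)
        raise DataError(f"unparseable markers value: {v!r}")

    need = set(markers_required) | set(markers_reference)
    rows = []
    for section_id, sub in cells.groupby("section_id", sort=True):
        msets = sub["markers"].map(_markers)
        denom = int(msets.map(lambda m: m >= markers_reference).sum())
        numer = int(msets.map(lambda m: m >= need).sum())
        rows.append({
            "section_id": section_id,
            "n_reference": denom,
            "n_colabeled": numer,
            "proportion": numer / denom if denom else np.nan,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------ intensity

@dataclass
class IntensityMeasurement:
    """One section's ISH signal: ROI mean minus background mean (a.u.)."""

    roi_mean: float
    background_mean: float
    roi_area_px: int
    embryo_id: str = ""
    group: str = ""
    section_id: str = ""

    @property
    def net(self) -> float:
        return self.roi_mean - self.background_mean


def _rect_slice(image: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """rect = (row0, row1, col0, col1), 0-based half-open."""
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise DataError(
            f"ROI {rect} does not lie within image of shape {image.shape}"
        )
    return image[r0:r1, c0:c1]


def intensity_quantify(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    expected_area: int = DEFAULT_ROI_AREA,
    embryo_id: str = "",
    group: str = "",
    section_id: str = "",
) -> IntensityMeasurement:
    """Mean intensity in a fixed-area ROI minus an adjacent background ROI.

    Rectangles are (row0, row1, col0, col1), 0-based half-open.  The
    signal ROI's area must equal ``expected_area`` up to one row or
    column of rounding; the two ROIs must not overlap.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DataError("intensity_quantify expects a 2D grayscale image")
    sig = _rect_slice(image, roi)
    bg = _rect_slice(image, background_roi)
    area = sig.size
    tol = max(sig.shape)  # one row/column of rounding slack
    if expected_area is not None and abs(area - expected_area) > tol:
        raise ConfigError(
            f"ROI area {area} px^2 differs from configured {expected_area} px^2 "
            f"by more than one row/column"
        )
    r0, r1, c0, c1 = roi
    b0, b1, d0, d1 = background_roi
    if (r0 < b1 and b0 < r1) and (c0 < d1 and d0 < c1):
        raise ConfigError("background ROI overlaps the signal ROI")
    return IntensityMeasurement(
        roi_mean=float(sig.mean()), background_mean=float(bg.mean()),
        roi_area_px=int(area), embryo_id=embryo_id, group=group,
        section_id=section_id,
    )


def compare_intensity(
    a: Iterable[IntensityMeasurement],
    b: Iterable[IntensityMeasurement],
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> CountComparisonResult:
    """Pooled-variance Student's t on per-embryo mean net intensities.

    Each embryo contributes the mean of its sections' net values.  The
    fold change mean_b / mean_a is reported; it is undefined (flagged)
    when mean_a <= 0, but the t statistic is still computed.
    """
    def per_embryo(ms: Iterable[IntensityMeasurement]) -> np.ndarray:
        df = pd.DataFrame(
            {"embryo_id": m.embryo_id, "net": m.net} for m in ms
        )
        if df.empty:
            raise DegenerateDataError("no intensity measurements")
        return df.groupby("embryo_id")["net"].mean().to_numpy()

    va, vb = per_embryo(a), per_embryo(b)
    if len(va) < 2 or len(vb) < 2:
        raise DegenerateDataError("compare_intensity needs >= 2 embryos per group")
    res = compare_counts(va, vb, method="student_t", threshold=threshold)
    if res.mean_a > 0:
        res.fold_change = res.mean_b / res.mean_a
        res.fold_change_defined = True
    else:
        res.fold_change = None
        res.fold_change_defined = False
    return res
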