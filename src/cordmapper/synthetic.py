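"""Synthetic hemicord datasets with retained ground truth.

The generator emulates the study design the analysis modules assume:
3 embryos per condition, 5 transverse hemisections per axial level
(brachial, thoracic, lumbar), soma positions drawn from per-population
Gaussian-mixture clusters in normalized (dv, ml) coordinates and emitted
as raw polar measurements through the exact inverse transform

    D = sqrt((dv*H)^2 + (ml*W)^2),   alpha = atan2(dv*H, ml*W)

so that normalization recovers the sampled positions to machine
precision.  Section geometries are log-normal (H, W always positive),
cell counts per section are Poisson, marker co-labeling is Bernoulli per
marker, and ISH-like images are a constant background plus Gaussian
pixel noise with a rectangular signal region of known amplitude.

Randomness is hierarchical: one global seed spawns per-embryo, then
per-section streams, so adding embryos or sections never perturbs
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from cordmapper.errors import ConfigError
from cordmapper.geometry import polar_from_normalized

TRUNCATION_BOUND = 1.05  # positions are resampled until inside [0, bound]^2
MAX_REJECTION_ATTEMPTS = 1000

DEFAULT_LEVELS = ("brachial", "thoracic", "lumbar")
DEFAULT_N_EMBRYOS = 3
DEFAULT_SECTIONS_PER_LEVEL = 5


@dataclass(frozen=True)
class ClusterSpec:
    """One Gaussian component of a population's position mixture."""

    weight: float
    mean: tuple[float, float]  # (dv, ml) in [0, 1]^2
    cov: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if not (0 < self.weight <= 1):
            raise ConfigError(f"cluster weight must be in (0, 1], got {self.weight}")
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ConfigError("cluster covariance must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ConfigError("cluster covariance must be positive-definite")

    def shifted(self, delta: tuple[float, float]) -> "ClusterSpec":
        mean = (self.mean[0] + delta[0], self.mean[1] + delta[1])
        if not all(0 <= m <= TRUNCATION_BOUND for m in mean):
            raise ConfigError(
                f"shifted cluster mean {mean} falls outside [0, {TRUNCATION_BOUND}]^2"
            )
        return ClusterSpec(weight=self.weight, mean=mean, cov=self.cov)


@dataclass
class SyntheticTruth:
    """Generating parameters retained alongside simulated data.

    ``clusters`` maps population label -> list of ClusterSpec (weights
    summing to 1).  Geometry: H ~ LogNormal(log_H_median, sigma_log),
    W likewise, in one arbitrary length unit.  ``colabel_probs`` maps
    secondary marker -> per-cell Bernoulli probability of carrying it in
    addition to the population's defining marker.
    """

    clusters: dict[str, list[ClusterSpec]]
    population_markers: dict[str, str] = field(default_factory=dict)
    colabel_probs: dict[str, float] = field(default_factory=dict)
    cells_per_section: float = 40.0  # Poisson mean
    H_median: float = 200.0
    W_median: float = 100.0
    sigma_log: float = 0.08
    group: str = "control"
    stage: str = "e12.5"
    # ISH intensity model, arbitrary units
    background_level: float = 40.0
    signal_amplitude: float = 60.0
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        for pop, specs in self.clusters.items():
            total = sum(s.weight for s in specs)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(
                    f"population {pop!r}: cluster weights sum to {total}, not 1"
                )
        for name, val in (("cells_per_section", self.cells_per_section),
                          ("H_median", self.H_median), ("W_median", self.W_median),
                          ("sigma_log", self.sigma_log),
                          ("background_level", self.background_level),
                          ("signal_amplitude", self.signal_amplitude)):
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clusters"] = {
            pop: [{"weight": s.weight, "mean": list(s.mean),
                   "cov": [list(r) for r in s.cov]} for s in specs]
            for pop, specs in self.clusters.items()
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d["clusters"] = {
            pop: [ClusterSpec(weight=s["weight"], mean=tuple(s["mean"]),
                              cov=tuple(tuple(r) for r in s["cov"]))
                  for s in specs]
            for pop, specs in d["clusters"].items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticTruth":
        return cls.from_dict(yaml.safe_load(text))

    def with_group(self, group: str) -> "SyntheticTruth":
        d = self.to_dict()
        d["group"] = group
        return SyntheticTruth.from_dict(d)


def _cov(s_dv: float, s_ml: float, rho: float = 0.0) -> tuple:
    c = rho * s_dv * s_ml
    return ((s_dv**2, c), (c, s_ml**2))


#: Stylized per-population scenarios encoding qualitative anatomy
#: (a dorso-medial stream plus a ventral cluster for dI2; one
#: intermediate cluster for dI3; medial major + lateral minor for dI5;
#: a ventro-medial cluster for dI6).  These are editable scenarios for
#: simulation studies, not reconstructions of any measured data.
PRESETS: dict[str, dict[str, list[ClusterSpec]]] = {
    "dI2_default": {
        "dI2": [
            ClusterSpec(0.65, (0.75, 0.35), _cov(0.07, 0.06)),
            ClusterSpec(0.35, (0.30, 0.30), _cov(0.06, 0.06)),
        ]
    },
    "dI3_default": {
        "dI3": [ClusterSpec(1.0, (0.55, 0.40), _cov(0.08, 0.07))]
    },
    "dI5_default": {
        "dI5": [
            ClusterSpec(0.7, (0.60, 0.30), _cov(0.07, 0.05)),
            ClusterSpec(0.3, (0.55, 0.70), _cov(0.05, 0.05)),
        ]
    },
    "dI6_default": {
        "dI6": [ClusterSpec(1.0, (0.25, 0.25), _cov(0.06, 0.05))]
    },
}

POPULATION_MARKERS = {"dI2": "Foxd3", "dI3": "Isl1", "dI5": "Lmx1b", "dI6": "Wt1"}


def preset_truth(name: str = "dI2_default", **overrides) -> SyntheticTruth:
    """Build a SyntheticTruth from a named cluster preset."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    clusters = PRESETS[name]
    markers = {p: POPULATION_MARKERS.get(p, p) for p in clusters}
    kw = dict(clusters=clusters, population_markers=markers,
              colabel_probs={"Pou2f2": 0.3})
    kw.update(overrides)
    return SyntheticTruth(**kw)


def _sample_mixture(
    specs: list[ClusterSpec], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n truncated mixture points; returns (positions, component index)."""
    weights = np.array([s.weight for s in specs])
    comp = rng.choice(len(specs), size=n, p=weights)
    out = np.empty((n, 2))
    for i, k in enumerate(comp):
        spec = specs[k]
        for _ in range(MAX_REJECTION_ATTEMPTS):
            x = rng.multivariate_normal(spec.mean, np.asarray(spec.cov))
            if 0 <= x[0] <= TRUNCATION_BOUND and 0 <= x[1] <= TRUNCATION_BOUND:
                out[i] = x
                break
        else:
            raise ConfigError(
                f"rejection sampling failed for cluster mean {spec.mean}; "
                "covariance too wide for the truncation bound"
            )
    return out, comp


def simulate_dataset(
    truth: SyntheticTruth,
    n_embryos: int = DEFAULT_N_EMBRYOS,
    sections_per_level: int = DEFAULT_SECTIONS_PER_LEVEL,
    seed: int = 0,
    levels: tuple[str, ...] = DEFAULT_LEVELS,
) -> dict:
    """Simulate a full dataset: sections, cells and counts tables.

    Returns ``{"sections": DataFrame, "cells": DataFrame,
    "counts": DataFrame, "truth": SyntheticTruth, "seed": int}``.
    The counts table is tallied from the cells table, so the two are
    consistent by construction.  Deterministic given (truth, seed).
    """
    if n_embryos < 1 or sections_per_level < 1:
        raise ConfigError("n_embryos and sections_per_level must be >= 1")
    root = np.random.SeedSequence(seed)
    embryo_seeds = root.spawn(n_embryos)
    sec_rows, cell_rows = [], []
    for e in range(n_embryos):
        embryo_id = f"{truth.group}_E{e + 1}"
        section_seeds = embryo_seeds[e].spawn(len(levels) * sections_per_level)
        si = 0
        for level in levels:
            for s in range(sections_per_level):
                rng = np.random.default_rng(section_seeds[si])
                si += 1
                section_id = f"{embryo_id}_{level}_S{s + 1}"
                H = float(truth.H_median * np.exp(rng.normal(0, truth.sigma_log)))
                W = float(truth.W_median * np.exp(rng.normal(0, truth.sigma_log)))
                sec_rows.append({
                    "section_id": section_id, "embryo_id": embryo_id,
                    "group": truth.group, "stage": truth.stage,
                    "axial_level": level, "side": "right",
                    "H": H, "W": W, "unit": "px",
                })
                for pop, specs in truth.clusters.items():
                    n_cells = int(rng.poisson(truth.cells_per_section))
                    if n_cells == 0:
                        continue
                    xy, _ = _sample_mixture(specs, n_cells, rng)
                    base_marker = truth.population_markers.get(pop, pop)
                    for c in range(n_cells):
                        dv, ml = float(xy[c, 0]), float(xy[c, 1])
                        D, alpha = polar_from_normalized(dv, ml, H, W)
                        markers = [base_marker]
                        for marker, prob in truth.colabel_probs.items():
                            if rng.random() < prob:
                                markers.append(marker)
                        cell_rows.append({
                            "cell_id": f"{section_id}_{pop}_c{c + 1}",
                            "section_id": section_id,
                            "population": pop,
                            "markers": ";".join(markers),
                            "D": D, "alpha_deg": alpha,
                            "true_dv": dv, "true_ml": ml,
                        })
    sections = pd.DataFrame(sec_rows)
    cells = pd.DataFrame(cell_rows)
    meta = sections[["section_id", "embryo_id", "group", "axial_level"]]
    if len(cells):
        counts = (
            cells.merge(meta, on="section_id")
            .groupby(["embryo_id", "group", "axial_level", "section_id", "population"])
            .size().rename("count").reset_index()
        )
    else:
        counts = pd.DataFrame(
            columns=["embryo_id", "group", "axial_level", "section_id",
                     "population", "count"]
        )
    return {"sections": sections, "cells": cells, "counts": counts,
            "truth": truth, "seed": seed}


def shifted_pair(
    truth: SyntheticTruth,
    delta: tuple[float, float],
    seed: int = 0,
    n_embryos: int = DEFAULT_N_EMBRYOS,
    sections_per_level: int = DEFAULT_SECTIONS_PER_LEVEL,
    levels: tuple[str, ...] = DEFAULT_LEVELS,
    group_a: str = "control",
    group_b: str = "mutant",
) -> dict:
    """Two datasets differing only by a translation of cluster means.

    Group B's clusters are group A's with means shifted by
    ``delta = (d_dv, d_ml)`` (re-validated against the truncation
    bound); everything else is shared.  Returns ``{"a": dataset,
    "b": dataset, "delta": delta}`` with independent random streams.
    """
    if not all(np.isfinite(delta)):
        raise ConfigError("delta must be finite")
    truth_a = truth.with_group(group_a)
    d_b = truth.to_dict()
    d_b["group"] = group_b
    truth_b = SyntheticTruth.from_dict(d_b)
    truth_b.clusters = {
        pop: [s.shifted(delta) for s in specs]
        for pop, specs in truth.clusters.items()
    }
    root = np.random.SeedSequence(seed)
    sa, sb = root.spawn(2)
    ds_a = simulate_dataset(truth_a, n_embryos, sections_per_level,
                            seed=sa.generate_state(1)[0] % (2**31), levels=levels)
    ds_b = simulate_dataset(truth_b, n_embryos, sections_per_level,
                            seed=sb.generate_state(1)[0] % (2**31), levels=levels)
    return {"a": ds_a, "b": ds_b, "delta": tuple(delta)}


def simulate_intensity_image(
    truth: SyntheticTruth,
    condition_fold: float = 1.0,
    shape: tuple[int, int] = (256, 320),
    seed: int = 0,
    roi_area: int = 13_500,
) -> dict:
    """ISH-like image: noisy constant background plus a rectangular
    signal region of amplitude signal_amplitude * condition_fold.

    Returns the image, the signal ROI, an adjacent background ROI (both
    (row0, row1, col0, col1), 0-based half-open) and the true net value.
    The signal ROI has the configured fixed area (135 x ceil(area/135)).
    """
    if condition_fold <= 0:
        raise ConfigError("condition_fold must be positive")
    rows = 135
    cols = int(math.ceil(roi_area / rows))
    if rows + 10 > shape[0] or 2 * cols + 30 > shape[1]:
        raise ConfigError(
            f"image shape {shape} cannot contain the {roi_area} px^2 ROI "
            "plus an adjacent background ROI"
        )
    rng = np.random.default_rng(seed)
    img = truth.background_level + rng.normal(0, truth.noise_sd, size=shape)
    r0 = (shape[0] - rows) // 2
    roi = (r0, r0 + rows, 10, 10 + cols)
    amplitude = truth.signal_amplitude * condition_fold
    img[roi[0]:roi[1], roi[2]:roi[3]] += amplitude
    background_roi = (r0, r0 + rows, 20 + cols, 20 + 2 * cols)
    return {"image": img, "roi": roi, "background_roi": background_roi,
            "true_net": amplitude}


def calibration_study(
    test: str,
    truth: SyntheticTruth,
    n_reps: int = 2000,
    n_per_group: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
    shift: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Empirical rejection rate of a test under repeated simulation.

    ``test`` is "hotelling_F", "hotelling_perm" or "counts_auto".
    Groups are drawn from the first population's mixture; group B's
    means are translated by ``shift`` (the null is shift = (0, 0)).
    Returns the rejection rate with a 95% binomial (Wilson) interval.
    """
    from scipy import stats as st
    from cordmapper.spatial import hotelling_t2, hotelling_permutation_p
    from cordmapper.abundance import compare_counts

    if n_reps < 100:
        raise ConfigError("n_reps must be >= 100")
    pop = next(iter(truth.clusters))
    specs_a = truth.clusters[pop]
    specs_b = [s.shifted(shift) for s in specs_a] if shift != (0.0, 0.0) else specs_a
    root = np.random.SeedSequence(seed)
    rejections = 0
    for rep_seed in root.spawn(n_reps):
        rng = np.random.default_rng(rep_seed)
        xa, _ = _sample_mixture(specs_a, n_per_group, rng)
        xb, _ = _sample_mixture(specs_b, n_per_group, rng)
        if test == "hotelling_F":
            p = hotelling_t2(xa, xb).p_value
        elif test == "hotelling_perm":
            p = hotelling_permutation_p(
                xa, xb, n_perm=199,
                seed=int(rng.integers(2**31)),
            )
        elif test == "counts_auto":
            p = compare_counts(xa[:, 0], xb[:, 0], method="auto").p_value
        else:
            raise ConfigError(f"unknown test {test!r}")
        if p <= alpha:
            rejections += 1
    rate = rejections / n_reps
    lo, hi = st.binomtest(rejections, n_reps).proportion_ci(method="wilson")
    return {"test": test, "n_reps": n_reps, "n_per_group": n_per_group,
            "alpha": alpha, "shift": list(shift), "rejection_rate": rate,
            "ci_low": float(lo), "ci_high": float(hi), "seed": seed}
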