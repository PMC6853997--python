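"""Two-sample comparison of 2D soma-position distributions.

The core statistic is the two-sample Hotelling T², the two-dimensional
generalization of Student's t.  For samples of sizes n1, n2 with means
x̄a, x̄b and pooled unbiased covariance S,

    T² = (n1 n2 / (n1 + n2)) (x̄a - x̄b)' S⁻¹ (x̄a - x̄b)
    F  = T² (n1 + n2 - p - 1) / (p (n1 + n2 - 2))   ~  F(p, n1+n2-p-1)

under multivariate normality with common covariance.  A label-permutation
companion provides an assumption-free p-value.  Density profiling uses a
Gaussian kernel with Silverman's rule bandwidth 1.06 σ̂ n^(-1/5) per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
from scipy import stats

from cordmapper.errors import DegenerateDataError
from cordmapper.geometry import PopulationSample

ArrayLike = Union[np.ndarray, PopulationSample]

#: covariance condition numbers above this are treated as singular
COND_LIMIT = 1e12


def _as_xy(sample: ArrayLike) -> np.ndarray:
    if isinstance(sample, PopulationSample):
        return sample.xy()
    xy = np.asarray(sample, dtype=float)
    if xy.ndim != 2:
        raise ValueError("expected an (n, d) array of positions")
    return xy


@dataclass
class HotellingResult:
    """Outcome of a two-sample Hotelling T² test."""

    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    mean_a: np.ndarray
    mean_b: np.ndarray
    pooled_cov: np.ndarray
    n1: int
    n2: int

    @property
    def centroid_shift(self) -> np.ndarray:
        """mean_b - mean_a, the estimated displacement of group b."""
        return self.mean_b - self.mean_a

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("mean_a", "mean_b", "pooled_cov"):
            d[k] = np.asarray(d[k]).tolist()
        d["centroid_shift"] = self.centroid_shift.tolist()
        return d


def hotelling_t2(a: ArrayLike, b: ArrayLike) -> HotellingResult:
    """Two-sample Hotelling T² with the classical F approximation.

    Requires n1, n2 >= 3 and n1 + n2 >= p + 2 so the F denominator
    degrees of freedom are positive.  Raises
    :class:`~cordmapper.errors.DegenerateDataError` when the pooled
    covariance is singular or near-singular (condition number > 1e12)
    rather than silently pseudo-inverting.
    """
    xa, xb = _as_xy(a), _as_xy(b)
    n1, n2 = len(xa), len(xb)
    p = xa.shape[1]
    if xb.shape[1] != p:
        raise ValueError("samples have different dimensions")
    if n1 < 3 or n2 < 3 or n1 + n2 < p + 2:
        raise DegenerateDataError(
            f"sample sizes too small for Hotelling T2 (n1={n1}, n2={n2}, p={p})"
        )
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    Sa = np.cov(xa, rowvar=False, ddof=1).reshape(p, p)
    Sb = np.cov(xb, rowvar=False, ddof=1).reshape(p, p)
    S = ((n1 - 1) * Sa + (n2 - 1) * Sb) / (n1 + n2 - 2)
    if np.linalg.cond(S) > COND_LIMIT:
        raise DegenerateDataError(
            "pooled covariance is singular or near-singular; the samples do "
            "not span both coordinates"
        )
    diff = ma - mb
    t2 = float(n1 * n2 / (n1 + n2) * diff @ np.linalg.solve(S, diff))
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return HotellingResult(
        t2=t2, f_stat=float(f_stat), df1=df1, df2=df2, p_value=p_value,
        mean_a=ma, mean_b=mb, pooled_cov=S, n1=n1, n2=n2,
    )


def _t2_statistic(x: np.ndarray, labels: np.ndarray) -> float:
    """T² for a given 0/1 label split of pooled positions (permutation core)."""
    xa, xb = x[labels == 0], x[labels == 1]
    n1, n2 = len(xa), len(xb)
    p = x.shape[1]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    Sa = np.cov(xa, rowvar=False, ddof=1).reshape(p, p)
    Sb = np.cov(xb, rowvar=False, ddof=1).reshape(p, p)
    S = ((n1 - 1) * Sa + (n2 - 1) * Sb) / (n1 + n2 - 2)
    diff = ma - mb
    return float(n1 * n2 / (n1 + n2) * diff @ np.linalg.solve(S, diff))


def hotelling_permutation_p(
    a: ArrayLike, b: ArrayLike, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for the T² statistic.

    Group labels are permuted over the pooled cells; the add-one
    estimator p = (1 + #{T²_perm >= T²_obs}) / (1 + n_perm) never
    returns zero.  Deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    xa, xb = _as_xy(a), _as_xy(b)
    obs = hotelling_t2(xa, xb).t2  # validates sizes / covariance
    pooled = np.vstack([xa, xb])
    labels = np.concatenate([np.zeros(len(xa), int), np.ones(len(xb), int)])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            t2p = _t2_statistic(pooled, perm)
        except np.linalg.LinAlgError:
            t2p = np.inf  # degenerate split counts against the observed value
        if t2p >= obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


@dataclass
class DensityProfile:
    """1D Gaussian-KDE density along the DV or ML axis."""

    axis: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_cells: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class DensityMap2D:
    """2D Gaussian-KDE density over the (dv, ml) unit hemicord."""

    dv_grid: np.ndarray
    ml_grid: np.ndarray
    density: np.ndarray  # shape (len(dv_grid), len(ml_grid))
    bandwidth: tuple[float, float]
    n_cells: int

    def integral(self) -> float:
        inner = np.trapezoid(self.density, self.ml_grid, axis=1)
        return float(np.trapezoid(inner, self.dv_grid))

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.dv_grid[i]), float(self.ml_grid[j])

    def marginal(self, axis: str) -> DensityProfile:
        """Integrate out the other coordinate; comparable to the 1D profile."""
        if axis == "DV":
            dens = np.trapezoid(self.density, self.ml_grid, axis=1)
            grid, bw = self.dv_grid, self.bandwidth[0]
        elif axis == "ML":
            dens = np.trapezoid(self.density, self.dv_grid, axis=0)
            grid, bw = self.ml_grid, self.bandwidth[1]
        else:
            raise ValueError("axis must be 'DV' or 'ML'")
        return DensityProfile(axis=axis, grid=grid, density=dens,
                              bandwidth=bw, n_cells=self.n_cells)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 1.06 sigma-hat n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sigma = x.std(ddof=1)
    return 1.06 * sigma * len(x) ** (-0.2)


def _axis_values(sample: ArrayLike, axis: str) -> np.ndarray:
    xy = _as_xy(sample)
    if axis == "DV":
        return xy[:, 0]
    if axis == "ML":
        return xy[:, 1]
    raise ValueError("axis must be 'DV' or 'ML'")


def density_profile(
    sample: ArrayLike,
    axis: str = "DV",
    bandwidth: float | str = "auto",
    grid_size: int = 256,
) -> DensityProfile:
    """Gaussian kernel density estimate of one coordinate.

    The evaluation grid spans [min - 3h, max + 3h] and always covers
    [0, 1], so the trapezoidal integral of the returned density is ~1
    (it is never clipped at the anatomical boundary).
    """
    x = _axis_values(sample, axis)
    if len(x) < 2:
        raise DegenerateDataError("density_profile needs at least 2 cells")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"zero variance on the {axis} axis")
    h = silverman_bandwidth(x) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    lo = min(x.min() - 3 * h, 0.0)
    hi = max(x.max() + 3 * h, 1.0)
    grid = np.linspace(lo, hi, grid_size)
    # vectorized kernel sum: (grid, n)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))
    return DensityProfile(axis=axis, grid=grid, density=dens, bandwidth=h,
                          n_cells=len(x))


def density_map_2d(
    sample: ArrayLike,
    grid_size: int = 128,
    bandwidth: float | str | tuple[float, float] = "auto",
) -> DensityMap2D:
    """2D KDE with a diagonal-bandwidth Gaussian kernel (per-axis Silverman)."""
    xy = _as_xy(sample)
    if len(xy) < 2:
        raise DegenerateDataError("density_map_2d needs at least 2 cells")
    dv, ml = xy[:, 0], xy[:, 1]
    if np.ptp(dv) == 0 or np.ptp(ml) == 0:
        raise DegenerateDataError("zero variance on one axis")
    if bandwidth == "auto":
        h = (silverman_bandwidth(dv), silverman_bandwidth(ml))
    elif np.isscalar(bandwidth):
        h = (float(bandwidth), float(bandwidth))
    else:
        h = (float(bandwidth[0]), float(bandwidth[1]))
    if h[0] <= 0 or h[1] <= 0:
        raise ValueError("bandwidth must be positive")
    dv_grid = np.linspace(min(dv.min() - 3 * h[0], 0.0), max(dv.max() + 3 * h[0], 1.0), grid_size)
    ml_grid = np.linspace(min(ml.min() - 3 * h[1], 0.0), max(ml.max() + 3 * h[1], 1.0), grid_size)
    zd = (dv_grid[:, None] - dv[None, :]) / h[0]
    zm = (ml_grid[:, None] - ml[None, :]) / h[1]
    kd = np.exp(-0.5 * zd**2)  # (grid, n)
    km = np.exp(-0.5 * zm**2)
    dens = kd @ km.T / (len(dv) * h[0] * h[1] * 2 * np.pi)
    return DensityMap2D(dv_grid=dv_grid, ml_grid=ml_grid, density=dens,
                        bandwidth=h, n_cells=len(dv))


@dataclass
class ComparisonReport:
    """Bundle of everything one two-group spatial comparison produces."""

    population: str
    axial_level: str
    group_a: str
    group_b: str
    test: HotellingResult
    permutation_p: float | None
    profiles: dict  # {"DV": {"a": DensityProfile, "b": ...}, "ML": {...}}
    maps: dict | None  # {"a": DensityMap2D, "b": DensityMap2D}
    alpha: float
    significant: bool
    n_outliers: tuple[int, int]
    pseudoreplication_note: str = (
        "cells pooled across sections and embryos are treated as independent "
        "observations; n_sections/n_embryos are reported for context"
    )
    n_sections: tuple[int, int] = (0, 0)
    n_embryos: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        d = {
            "population": self.population,
            "axial_level": self.axial_level,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "test": self.test.to_dict(),
            "permutation_p": self.permutation_p,
            "alpha": self.alpha,
            "significant": self.significant,
            "n_outliers": list(self.n_outliers),
            "n_sections": list(self.n_sections),
            "n_embryos": list(self.n_embryos),
            "pseudoreplication_note": self.pseudoreplication_note,
            "profiles": {
                ax: {
                    g: {
                        "grid": pr.grid.tolist(),
                        "density": pr.density.tolist(),
                        "bandwidth": pr.bandwidth,
                        "n_cells": pr.n_cells,
                    }
                    for g, pr in by_group.items()
                }
                for ax, by_group in self.profiles.items()
            },
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @staticmethod
    def from_json(text: str) -> dict:
        return json.loads(text)


def compare_distributions(
    a: PopulationSample,
    b: PopulationSample,
    alpha: float = 0.05,
    bandwidth: float | str = "auto",
    grid_size: int = 256,
    permutations: int = 0,
    seed: int = 0,
    with_maps: bool = False,
) -> ComparisonReport:
    """Full spatial comparison of two pooled samples.

    Runs the Hotelling T² test (plus an optional permutation companion),
    builds 1D density profiles for both groups on both axes, optionally
    2D maps, and issues a significance verdict at ``alpha`` (default
    0.05, two-sided F upper tail).
    """
    if isinstance(a, PopulationSample) and isinstance(b, PopulationSample):
        if a.population != b.population or a.axial_level != b.axial_level:
            raise ValueError(
                "compare_distributions expects samples of the same population "
                f"and axial level, got {a.population}/{a.axial_level} vs "
                f"{b.population}/{b.axial_level}"
            )
    res = hotelling_t2(a, b)
    perm_p = (
        hotelling_permutation_p(a, b, n_perm=permutations, seed=seed)
        if permutations else None
    )
    profiles = {
        ax: {
            "a": density_profile(a, axis=ax, bandwidth=bandwidth, grid_size=grid_size),
            "b": density_profile(b, axis=ax, bandwidth=bandwidth, grid_size=grid_size),
        }
        for ax in ("DV", "ML")
    }
    maps = None
    if with_maps:
        maps = {
            "a": density_map_2d(a, grid_size=min(grid_size, 128), bandwidth=bandwidth),
            "b": density_map_2d(b, grid_size=min(grid_size, 128), bandwidth=bandwidth),
        }
    return ComparisonReport(
        population=a.population,
        axial_level=a.axial_level,
        group_a=a.group,
        group_b=b.group,
        test=res,
        permutation_p=perm_p,
        profiles=profiles,
        maps=maps,
        alpha=alpha,
        significant=bool(res.p_value <= alpha),
        n_outliers=(a.n_outliers, b.n_outliers),
        n_sections=(a.n_sections, b.n_sections),
        n_embryos=(a.n_embryos, b.n_embryos),
    )
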