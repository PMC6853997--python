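"""Figure export: 2D scatter + density panels and overlaid 1D profiles.

Two-color convention: group A blue, group B red.  Figures are optional
side outputs; every number they show also appears in the JSON report.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from cordmapper.geometry import PopulationSample  # noqa: E402
from cordmapper.spatial import density_map_2d, density_profile  # noqa: E402

COLOR_A, COLOR_B = "tab:blue", "tab:red"


def plot_comparison(
    a: PopulationSample,
    b: PopulationSample,
    path: str | Path,
    bandwidth: float | str = "auto",
    grid_size: int = 128,
) -> Path:
    """Four-panel figure: per-group 2D scatter over density, and DV/ML
    1D density overlays.  Returns the written path (PNG or SVG by
    extension)."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, sample, color, label in (
        (axes[0, 0], a, COLOR_A, a.group),
        (axes[0, 1], b, COLOR_B, b.group),
    ):
        m = density_map_2d(sample, grid_size=grid_size, bandwidth=bandwidth)
        ax.contourf(m.ml_grid, m.dv_grid, m.density, levels=12, cmap="Greys")
        xy = sample.xy()
        ax.scatter(xy[:, 1], xy[:, 0], s=4, color=color, alpha=0.5)
        ax.set_xlim(0, 1.05)
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("ML position")
        ax.set_ylabel("DV position")
        ax.set_title(f"{sample.population} {label} (n={sample.n_cells})")
    for ax, axis in ((axes[1, 0], "DV"), (axes[1, 1], "ML")):
        for sample, color, label in ((a, COLOR_A, a.group), (b, COLOR_B, b.group)):
            pr = density_profile(sample, axis=axis, bandwidth=bandwidth)
            ax.plot(pr.grid, pr.density, color=color, label=label)
        ax.set_xlabel(f"{axis} position")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
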