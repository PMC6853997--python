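"""Axis-wise density profiles and a 2D density map of one population.

Simulates a dI2-like dataset (dorso-medial stream plus ventral cluster),
builds Gaussian-KDE profiles on each axis and a 2D map, and reports the
modes and integrals.  The profiles are what two-group overlay figures
are built from.
"""

from cordmapper import (
    density_map_2d,
    density_profile,
    normalize_table,
    pool_samples,
    preset_truth,
    simulate_dataset,
)

truth = preset_truth("dI2_default")
ds = simulate_dataset(truth, n_embryos=3, sections_per_level=5, seed=42)
norm = normalize_table(ds["cells"].drop(columns=["true_dv", "true_ml"]),
                       ds["sections"])
samples = {s.axial_level: s for s in pool_samples(norm)}
sample = samples["thoracic"]
print(f"thoracic sample: {sample.n_cells} cells from {sample.n_sections} "
      f"sections of {sample.n_embryos} embryos")

for axis in ("DV", "ML"):
    pr = density_profile(sample, axis=axis, bandwidth="auto", grid_size=256)
    print(f"{axis}: Silverman bandwidth {pr.bandwidth:.4f}, "
          f"mode at {pr.mode():.3f}, integral {pr.integral():.4f}")

m = density_map_2d(sample, grid_size=128)
peak = m.argmax()
print(f"2D map peak at (dv, ml) = ({peak[0]:.3f}, {peak[1]:.3f}), "
      f"integral {m.integral():.4f}")
print("\nThe DV mode sits near the dominant dorso-medial cluster (dv ~0.75); "
      "integrals ~1 confirm the estimates are proper densities.")
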