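"""Detect a simulated ventral shift with the two-sample Hotelling T2 test.

Simulates a control/mutant pair whose only difference is a -0.1 shift of
every cluster mean along DV, normalizes both, and runs the full spatial
comparison.  The test should flag the difference and the centroid shift
should estimate (-0.1, 0).
"""

from cordmapper import (
    compare_distributions,
    normalize_table,
    pool_samples,
    preset_truth,
    shifted_pair,
)

truth = preset_truth("dI3_default", cells_per_section=50)
pair = shifted_pair(truth, delta=(-0.1, 0.0), seed=7, n_embryos=3,
                    sections_per_level=5, levels=("thoracic",))

samples = {}
for label, ds in (("a", pair["a"]), ("b", pair["b"])):
    norm = normalize_table(ds["cells"].drop(columns=["true_dv", "true_ml"]),
                           ds["sections"])
    (samples[label],) = pool_samples(norm)

rep = compare_distributions(samples["a"], samples["b"], permutations=999, seed=1)
t = rep.test
print(f"n = {t.n1} control vs {t.n2} mutant cells")
print(f"T2 = {t.t2:.2f}, F({t.df1},{t.df2}) = {t.f_stat:.2f}, "
      f"p = {t.p_value:.3g} (permutation p = {rep.permutation_p:.3g})")
print(f"centroid shift (dv, ml) = ({t.centroid_shift[0]:+.3f}, "
      f"{t.centroid_shift[1]:+.3f})  [true: (-0.100, +0.000)]")
print(f"verdict at alpha={rep.alpha}: "
      f"{'significant' if rep.significant else 'not significant'}")
print("\nThe shift estimate recovers the simulated ventral displacement; "
      "the permutation p-value corroborates the F approximation.")
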