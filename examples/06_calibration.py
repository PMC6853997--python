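"""Type-I error and power of the Hotelling F-approximation test.

Runs the built-in calibration study under the simulated null (no shift)
and under a fixed DV shift, and compares the empirical power with the
noncentral-F analytic value.
"""

import numpy as np
from scipy import stats

from cordmapper import calibration_study, preset_truth

truth = preset_truth("dI3_default")
n = 30

null = calibration_study("hotelling_F", truth, n_reps=1000, n_per_group=n, seed=7)
print(f"null rejection rate at alpha=0.05: {null['rejection_rate']:.3f} "
      f"(95% CI {null['ci_low']:.3f}-{null['ci_high']:.3f}; nominal 0.050)")

shift = (0.06, 0.0)
power = calibration_study("hotelling_F", truth, n_reps=1000, n_per_group=n,
                          seed=8, shift=shift)
cov = np.diag([0.08**2, 0.07**2])
lam = (n / 2) * np.array(shift) @ np.linalg.solve(cov, np.array(shift))
analytic = stats.ncf.sf(stats.f.isf(0.05, 2, 2 * n - 3), 2, 2 * n - 3, lam)
print(f"power under a 0.06 DV shift: empirical {power['rejection_rate']:.3f}, "
      f"noncentral-F analytic {analytic:.3f}")
print("\nA well-calibrated test rejects ~5% of true nulls and matches the "
      "analytic power curve under the alternative.")
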