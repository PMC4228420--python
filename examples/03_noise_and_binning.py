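"""Noise versus processing resolution.

Adds 20% baseline Gaussian noise to the phantom and fits one patch at
three resolutions.  Averaging k x k pixels divides the noise sigma by k
(20% -> 10% at 2x2 -> 2% at 10x10), which shows up directly in the spread
of the fitted Ktrans values.
"""

import numpy as np

import dcepk as d

spec = d.default_tofts_spec(noise_sigma_fraction=0.2, seed=42)
series, truth = d.generate(spec)
relax = d.RelaxationParams(spec.r1, spec.T10_tissue)

# the Ktrans = 0.1 / ve = 0.2 patch (row 3, col 3 of the grid)
mask = np.zeros_like(truth.tissue_mask)
mask[30:40, 30:40] = True

print("patch truth: Ktrans = 0.1 1/min, ve = 0.2; noise sigma = 20% baseline")
for k in (1, 2, 10):
    pm = d.fit_roi(series, d.ROI(0, mask, bin_factor=k), "tofts",
                   relax=relax, aif=spec.aif)
    stats = d.roi_statistics(pm)
    kt = stats["Ktrans"]
    print(f"  {k:2d}x{k:<2d} cells={kt['n']:3d}  effective sigma {20 / k:4.1f}%  "
          f"Ktrans = {kt['mean']:.4f} +/- {kt['sd']:.4f} 1/min")
# The mean stays on target while the cell-to-cell SD shrinks roughly as
# 1/k — the reason coarse maps are used for noisy preclinical data.
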