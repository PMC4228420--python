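"""Model-free analysis: RCE, IAUC and TTM maps.

These need no model, AIF, or calibration constants — only the curve shape
— and are the first look at any dynamic study.
"""

import numpy as np

import dcepk as d

spec = d.default_tofts_spec()
series, truth = d.generate(spec)

pm = d.semiquant_map(series, d.ROI(0, truth.tissue_mask, bin_factor=10),
                     relax=d.RelaxationParams(spec.r1, spec.T10_tissue),
                     window=60.0)

print("patch-level RCE (%), rows = ve ascending, cols = Ktrans ascending:")
print(np.array2string(pm["RCE"], precision=1, suppress_small=True))
print("\nIAUC60 (mM*s):")
print(np.array2string(pm["IAUC"], precision=2, suppress_small=True))
print("\nTTM (s):")
print(np.array2string(pm["TTM"], precision=0))
# RCE grows along each row (more transfer -> more enhancement) and IAUC
# with it; TTM shortens as washout (kep = Ktrans/ve) accelerates, which is
# why the low-ve rows peak earliest.
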