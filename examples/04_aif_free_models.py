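"""Models that avoid arterial input function measurement.

Preclinical studies often cannot sample blood: the Hoffmann model works on
the raw signal enhancement and the reference-region model replaces the AIF
with a second, well-characterised tissue.  Both are demonstrated on
synthetic curves with known truth.
"""

import numpy as np

import dcepk as d
from dcepk.fitting import _model_spec, fit_curve

aif = d.default_population_aif(D=0.2)

# --- Hoffmann: signal-domain fit, parameters (A_H, kep, kel) -------------
t = np.linspace(-1.0, 15.0, 320)                  # minutes since injection
truth = d.HoffmannParams(A_H=1.0, kep=1.0, kel=0.1)
y = d.hoffmann_signal(truth, 100.0, t)
names, init, lo, hi, _, factory = _model_spec("hoffmann")
res = fit_curve(factory(100.0), t, y, names, init, lo, hi)
print("Hoffmann fit (truth A_H=1, kep=1, kel=0.1 1/min):")
for n in names:
    print(f"  {n:4s} = {res.params[n]:.6f} +/- {res.stderr[n]:.2e}")

# --- reference region: concentration-domain, AIF eliminated --------------
tt = np.arange(0, 600, 1.0) / 60.0
ct_tissue = d.tofts_ct_analytic(d.ToftsParams(0.25, 0.4), aif, tt)
ct_ref = d.tofts_ct_analytic(d.ToftsParams(0.1, 0.1), aif, tt)
out = d.rr_ct(d.RRParams(0.25, 0.4, 0.1, 0.1), ct_ref, tt)
err = np.max(np.abs(out[60:] - ct_tissue[60:]) / ct_tissue[60:])
print("\nreference-region reconstruction of the tissue curve:")
print(f"  tissue (Ktrans=0.25, ve=0.4) from reference (0.1, 0.1)")
print(f"  max relative error after 1 min: {err:.2e}")
# kep = Ktrans/ve is the washout rate; in rodent tumours it typically falls
# between ~0.3 and ~1.5 1/min, so these synthetic values are realistic.
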