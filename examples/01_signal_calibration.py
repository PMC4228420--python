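"""Convert an MR signal curve to gadolinium concentration and back.

Builds a known concentration level, pushes it through the SPGR signal
equation, then inverts the measured signal with only the baseline, TR,
flip angle, r1 and T10 — the situation in a real study.
"""

import dcepk as d

relax = d.RelaxationParams(r1=4.5, T10=1000.0)     # 1/(s mM), ms
acq = d.AcquisitionParams("spgr", TR=5.0, flip_angle=30.0,
                          frame_interval=0.5, injection_frame=1)

Ct_true = 0.5                                       # mM
T1 = d.t1_from_concentration(Ct_true, relax)
S_base = d.spgr_signal(1000.0, 1000.0, 5.0, 30.0)   # pre-contrast signal
S_t = d.spgr_signal(1000.0, T1, 5.0, 30.0)          # post-contrast signal

Ct_est, invalid = d.concentration_from_spgr(S_t, S_base, acq, relax)

print(f"true concentration : {Ct_true:.6f} mM")
print(f"T1 at that level   : {T1:.2f} ms   (T10 was 1000 ms)")
print(f"signal base -> post: {S_base:.3f} -> {S_t:.3f} a.u.")
print(f"recovered          : {Ct_est:.6f} mM  (invalid={invalid})")
# The inversion is exact: 0.5 mM shortens T1 to ~308 ms, raising the SPGR
# signal; recovering 0.500000 mM confirms the calibration chain is lossless.
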