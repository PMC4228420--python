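# Methods

## Compartmental model

All quantitative models here derive from the open two-compartment
description of low-molecular-weight gadolinium kinetics: the agent is
injected into blood plasma (central compartment, with renal elimination),
leaks across the capillary endothelium into the extravascular-
extracellular space (EES), and cannot enter cells. First-order exchange
gives

    dCe/dt = (Ktrans/ve)·(Cp − Ce),    Ct = vp·Cp + ve·Ce

with `Ktrans` (min⁻¹) the plasma↔EES volume transfer constant, `ve` and
`vp` the EES and plasma volume fractions, and `kep = Ktrans/ve` the
washout rate. `Ktrans` conflates flow and permeability; unless tissue
physiology is known its interpretation is left open. For an instantaneous
bolus and a bi-exponential plasma curve `Cp(t) = D·Σ aᵢ·e^(−mᵢ·t)` the
standard-model solution is the closed form

    Ct(t) = D·Ktrans·Σ aᵢ·(e^(−kep·t) − e^(−mᵢ·t))/(mᵢ − kep),

used whenever the AIF is parametric; for sampled AIFs the convolution
`Ct = Cp ∗ Ktrans·e^(−kep·t)` is evaluated numerically (below). The
extended model adds `vp·Cp(t)`. The Hoffmann and Larsson models work in
the signal domain (no calibration): Hoffmann's three parameters are an
EES-size-like amplitude `A_H`, `kep`, and the elimination constant `kel`;
Larsson's amplitude is the initial signal slope `Ṡ(0)`, normalised so the
model's derivative at t = 0⁺ equals it exactly. The reference-region
model eliminates `Cp` by combining the tissue equation with that of a
reference tissue of known `(Ktrans,r, ve,r)`; its algebra satisfies the
identity `Ct ≡ Ct,r` when tissue equals reference, which the test suite
uses as the disambiguating check of the implemented grouping.

## Signal model and calibration

The agent shortens T1 via `1/T1(t) = 1/T10 + r1·Ct(t)` (`r1` in
s⁻¹·mM⁻¹; BMS shift and T2*/echo-time effects neglected — short-TE
assumption). Forward signals: spin echo `S = S0·(1 − e^(−TR/T1))`; SPGR
`S = S0·(1 − E)·sinα/(1 − E·cosα)`, `E = e^(−TR/T1)`. Both inversions
are algebraically exact on the valid range and are written in terms of
the *measured pre-injection baseline* (mean of the frames before the
injection frame — the variance-minimising estimator), never the
unobservable equilibrium amplitude; for SPGR the needed product
`S0_eq·sinα` is recovered from the baseline as
`S0_base·(1 − m·cosα)/(1 − m)`, `m = e^(−TR/T10)`. Only the ratio
`TR/T1` enters any signal expression, so TR and T1 stay in ms throughout;
T10 is converted to seconds only where it meets `r1`. Calibration is
ratio-invariant: rescaling signal and baseline jointly changes nothing.

When noise pushes a sample outside the invertible range (log argument
≤ 0, SPGR fraction outside (0, 1)) the intermediate is clamped to the
edge of the valid interval with relative margin 1e-6 and the sample is
flagged; flags propagate to the parameter maps instead of NaNs
poisoning the pipeline.

T10 mapping from multi-TR spin echoes: two-point TR-ratio solved per
pixel by bracketed root finding on T1 ∈ (0, ∞) (the ratio is monotone),
or per-pixel least squares of `(S0, T10)` over ≥ 2 images. Ratios outside
the attainable range `(TR1/TR2, 1)` are flagged invalid. The solver and
starting values are this package's choice; the two-point bracket is
robust because the objective is monotone.

## Numerics

* **Convolution quadrature.** Product integration on the uniform frame
  grid: the input series is taken piecewise linear and integrated
  against `e^(−rate·t)` exactly per interval. The interval weights reduce
  to the ordinary trapezoid rule as `rate·Δt → 0`, but remain accurate
  at fast washout (`kep` up to 35 min⁻¹ on a 0.5 s grid, where a plain
  trapezoid errs by several tenths of a percent); the analytic-vs-numeric
  agreement bound of 0.1% over the full phantom grid is part of the test
  suite. The unrolled recursion is evaluated as a single FFT-free
  `np.convolve`, O(N²) worst case but a few hundred microseconds at
  N = 1200.
* **Removable singularities.** When an AIF rate coincides with `kep`
  (or `kel → kep` in the Hoffmann model) within 1e-8 min⁻¹, the
  closed-form limit branch `a·t·e^(−kep·t)` is used; continuity across
  the switch is property-tested.
* **Fitting.** Bounded least squares via SciPy's trust-region-reflective
  solver with MINPACK-style tolerances (ftol = xtol = gtol = 1e-8,
  200 iterations); rates bounded below by 0, fractions in (0, 1].
  Default starts: Ktrans 0.1 min⁻¹, ve 0.3, vp 0.02, A_H 1, kep 1 min⁻¹,
  kel 0.05 min⁻¹ — mid-range of the validation grids. Standard errors are
  `sqrt(diag(s²·(JᵀJ)⁻¹))` with `s²` the residual variance at the
  solution: 1-sigma values, reported only for converged cells.
  Unweighted residuals. Flat (no-enhancement) curves are reported as
  degenerate rather than fitted; NaN frames are dropped. Fitting contains
  no randomness; cells are independent, so maps are bit-reproducible and
  order-invariant.
* **Time conventions.** Frame times in seconds on the acquisition clock;
  model time is minutes since the injection instant
  (`frame_times[injection_frame]`); rate constants are reported in
  min⁻¹. Concentration models are identically zero at and before
  injection.
* **Binning.** k×k non-overlapping blocks (k = 1…10) anchored at the ROI
  bounding-box origin; a cell's curve is the unweighted mean of its
  masked member pixels, so i.i.d. pixel noise of σ scales to σ/k.

## Arterial input function

Default is the bi-exponential population model with the Weinmann/Tofts
literature constants a = (3.99, 4.78) kg/L, m = (0.144, 0.0111) min⁻¹
and dose D = 0.2 mmol/kg (a typical preclinical bolus); these are
configurable and explicitly population values, not fitted here. Sampled
AIFs (two-column text) are resampled to the frame grid by linear
interpolation, zero before the first sample, last value held after the
last; whole-blood measurements convert to plasma by `Cp = Cb/(1 − Hct)`.

## The synthetic phantom

The generator reproduces the published style of digital reference object
so the whole pipeline can be validated without downloads: a tissue region
tiled with 10×10 px patches, one per parameter combination, plus a
bottom vascular strip carrying the whole-blood signal at the blood T10.

* Single-compartment set: Ktrans ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.35}
  min⁻¹ × ve ∈ {0.01, 0.05, 0.1, 0.2, 0.5} → 30 patches on 50×60 px;
  SPGR, flip 30°, TR 5 ms, 0.5 s frames, 10 min study, injection at
  60 s; T10 tissue/blood 1000/1440 ms, hematocrit 0.45.
* Extended set: Ktrans ∈ {0, 0.01, 0.02, 0.05, 0.1, 0.2} min⁻¹ ×
  ve ∈ {0.1, 0.2, 0.5} × vp ∈ {0.001, 0.005, 0.01, 0.02, 0.05, 0.1}
  → 108 patches on a 180×60 px region (60 wide × 180 tall; the patch
  rows run ve-outer/vp-inner, columns Ktrans); flip 25°, 3.5 min study,
  injection at 5 s, 60×20 vascular strip.

Values not printed anywhere for these objects and therefore fixed here
once: relaxivity r1 = 4.5 s⁻¹·mM⁻¹ (typical Gd-DTPA at high field),
equilibrium amplitude 1000 a.u. (extended set 250, echoing its coarser
discretization), vascular strip height 10 rows for the single-compartment
object, and the population AIF above used identically for synthesis and
fitting — recovery conclusions are therefore independent of the true AIF
shape. Noise is i.i.d. zero-mean Gaussian with σ a fraction of the
per-pixel baseline mean, seeded. Optional integer rounding of signals is
off by default.

What the phantom does *not* emulate: motion, partial volume, BMS shift,
spatially varying T10 or coil sensitivity, temporal AIF dispersion, and
Rician (magnitude) noise statistics. Passing recovery tests therefore
demonstrates the correctness of the calibration + fitting chain, not
robustness to those real-data effects.

## I/O conventions

4D data are X-Y-Z-time; raw binary stores X fastest (Fortran order) with
a JSON sidecar naming dims/dtype/byteorder and acquisition parameters.
DICOM series are written one file per (slice, frame) with temporal
position, slice location, TR, flip angle and a JSON comment carrying the
injection frame; reading sorts by temporal tag (fallback: acquisition
time, then instance number) and applies rescale slope/intercept. Pixel
data are uint16 with per-file scaling, so DICOM round trips are exact to
~1.5e-5 of the per-frame range (the raw writer is lossless). ROIs
persist as versioned JSON with a run-length-encoded mask. Parameter maps
export as single-column, multi-column or matrix text (`%.10g`, `nan` for
missing cells), all round-trip parseable. NIfTI export is intentionally
not included.

## Problem sizes used in the validation runs

The acceptance script fits patch-mean curves (bin factor 10): 30 fits of
1200-frame curves for the single-compartment object and 108 fits of
420-frame curves for the extended object — a few seconds in total. The
noisy-recovery property test fits all 100 pixels of each identifiable
patch (Ktrans ≤ 0.2 min⁻¹, ve ≥ 0.1) at σ = 20% and checks the patch
median against truth (≤ 10% deviation); ve < 0.1 rows are excluded
because their washout rate (kep up to 35 min⁻¹) exceeds what a 0.5 s
frame interval can constrain under that noise.

## Known limitations

* Larsson's `S0` and Hoffmann's `S0` are fixed to the measured baseline
  rather than fitted (the standard practical choice; a config flag could
  free them).
* The `ve + vp ≤ 1` constraint of the extended model is validated on
  constructed parameter objects but not enforced as a joint constraint
  during fitting (box bounds only).
* Reported ± values are 1-sigma standard errors from the local linear
  approximation, not profile or Bayesian intervals.
* The reference-region implementation expects the reference curve on the
  same uniform frame grid as the tissue data.
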