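# dcepk

Pharmacokinetic analysis of T1-weighted dynamic contrast-enhanced MRI
(DCE-MRI), aimed at preclinical (small-animal) studies: a scriptable
library plus a thin command line for batch work.

After a bolus of a low-molecular-weight gadolinium agent, tissue signal
enhancement tracks the exchange of contrast between blood plasma and the
extravascular-extracellular space (EES). dcepk fits that exchange
pixel-by-pixel over a region of interest with five compartmental models,
and handles everything around the fit: MR signal ↔ concentration
calibration, T10 mapping, arterial input functions, coarse-resolution
binning, model-free (semi-quantitative) parameters, file I/O, and a
digital reference phantom for end-to-end validation.

## Models

With `Cp(t)` the plasma concentration, `Ct(t)` tissue concentration,
`Ktrans` (min⁻¹) the transfer constant, `ve`, `vp` the EES and plasma
volume fractions and `kep = Ktrans/ve`:

* **standard two-compartment (Tofts)** — `Ct = Cp ∗ Ktrans·e^(−kep·t)`,
  solved in closed form for a bi-exponential population AIF
  `Cp = D·Σ aᵢ·e^(−mᵢ·t)`, or by discrete convolution for a sampled AIF;
* **extended model** — adds the intravascular term `vp·Cp(t)`;
* **Hoffmann** — signal-domain,
  `S/S₀ = 1 + A_H·kep·(e^(−kep·t) − e^(−kel·t))/(kel − kep)`; no AIF or
  calibration needed;
* **Larsson** — signal-domain, driven by the AIF shape with the initial
  slope `Ṡ(0)` as amplitude;
* **reference region** — eliminates `Cp` using a second tissue with known
  `(Ktrans,r, ve,r)`.

Signal calibration uses `1/T1(t) = 1/T10 + r1·Ct(t)` with exact
inversions of the spin-echo and spoiled gradient-echo (SPGR) signal
equations. Estimation is bounded Levenberg–Marquardt-style least squares
per pixel (or per k×k cell, k = 1…10), with standard errors from the
scaled covariance at the solution.

## Worked example

Generate the built-in noise-free validation phantom — 30 patches of
10×10 px, one per `(Ktrans, ve)` combination, synthesised through the
SPGR signal chain — and refit every patch:

```python
import numpy as np, dcepk as d

spec = d.default_tofts_spec()
series, truth = d.generate(spec)
roi = d.ROI(0, truth.tissue_mask, bin_factor=10, kind="box")
pm = d.fit_roi(series, roi, "tofts",
               relax=d.RelaxationParams(spec.r1, spec.T10_tissue),
               aif=spec.aif)
print(np.array2string(pm["Ktrans"], precision=4, suppress_small=True))
```

prints

```
[[0.01 0.02 0.05 0.1  0.2  0.35]
 [0.01 0.02 0.05 0.1  0.2  0.35]
 [0.01 0.02 0.05 0.1  0.2  0.35]
 [0.01 0.02 0.05 0.1  0.2  0.35]
 [0.01 0.02 0.05 0.1  0.2  0.35]]
```

i.e. the exact generating grid: each column is one `Ktrans` value
(0.01 … 0.35 min⁻¹) repeated across the five `ve` rows. With 20% baseline
Gaussian noise added, the same fit at coarser resolutions shows the
noise/resolution trade (`examples/03_noise_and_binning.py`):

```
 1x1  cells=100  effective sigma 20.0%  Ktrans = 0.1004 +/- 0.0055 1/min
 2x2  cells= 25  effective sigma 10.0%  Ktrans = 0.1001 +/- 0.0031 1/min
10x10 cells=  1  effective sigma  2.0%  Ktrans = 0.1000 +/- 0.0000 1/min
```

— the mean stays on target while the cell-to-cell spread shrinks as 1/k.
The `examples/` directory holds one short script per capability
(calibration, phantom recovery, binning, AIF-free models, semi-quantitative
maps); each prints what it computes and what the numbers mean.

## Command line

```sh
dcepk phantom --kind tofts --noise 0.2 --seed 42 --out ph/
dcepk analyze --input ph/series.raw --model tofts --config cfg.toml \
              --bin 10 --out maps.txt
dcepk t10 --input t10_dicoms/ --out t10.txt
dcepk export --input maps.txt --layout single_column --out maps_col.txt
```

Exit codes: 0 success, 2 configuration error (a missing model block is
named), 1 runtime error. The configuration file format is documented in
`dcepk/config.py`.

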