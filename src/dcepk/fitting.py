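"""Pixel-wise nonlinear least-squares estimation over an ROI.

Each cell of the (optionally coarsened) ROI grid contributes one averaged
time curve; for the concentration-domain models the curve is first
calibrated from signal to contrast-agent concentration, then fitted by
bounded Levenberg-Marquardt-style least squares (trust-region reflective,
MINPACK-style tolerances).  Cells are independent, so results are
order-invariant and deterministic.

Coarse binning follows the ROI convention of the original tool: k x k
non-overlapping blocks (k = 1..10) anchored at the mask bounding-box
origin, each cell's curve being the unweighted mean over its masked member
pixels.  Averaging k*k i.i.d.-noise pixels divides the noise standard
deviation by k, which is why coarse maps are markedly cleaner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Literal

import numpy as np
from scipy import optimize

from .aif import BiexpAIF, SampledAIF
from .containers import DCESeries
from .pk_models import (RRParams, ToftsParams, exp_kernel_convolve,
                        hoffmann_signal, larsson_signal, rr_ct,
                        tofts_ct_analytic, HoffmannParams, LarssonParams)
from .signal_model import (AcquisitionParams, RelaxationParams,
                           baseline_signal, calibrate_curve)

__all__ = [
    "ROI",
    "FitConfig",
    "FitResult",
    "ParameterMap",
    "ConfigurationError",
    "BinnedCurves",
    "bin_signals",
    "fit_curve",
    "fit_roi",
    "roi_statistics",
    "MODEL_NAMES",
]

MODEL_NAMES = ("tofts", "ext_tofts", "hoffmann", "larsson", "rr")
_ALIASES = {"xtofts": "ext_tofts", "extended_tofts": "ext_tofts"}


class ConfigurationError(Exception):
    """A required configuration block for the chosen model is missing."""


@dataclass(frozen=True)
class ROI:
    """A region of interest on one Z-slice.

    ``mask`` is boolean in display order (rows = Y, cols = X);
    ``bin_factor`` selects the processing resolution (1 = intrinsic,
    up to 10 x 10 pixel cells).
    """

    slice_index: int
    mask: np.ndarray
    bin_factor: int = 1
    kind: Literal["box", "full", "free"] = "free"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("mask must be a non-empty 2D boolean array")
        if not 1 <= int(self.bin_factor) <= 10:
            raise ValueError("bin_factor must be in 1..10")
        if self.kind not in ("box", "full", "free"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "bin_factor", int(self.bin_factor))

    @classmethod
    def box(cls, x0: int, y0: int, x1: int, y1: int, image_shape_yx,
            slice_index: int = 0, bin_factor: int = 1) -> "ROI":
        """Rectangular ROI from corner (x0, y0) to (x1, y1), inclusive."""
        mask = np.zeros(image_shape_yx, dtype=bool)
        mask[y0:y1 + 1, x0:x1 + 1] = True
        return cls(slice_index, mask, bin_factor, "box")

    @classmethod
    def full(cls, image_shape_yx, slice_index: int = 0, bin_factor: int = 1) -> "ROI":
        return cls(slice_index, np.ones(image_shape_yx, dtype=bool),
                   bin_factor, "full")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1) inclusive bounds of the mask."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


@dataclass
class BinnedCurves:
    """Averaged curves on the coarsened ROI grid."""

    cells: list[tuple[int, int]]      # (row, col) on the binned grid
    curves: np.ndarray                # (n_cells, n_frames)
    grid_shape: tuple[int, int]
    origin: tuple[int, int]           # bounding-box (row0, col0) in pixels
    bin_factor: int


def bin_signals(series: DCESeries, roi: ROI) -> BinnedCurves:
    """Average pixel curves over k x k cells of the ROI.

    Cells containing no masked pixel are skipped; ``bin_factor`` 1 returns
    the per-pixel curves unchanged.
    """
    ny, nx = roi.mask.shape
    if ny != series.shape[1] or nx != series.shape[0]:
        raise ValueError("ROI mask shape does not match the series X-Y plane")
    if not 0 <= roi.slice_index < series.shape[2]:
        raise ValueError("ROI slice index outside the series")
    plane = series.slice_yx(roi.slice_index)  # (Y, X, T)
    k = roi.bin_factor
    r0, c0, r1, c1 = roi.bounding_box()
    grid_h = -(-(r1 - r0 + 1) // k)
    grid_w = -(-(c1 - c0 + 1) // k)
    cells: list[tuple[int, int]] = []
    curves: list[np.ndarray] = []
    for i in range(grid_h):
        for j in range(grid_w):
            rs = slice(r0 + i * k, min(r0 + (i + 1) * k, ny))
            cs = slice(c0 + j * k, min(c0 + (j + 1) * k, nx))
            m = roi.mask[rs, cs]
            if not m.any():
                continue
            block = plane[rs, cs, :]
            cells.append((i, j))
            curves.append(block[m].mean(axis=0))
    return BinnedCurves(cells, np.asarray(curves), (grid_h, grid_w), (r0, c0), k)


@dataclass(frozen=True)
class FitConfig:
    """Solver settings (MINPACK-style defaults)."""

    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    max_iter: int = 200
    init: dict = field(default_factory=dict)     # per-parameter overrides
    bounds: dict = field(default_factory=dict)   # name -> (lo, hi)
    min_frames: int | None = None                # default: n_params + 1


@dataclass
class FitResult:
    """Outcome of one curve fit."""

    params: dict
    stderr: dict | None
    residual_norm: float
    converged: bool
    n_iter: int
    invalid: bool = False
    message: str = ""


def fit_curve(curve_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
              t: np.ndarray, y: np.ndarray,
              names: Iterable[str], init: np.ndarray,
              lower: np.ndarray, upper: np.ndarray,
              config: FitConfig | None = None,
              invalid: bool = False) -> FitResult:
    """Bounded least-squares fit of ``curve_fn(t, theta)`` to ``y``.

    NaN observations are dropped; an all-constant curve (no enhancement)
    is reported as non-converged with reason ``"degenerate"``.  Standard
    errors come from the residual-variance-scaled inverse of J^T J at the
    solution and are present only when the fit converged.
    """
    config = config or FitConfig()
    names = list(names)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(y)
    min_frames = config.min_frames or len(names) + 1
    if finite.sum() < min_frames:
        raise ValueError(f"fewer than {min_frames} finite observations")
    yf = y[finite]
    if np.ptp(yf) <= 1e-12 * max(1.0, np.abs(yf).max()):
        return FitResult({n: np.nan for n in names}, None, 0.0, False, 0,
                         invalid, "degenerate")

    x0 = np.clip(np.asarray(init, dtype=float), lower, upper)

    def resid(theta: np.ndarray) -> np.ndarray:
        return curve_fn(t, theta)[finite] - yf

    res = optimize.least_squares(
        resid, x0, bounds=(lower, upper), method="trf",
        ftol=config.ftol, xtol=config.xtol, gtol=config.gtol,
        max_nfev=config.max_iter * (len(names) + 1))
    converged = bool(res.success)
    params = dict(zip(names, (float(v) for v in res.x)))
    residual_norm = float(np.sqrt(2.0 * res.cost))
    stderr = None
    if converged:
        dof = finite.sum() - len(names)
        s2 = (2.0 * res.cost / dof) if dof > 0 else 0.0
        try:
            cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        stderr = dict(zip(names, (float(v) for v in se)))
    return FitResult(params, stderr, residual_norm, converged,
                     int(res.nfev), invalid, res.message)


# ---------------------------------------------------------------------------
# model builders: each returns (names, init, lower, upper, space, factory)
# where factory(baseline) -> curve_fn(t_min, theta)

_DEFAULT_INIT = {"Ktrans": 0.1, "ve": 0.3, "vp": 0.02,
                 "A_H": 1.0, "kep": 1.0, "kel": 0.05}


def _model_spec(model: str, *, aif=None, Cp_grid=None, rr_constants=None,
                Ct_r=None):
    """Assemble parameter names, defaults, bounds and the curve factory."""
    if model == "tofts":
        names = ["Ktrans", "ve"]
        lower = np.array([0.0, 1e-6])
        upper = np.array([np.inf, 1.0])

        def factory(S0b):
            if isinstance(aif, BiexpAIF):
                def fn(t, th):
                    return tofts_ct_analytic(
                        ToftsParams(max(th[0], 0.0), min(max(th[1], 1e-6), 1.0)),
                        aif, t)
            else:
                def fn(t, th):
                    kep = max(th[0], 0.0) / min(max(th[1], 1e-6), 1.0)
                    return exp_kernel_convolve(Cp_grid, t, max(th[0], 0.0), kep)
            return fn
        space = "concentration"

    elif model == "ext_tofts":
        names = ["Ktrans", "ve", "vp"]
        lower = np.array([0.0, 1e-6, 0.0])
        upper = np.array([np.inf, 1.0, 1.0])

        def factory(S0b):
            if isinstance(aif, BiexpAIF):
                def fn(t, th):
                    Cp = aif.cp_minutes(t)
                    leak = tofts_ct_analytic(
                        ToftsParams(max(th[0], 0.0), min(max(th[1], 1e-6), 1.0)),
                        aif, t)
                    return th[2] * Cp + leak
            else:
                def fn(t, th):
                    kep = max(th[0], 0.0) / min(max(th[1], 1e-6), 1.0)
                    leak = exp_kernel_convolve(Cp_grid, t, max(th[0], 0.0), kep)
                    return th[2] * Cp_grid + leak
            return fn
        space = "concentration"

    elif model == "hoffmann":
        names = ["A_H", "kep", "kel"]
        lower = np.zeros(3)
        upper = np.array([np.inf, np.inf, np.inf])

        def factory(S0b):
            def fn(t, th):
                return hoffmann_signal(HoffmannParams(*np.clip(th, 0, None)), S0b, t)
            return fn
        space = "signal"

    elif model == "larsson":
        names = ["kep", "Sdot0"]
        lower = np.zeros(2)
        upper = np.array([np.inf, np.inf])
        amps, rates = aif.amplitudes, aif.rates

        def factory(S0b):
            def fn(t, th):
                return larsson_signal(
                    LarssonParams(max(th[0], 0.0), S0b, th[1]), amps, rates, t)
            return fn
        space = "signal"

    elif model == "rr":
        names = ["Ktrans", "ve"]
        lower = np.array([0.0, 1e-6])
        upper = np.array([np.inf, 1.0])
        Kt_r, ve_r = rr_constants

        def factory(S0b):
            def fn(t, th):
                p = RRParams(max(th[0], 0.0), min(max(th[1], 1e-6), 1.0),
                             Kt_r, ve_r)
                return rr_ct(p, Ct_r, t)
            return fn
        space = "concentration"

    else:
        raise ValueError(f"unknown model {model!r}")

    init = np.array([_DEFAULT_INIT.get(n, 1.0) for n in names])
    return names, init, lower, upper, space, factory


@dataclass
class ParameterMap:
    """Per-cell fitted parameters on the binned ROI grid.

    Non-fitted or non-converged cells carry NaN; ``invalid`` marks cells
    where calibration clamping occurred.
    """

    model: str
    param_names: list[str]
    maps: dict
    stderr_maps: dict
    residual_norm: np.ndarray
    converged: np.ndarray
    invalid: np.ndarray
    grid_shape: tuple[int, int]
    roi: ROI | None = None
    config: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def fit_roi(series: DCESeries, roi: ROI, model: str,
            acq: AcquisitionParams | None = None,
            relax: RelaxationParams | None = None,
            aif: BiexpAIF | SampledAIF | None = None,
            rr_constants: tuple[float, float] | None = None,
            rr_reference: np.ndarray | ROI | None = None,
            config: FitConfig | None = None) -> ParameterMap:
    """Fit every cell of an ROI with the chosen pharmacokinetic model.

    The per-cell pipeline is: average the member-pixel curves, estimate the
    pre-injection baseline, calibrate signal to concentration for the
    concentration-domain models, then run the bounded least-squares fit.

    Model requirements: ``tofts``/``ext_tofts`` need an AIF plus relaxation
    parameters for calibration; ``larsson`` needs the AIF shape; ``rr``
    needs the reference-tissue constants, a reference curve (or ROI), and
    relaxation parameters; ``hoffmann`` needs signals only.
    """
    model = _ALIASES.get(model, model)
    if model not in MODEL_NAMES:
        raise ConfigurationError(
            f"unknown model {model!r}; choose from {MODEL_NAMES}")
    acq = acq or series.acq
    config = config or FitConfig()

    if model in ("tofts", "ext_tofts"):
        if aif is None:
            raise ConfigurationError(f"model {model!r} requires the [aif] block")
        if relax is None:
            raise ConfigurationError(
                f"model {model!r} requires the [ca] block (r1, T10)")
    if model == "larsson" and aif is None:
        raise ConfigurationError("model 'larsson' requires the [aif] block")
    if model == "larsson" and not isinstance(aif, BiexpAIF):
        raise ConfigurationError(
            "model 'larsson' needs a parametric (exponential-sum) AIF shape")
    if model == "rr":
        if rr_constants is None:
            raise ConfigurationError(
                "model 'rr' requires the [rr] block (Ktrans_r, ve_r)")
        if rr_reference is None:
            raise ConfigurationError(
                "model 'rr' requires a reference-region curve or ROI")
        if relax is None:
            raise ConfigurationError(
                "model 'rr' requires the [ca] block (r1, T10)")

    t_min = series.minutes_since_injection()
    binned = bin_signals(series, roi)

    Cp_grid = None
    if isinstance(aif, SampledAIF):
        Cp_grid = aif.cp_minutes(t_min)

    Ct_r = None
    if model == "rr":
        if isinstance(rr_reference, ROI):
            ref_binned = bin_signals(series, ROI(rr_reference.slice_index,
                                                 rr_reference.mask, 1,
                                                 rr_reference.kind))
            ref_curve = ref_binned.curves.mean(axis=0)
            S0r = baseline_signal(ref_curve, acq.injection_frame)
            Ct_r, _ = calibrate_curve(ref_curve, S0r, acq, relax)
        else:
            Ct_r = np.asarray(rr_reference, dtype=float)
            if Ct_r.shape != t_min.shape:
                raise ConfigurationError(
                    "reference curve length must match the frame grid")

    names, init, lower, upper, space, factory = _model_spec(
        model, aif=aif, Cp_grid=Cp_grid, rr_constants=rr_constants, Ct_r=Ct_r)
    for i, n in enumerate(names):
        if n in config.init:
            init[i] = config.init[n]
        if n in config.bounds:
            lower[i], upper[i] = config.bounds[n]

    gh, gw = binned.grid_shape
    maps = {n: np.full((gh, gw), np.nan) for n in names}
    stderr_maps = {n: np.full((gh, gw), np.nan) for n in names}
    residual_norm = np.full((gh, gw), np.nan)
    converged = np.zeros((gh, gw), dtype=bool)
    invalid = np.zeros((gh, gw), dtype=bool)

    for (i, j), curve in zip(binned.cells, binned.curves):
        S0b = baseline_signal(curve, acq.injection_frame)
        cell_invalid = False
        if space == "concentration":
            y, inval = calibrate_curve(curve, S0b, acq, relax)
            cell_invalid = bool(np.any(inval))
        else:
            y = curve
        fn = factory(S0b)
        try:
            res = fit_curve(fn, t_min, y, names, init, lower, upper,
                            config, invalid=cell_invalid)
        except ValueError:
            continue
        for n in names:
            if res.converged:
                maps[n][i, j] = res.params[n]
                stderr_maps[n][i, j] = res.stderr[n]
        residual_norm[i, j] = res.residual_norm
        converged[i, j] = res.converged
        invalid[i, j] = res.invalid

    snapshot = {"model": model, "bin_factor": roi.bin_factor,
                "fit": {k: v for k, v in asdict(config).items()}}
    return ParameterMap(model, names, maps, stderr_maps, residual_norm,
                        converged, invalid, (gh, gw), roi, snapshot)


def roi_statistics(pmap: ParameterMap) -> dict:
    """Unweighted per-parameter mean, SD and n over converged, valid cells.

    A single-cell map reports SD 0 by convention.
    """
    ok = pmap.converged & ~pmap.invalid
    if not ok.any():
        raise ValueError("no converged cells to summarise")
    out = {}
    for n in pmap.param_names:
        vals = pmap.maps[n][ok]
        vals = vals[np.isfinite(vals)]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[n] = {"mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)}
    return out
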