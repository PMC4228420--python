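"""Model-free (semi-quantitative) descriptive parameters.

Three closed-form statistics per pixel/cell, no solver involved:

* RCE — relative contrast enhancement, the peak post-injection signal
  increase over the pre-injection baseline, in percent;
* IAUC — initial area under the curve over a fixed window after injection
  (on calibrated concentration when calibration inputs are supplied,
  otherwise on relative enhancement);
* TTM — time from injection to the (first) maximal enhancement, seconds.
"""

from __future__ import annotations

import numpy as np

from .containers import DCESeries
from .fitting import ROI, ParameterMap, bin_signals
from .signal_model import (AcquisitionParams, RelaxationParams,
                           baseline_signal, calibrate_curve)

__all__ = ["rce", "iauc", "ttm", "semiquant_map"]


def rce(curve: np.ndarray, injection_frame: int) -> float:
    """Relative contrast enhancement in percent.

    ``100 (max_{t>=inj} S - S_base) / S_base`` with the baseline the mean
    of the pre-injection frames; the max is over post-injection frames
    only, so baseline noise cannot set it.
    """
    curve = np.asarray(curve, dtype=float)
    base = baseline_signal(curve, injection_frame)
    if base <= 0:
        raise ValueError("non-positive baseline")
    return float(100.0 * (curve[injection_frame:].max() - base) / base)


def iauc(curve: np.ndarray, injection_frame: int, frame_interval: float,
         window: float = 60.0) -> float:
    """Initial area under the curve over ``window`` seconds after injection.

    Trapezoidal quadrature on the frame grid; if the window end falls
    between frames the final sample is linearly interpolated.  The window
    must lie inside the acquired span (no extrapolation).
    """
    curve = np.asarray(curve, dtype=float)
    post = curve[injection_frame:]
    span = (post.size - 1) * frame_interval
    if window <= 0:
        raise ValueError("window must be positive")
    if window > span + 1e-9:
        raise ValueError(f"window {window} s exceeds the post-injection span {span} s")
    t = np.arange(post.size) * frame_interval
    n_full = int(np.floor(window / frame_interval))
    area = float(np.trapezoid(post[:n_full + 1], t[:n_full + 1]))
    rem = window - n_full * frame_interval
    if rem > 1e-12 * frame_interval:
        y_end = np.interp(window, t, post)
        area += 0.5 * (post[n_full] + y_end) * rem
    return area


def ttm(curve: np.ndarray, injection_frame: int, frame_interval: float) -> float:
    """Time to maximal enhancement, seconds since injection.

    Ties are broken by the earliest frame (argmax convention).
    """
    curve = np.asarray(curve, dtype=float)
    post = curve[injection_frame:]
    if post.size < 1:
        raise ValueError("need at least one post-injection frame")
    return float(np.argmax(post) * frame_interval)


def semiquant_map(series: DCESeries, roi: ROI,
                  acq: AcquisitionParams | None = None,
                  relax: RelaxationParams | None = None,
                  window: float = 60.0) -> ParameterMap:
    """RCE / IAUC / TTM planes over the binned ROI grid.

    When ``relax`` is given, IAUC is computed on calibrated concentration
    (mM*s); otherwise on relative enhancement (%*s), recorded in the map's
    config snapshot under ``iauc_basis``.
    """
    acq = acq or series.acq
    binned = bin_signals(series, roi)
    gh, gw = binned.grid_shape
    names = ["RCE", "IAUC", "TTM"]
    maps = {n: np.full((gh, gw), np.nan) for n in names}
    converged = np.zeros((gh, gw), dtype=bool)
    invalid = np.zeros((gh, gw), dtype=bool)
    dt = series.frame_interval
    basis = "concentration" if relax is not None else "relative_enhancement"
    for (i, j), curve in zip(binned.cells, binned.curves):
        base = baseline_signal(curve, acq.injection_frame)
        maps["RCE"][i, j] = rce(curve, acq.injection_frame)
        maps["TTM"][i, j] = ttm(curve, acq.injection_frame, dt)
        if relax is not None:
            y, inval = calibrate_curve(curve, base, acq, relax)
            invalid[i, j] = bool(np.any(inval))
        else:
            y = 100.0 * (curve - base) / base
        maps["IAUC"][i, j] = iauc(y, acq.injection_frame, dt, window)
        converged[i, j] = True
    zeros = np.full((gh, gw), np.nan)
    return ParameterMap("semiquant", names, maps,
                        {n: zeros.copy() for n in names}, zeros.copy(),
                        converged, invalid, (gh, gw), roi,
                        {"model": "semiquant", "window_s": window,
                         "iauc_basis": basis, "bin_factor": roi.bin_factor})
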