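"""Forward MR signal equations and their inversion to contrast-agent concentration.

Two pulse sequences are supported: a T1-weighted spin echo at short echo
time, ``S = S0 (1 - exp(-TR/T1))``, and a spoiled gradient echo (SPGR),
``S = S0 (1 - E) sin(a) / (1 - E cos(a))`` with ``E = exp(-TR/T1)``.

A low-molecular-weight gadolinium agent shortens T1 according to the
Solomon-Bloembergen relation ``1/T1(t) = 1/T10 + r1 Ct(t)``, so a dynamic
signal series can be converted to a concentration series once ``r1`` and the
pre-contrast ``T10`` are known.  The inversions here are exact inverses of
the forward equations over the physically valid range; when noise pushes a
signal sample outside that range the offending intermediate quantity is
clamped to the edge of the valid interval (relative margin ``CLAMP_EPS``)
and the sample is flagged invalid rather than returned as NaN, so flags can
propagate cleanly to parameter maps.

Unit conventions: TR and T1/T10 in milliseconds (only their ratio enters
the signal equations); r1 in s^-1 mM^-1; concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "AcquisitionParams",
    "RelaxationParams",
    "spin_echo_signal",
    "spgr_signal",
    "t1_from_concentration",
    "concentration_from_t1",
    "concentration_from_spinecho",
    "t1_from_spgr",
    "concentration_from_spgr",
    "calibrate_curve",
    "baseline_signal",
    "estimate_t10",
]

#: relative margin used when clamping out-of-range intermediates under noise
CLAMP_EPS = 1e-6

SequenceKind = Literal["spin_echo", "spgr"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic acquisition parameters.

    Parameters
    ----------
    sequence_kind:
        ``"spin_echo"`` or ``"spgr"``.
    TR:
        Repetition time in ms.
    flip_angle:
        Flip angle in degrees; only used for SPGR.
    frame_interval:
        Seconds per dynamic frame.
    injection_frame:
        0-based index of the first post-injection frame; at least one
        baseline frame must precede it.
    """

    sequence_kind: SequenceKind
    TR: float
    flip_angle: float = 90.0
    frame_interval: float = 1.0
    injection_frame: int = 1

    def __post_init__(self) -> None:
        if self.sequence_kind not in ("spin_echo", "spgr"):
            raise ValueError(f"unknown sequence kind {self.sequence_kind!r}")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.injection_frame < 1:
            raise ValueError("injection_frame must be >= 1 (need a baseline)")


@dataclass(frozen=True)
class RelaxationParams:
    """Relaxivity and pre-contrast T1.

    ``T10`` may be a scalar (ms) or a per-pixel map broadcastable against
    the signal arrays it is used with.
    """

    r1: float
    T10: float | np.ndarray = 1000.0

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")
        if np.any(np.asarray(self.T10) <= 0):
            raise ValueError("all T10 values must be positive")


def _maybe_scalar(x: np.ndarray, *inputs) -> np.ndarray | float:
    if all(np.isscalar(v) or np.ndim(v) == 0 for v in inputs):
        return float(x)
    return x


def spin_echo_signal(S0, T1, TR):
    """Spin-echo signal ``S0 (1 - exp(-TR/T1))`` (short echo time).

    T1 and TR in ms (any common unit works: only the ratio enters).
    """
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0) or TR <= 0:
        raise ValueError("T1 and TR must be positive")
    out = np.asarray(S0 * (1.0 - np.exp(-TR / T1)))
    return _maybe_scalar(out, S0, T1)


def spgr_signal(S0, T1, TR, alpha):
    """Spoiled gradient-echo signal for flip angle ``alpha`` (degrees)."""
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0) or TR <= 0:
        raise ValueError("T1 and TR must be positive")
    if not 0 < alpha <= 90:
        raise ValueError("flip angle must be in (0, 90] degrees")
    a = np.deg2rad(alpha)
    E = np.exp(-TR / T1)
    out = np.asarray(S0 * (1.0 - E) * np.sin(a) / (1.0 - E * np.cos(a)))
    return _maybe_scalar(out, S0, T1)


def t1_from_concentration(Ct, relax: RelaxationParams):
    """T1 (ms) from concentration via ``1/T1 = 1/T10 + r1 Ct``.

    ``r1`` is in s^-1 mM^-1, so T10 is converted to seconds where it meets
    the relaxivity term.
    """
    Ct = np.asarray(Ct, dtype=float)
    T10_s = np.asarray(relax.T10, dtype=float) / 1000.0
    T1_s = 1.0 / (1.0 / T10_s + relax.r1 * Ct)
    return _maybe_scalar(np.asarray(T1_s * 1000.0), Ct)


def concentration_from_t1(T1, relax: RelaxationParams):
    """Concentration (mM) from T1 (ms); negative iff T1 > T10."""
    T1_s = np.asarray(T1, dtype=float) / 1000.0
    T10_s = np.asarray(relax.T10, dtype=float) / 1000.0
    Ct = (1.0 / T1_s - 1.0 / T10_s) / relax.r1
    return _maybe_scalar(np.asarray(Ct), T1)


def baseline_signal(curve: np.ndarray, injection_frame: int, axis: int = -1):
    """Per-pixel baseline: mean of the pre-injection frames ``[0, injection_frame)``."""
    if injection_frame < 1:
        raise ValueError("need at least one pre-injection frame")
    curve = np.asarray(curve, dtype=float)
    sl = [slice(None)] * curve.ndim
    sl[axis] = slice(0, injection_frame)
    return curve[tuple(sl)].mean(axis=axis)


def concentration_from_spinecho(S_t, S0_base, acq: AcquisitionParams,
                                relax: RelaxationParams):
    """Invert the spin-echo signal equation to concentration.

    ``S0_base`` is the measured pre-injection signal (not the equilibrium
    amplitude).  Returns ``(Ct, invalid)`` where ``invalid`` marks samples
    whose log argument had to be clamped.
    """
    S_t = np.asarray(S_t, dtype=float)
    S0_base = np.asarray(S0_base, dtype=float)
    if np.any(S0_base <= 0):
        raise ValueError("baseline signal must be positive")
    TR = acq.TR
    T10 = np.asarray(relax.T10, dtype=float)
    arg = S0_base - S_t * (1.0 - np.exp(-TR / T10))
    lo = CLAMP_EPS * S0_base
    invalid = arg < lo
    arg = np.where(invalid, lo, arg)
    # 1/T1 in ms^-1, converted to s^-1 at the r1 boundary
    inv_T1_ms = np.log(S0_base / arg) / TR
    Ct = (inv_T1_ms - 1.0 / T10) * 1000.0 / relax.r1
    return _maybe_scalar(np.asarray(Ct), S_t, S0_base), _maybe_bool(invalid, S_t, S0_base)


def _maybe_bool(x: np.ndarray, *inputs):
    if all(np.isscalar(v) or np.ndim(v) == 0 for v in inputs):
        return bool(x)
    return x


def t1_from_spgr(S_t, S0_base, acq: AcquisitionParams, relax: RelaxationParams):
    """Dynamic T1 (ms) from an SPGR signal series and its measured baseline.

    The textbook inversion divides the signal increase by the equilibrium
    amplitude times sin(alpha); that product is recovered from the baseline
    as ``S0_base (1 - m cos a) / (1 - m)`` with ``m = exp(-TR/T10)``, so
    only measured quantities enter.  Returns ``(T1_ms, invalid)``.
    """
    S_t = np.asarray(S_t, dtype=float)
    S0_base = np.asarray(S0_base, dtype=float)
    if np.any(S0_base <= 0):
        raise ValueError("baseline signal must be positive")
    a = np.deg2rad(acq.flip_angle)
    c, TR = np.cos(a), acq.TR
    m = np.exp(-TR / np.asarray(relax.T10, dtype=float))
    base_frac = (1.0 - m) / (1.0 - m * c)
    S0eq_sin = S0_base / base_frac  # equilibrium amplitude x sin(alpha)
    X = (S_t - S0_base) / S0eq_sin + base_frac
    # E = exp(-TR/T1) must lie in (0, 1)  <=>  X in (0, 1)
    lo, hi = CLAMP_EPS, 1.0 - CLAMP_EPS
    invalid = (X <= lo) | (X >= hi)
    X = np.clip(X, lo, hi)
    E = (1.0 - X) / (1.0 - X * c)
    T1 = -TR / np.log(E)
    return _maybe_scalar(np.asarray(T1), S_t, S0_base), _maybe_bool(invalid, S_t, S0_base)


def concentration_from_spgr(S_t, S0_base, acq: AcquisitionParams,
                            relax: RelaxationParams):
    """SPGR signal series -> concentration (mM); returns ``(Ct, invalid)``."""
    T1, invalid = t1_from_spgr(S_t, S0_base, acq, relax)
    return concentration_from_t1(T1, relax), invalid


def calibrate_curve(S_t, S0_base, acq: AcquisitionParams, relax: RelaxationParams):
    """Signal -> concentration for whichever sequence ``acq`` declares."""
    if acq.sequence_kind == "spin_echo":
        return concentration_from_spinecho(S_t, S0_base, acq, relax)
    return concentration_from_spgr(S_t, S0_base, acq, relax)


def estimate_t10(images: Sequence[tuple[float, np.ndarray]],
                 method: Literal["two_point_ratio", "least_squares"] = "two_point_ratio"):
    """Estimate a pre-contrast T10 map from spin-echo images at several TRs.

    Parameters
    ----------
    images:
        Sequence of ``(TR_ms, intensity_image)`` pairs; >= 2 entries with
        distinct TRs and identical shapes.
    method:
        ``"two_point_ratio"`` solves the TR-ratio equation per pixel by
        bracketed root finding using the first two images;
        ``"least_squares"`` fits ``S0 (1 - exp(-TR/T1))`` per pixel over
        all images.

    Returns
    -------
    (T10_map, invalid) : ndarray, ndarray of bool
        T10 in ms; pixels whose intensity ratio falls outside the range the
        model can produce are flagged and set to NaN.
    """
    if len(images) < 2:
        raise ValueError("need at least two images with different TR")
    TRs = np.array([float(tr) for tr, _ in images])
    if len(np.unique(TRs)) != len(TRs):
        raise ValueError("repetition times must be distinct")
    arrs = [np.asarray(img, dtype=float) for _, img in images]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all images must share the same shape")

    T1_LO, T1_HI = 1e-3, 1e7  # ms bracket: essentially (0, inf)

    if method == "two_point_ratio":
        (TR1, S1), (TR2, S2) = (TRs[0], arrs[0]), (TRs[1], arrs[1])
        if TR1 > TR2:  # order so that the ratio is increasing in T1
            TR1, TR2, S1, S2 = TR2, TR1, S2, S1
        out = np.full(shape, np.nan)
        invalid = np.zeros(shape, dtype=bool)
        ratio = np.divide(S1, S2, out=np.full(shape, np.nan), where=S2 != 0)

        def f(T1, r):
            return (1.0 - np.exp(-TR1 / T1)) / (1.0 - np.exp(-TR2 / T1)) - r

        rmin = f(T1_HI, 0.0)  # -> TR1/TR2 as T1 -> inf
        rmax = f(T1_LO, 0.0)  # -> 1 as T1 -> 0
        it = np.nditer(np.zeros(shape), flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            r = ratio[idx]
            if not np.isfinite(r) or not (rmin < r < rmax):
                invalid[idx] = True
                continue
            out[idx] = optimize.brentq(f, T1_LO, T1_HI, args=(r,), xtol=1e-9)
        return out, invalid

    if method == "least_squares":
        out = np.full(shape, np.nan)
        invalid = np.zeros(shape, dtype=bool)
        stack = np.stack(arrs, axis=-1)  # (..., n_images)
        it = np.nditer(np.zeros(shape), flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            y = stack[idx]
            if np.any(~np.isfinite(y)) or y.max() <= 0:
                invalid[idx] = True
                continue

            def resid(p):
                S0, T1 = p
                return S0 * (1.0 - np.exp(-TRs / T1)) - y

            res = optimize.least_squares(
                resid, x0=[y.max(), float(np.mean(TRs))],
                bounds=([0.0, T1_LO], [np.inf, T1_HI]), method="trf")
            if not res.success:
                invalid[idx] = True
                continue
            out[idx] = res.x[1]
        return out, invalid

    raise ValueError(f"unknown method {method!r}")
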