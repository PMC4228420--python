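"""Forward pharmacokinetic model curves for T1-weighted DCE-MRI.

All models derive from the open two-compartment exchange between blood
plasma and the extravascular-extracellular space (EES):

* standard model (Ktrans, ve): tissue concentration is the plasma curve
  convolved with ``Ktrans exp(-kep t)``, ``kep = Ktrans / ve``;
* extended model adds the intravascular term ``vp Cp(t)``;
* Hoffmann: a direct signal-enhancement model (A_H, kep, kel) needing no
  AIF or concentration calibration;
* Larsson: a signal-domain model driven by the AIF shape with the initial
  signal slope as amplitude;
* reference-region model: eliminates Cp using a second, well-characterised
  tissue with known (Ktrans_r, ve_r).

Time is minutes since injection throughout; all rate constants are 1/min.
Every concentration model is identically zero at and before the injection
instant.  Removable singularities (an AIF decay rate coinciding with kep,
or kel -> kep in the Hoffmann model) switch to the analytic limit branch
when the rate gap is below ``RATE_GAP`` (1e-8 1/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import BiexpAIF, SampledAIF

__all__ = [
    "ToftsParams",
    "ExtToftsParams",
    "HoffmannParams",
    "LarssonParams",
    "RRParams",
    "exp_kernel_convolve",
    "tofts_ct_analytic",
    "tofts_ct",
    "ext_tofts_ct",
    "hoffmann_signal",
    "larsson_signal",
    "rr_ct",
]

RATE_GAP = 1e-8  # 1/min: below this, use the coinciding-rates limit branch


@dataclass(frozen=True)
class ToftsParams:
    Ktrans: float  # 1/min
    ve: float      # fraction of tissue volume

    def __post_init__(self) -> None:
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be non-negative")
        if not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1]")

    @property
    def kep(self) -> float:
        """Washout rate EES -> plasma, Ktrans/ve (1/min)."""
        return self.Ktrans / self.ve


@dataclass(frozen=True)
class ExtToftsParams:
    Ktrans: float
    ve: float
    vp: float

    def __post_init__(self) -> None:
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be non-negative")
        if not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1]")
        if not 0 <= self.vp <= 1:
            raise ValueError("vp must lie in [0, 1]")
        if self.ve + self.vp > 1:
            raise ValueError("ve + vp must not exceed 1")

    @property
    def kep(self) -> float:
        return self.Ktrans / self.ve


@dataclass(frozen=True)
class HoffmannParams:
    A_H: float   # dimensionless amplitude, ~ EES size
    kep: float   # 1/min
    kel: float   # renal elimination constant, 1/min

    def __post_init__(self) -> None:
        if self.A_H < 0 or self.kep < 0 or self.kel < 0:
            raise ValueError("Hoffmann parameters must be non-negative")


@dataclass(frozen=True)
class LarssonParams:
    kep: float    # 1/min
    S0: float     # baseline signal
    Sdot0: float  # initial signal slope, signal/min

    def __post_init__(self) -> None:
        if self.kep < 0:
            raise ValueError("kep must be non-negative")
        if self.S0 <= 0:
            raise ValueError("baseline signal must be positive")


@dataclass(frozen=True)
class RRParams:
    Ktrans: float
    ve: float
    Ktrans_r: float  # reference-tissue transfer constant, fixed in fits
    ve_r: float

    def __post_init__(self) -> None:
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be non-negative")
        if min(self.ve, self.Ktrans_r, self.ve_r) <= 0:
            raise ValueError("ve and reference constants must be positive")
        if self.ve > 1 or self.ve_r > 1:
            raise ValueError("ve fractions must not exceed 1")


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("need at least two samples")
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
        raise ValueError("time grid must be uniform; resample first")
    return float(dt[0])


def _trapz_exp_convolve(series: np.ndarray, t: np.ndarray, rate: float) -> np.ndarray:
    """``int_0^t series(u) exp(-rate (t-u)) du`` on a uniform grid.

    Product integration: the series is taken piecewise linear between
    samples and integrated against the exponential kernel exactly, which
    keeps the quadrature accurate even when ``rate * dt`` is not small
    (fast washout on a coarse frame grid).  As ``rate * dt -> 0`` the
    interval weights reduce to the ordinary trapezoid rule.
    """
    dt = _check_uniform(t)
    n = series.size
    x = rate * dt
    if x < 1e-12:
        A, B = dt, dt / 2.0  # trapezoid limit
    else:
        em = np.exp(-x)
        A = (1.0 - em) / rate                      # int of kernel over one step
        B = A - (1.0 - em * (1.0 + x)) / (rate * x)  # weight of the newer sample
    kernel = np.exp(-x * np.arange(n))
    S = np.convolve(series, kernel)[:n]
    out = np.empty(n)
    out[0] = 0.0
    # recursion I_n = e^-x I_{n-1} + C_{n-1} (A - B) + C_n B, unrolled
    out[1:] = (A - B) * S[:-1] + B * (S[1:] - series[0] * kernel[1:])
    return out


def exp_kernel_convolve(Cp: np.ndarray, t_min: np.ndarray,
                        Ktrans: float, kep: float) -> np.ndarray:
    """Discrete-convolution tissue curve ``Cp * Ktrans exp(-kep t)``.

    ``Cp`` is a plasma concentration series sampled on the uniform grid
    ``t_min`` (minutes); quadrature is trapezoidal on that grid.
    """
    Cp = np.asarray(Cp, dtype=float)
    t = np.asarray(t_min, dtype=float)
    if Cp.shape != t.shape:
        raise ValueError("Cp and time grid must have the same length")
    return Ktrans * _trapz_exp_convolve(Cp, t, kep)


def _biexp_response(amplitudes, rates, kep: float, t: np.ndarray) -> np.ndarray:
    """``sum_i a_i (exp(-kep t) - exp(-m_i t)) / (m_i - kep)`` with limit branch."""
    out = np.zeros_like(t)
    pos = t >= 0
    tp = np.where(pos, t, 0.0)
    for a, m in zip(amplitudes, rates):
        if abs(m - kep) < RATE_GAP:
            term = a * tp * np.exp(-kep * tp)
        else:
            term = a * (np.exp(-kep * tp) - np.exp(-m * tp)) / (m - kep)
        out = out + np.where(pos, term, 0.0)
    return out


def tofts_ct_analytic(p: ToftsParams, aif: BiexpAIF, t_min) -> np.ndarray:
    """Closed-form tissue curve for the standard model with a bi-exponential AIF.

    ``Ct(t) = D Ktrans sum_i a_i (exp(-kep t) - exp(-m_i t)) / (m_i - kep)``
    for an instantaneous bolus at t = 0.
    """
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    out = aif.D * p.Ktrans * _biexp_response(aif.amplitudes, aif.rates, p.kep, t)
    return out if np.ndim(t_min) else float(out[0])


def tofts_ct(p: ToftsParams, aif, t_min) -> np.ndarray:
    """Standard-model tissue curve; analytic for a bi-exponential AIF,
    discrete convolution for a sampled one."""
    if isinstance(aif, BiexpAIF):
        return tofts_ct_analytic(p, aif, t_min)
    t = np.asarray(t_min, dtype=float)
    Cp = aif.cp_minutes(t) if isinstance(aif, SampledAIF) else np.asarray(aif, dtype=float)
    return exp_kernel_convolve(Cp, t, p.Ktrans, p.kep)


def ext_tofts_ct(p: ExtToftsParams, aif, t_min) -> np.ndarray:
    """Extended-model tissue curve ``vp Cp(t) + (Cp * Ktrans exp(-kep t))``."""
    t = np.asarray(t_min, dtype=float)
    if isinstance(aif, BiexpAIF):
        Cp = aif.cp_minutes(t)
        leak = tofts_ct_analytic(ToftsParams(p.Ktrans, p.ve), aif, t) \
            if p.Ktrans > 0 else np.zeros_like(t)
    else:
        Cp = aif.cp_minutes(t) if isinstance(aif, SampledAIF) else np.asarray(aif, dtype=float)
        leak = exp_kernel_convolve(Cp, t, p.Ktrans, p.kep) \
            if p.Ktrans > 0 else np.zeros_like(t)
    return p.vp * Cp + leak


def hoffmann_signal(p: HoffmannParams, S0: float, t_min) -> np.ndarray:
    """Hoffmann enhancement curve.

    ``S(t)/S0 = 1 + A_H kep (exp(-kep t) - exp(-kel t)) / (kel - kep)``;
    for ``kel -> kep`` the limit ``1 + A_H kep t exp(-kep t)`` is used.
    ``S(t) = S0`` before injection.
    """
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    pos = t >= 0
    tp = np.where(pos, t, 0.0)
    if abs(p.kel - p.kep) < RATE_GAP:
        enh = p.A_H * p.kep * tp * np.exp(-p.kep * tp)
    else:
        enh = p.A_H * p.kep * (np.exp(-p.kep * tp) - np.exp(-p.kel * tp)) / (p.kel - p.kep)
    out = S0 * (1.0 + np.where(pos, enh, 0.0))
    return out if np.ndim(t_min) else float(out[0])


def larsson_signal(p: LarssonParams, amplitudes, rates, t_min) -> np.ndarray:
    """Larsson signal curve driven by an exponential-sum AIF shape.

    ``S(t) = S0 + Sdot0 * [sum_i a_i (exp(-kep t) - exp(-m_i t))/(m_i - kep)]
    / sum_i a_i`` — normalised so the initial slope equals ``Sdot0`` exactly.
    """
    amplitudes = tuple(amplitudes)
    rates = tuple(rates)
    if len(amplitudes) != len(rates) or not amplitudes:
        raise ValueError("need matching, non-empty amplitude/rate lists")
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    resp = _biexp_response(amplitudes, rates, p.kep, t) / sum(amplitudes)
    out = p.S0 + p.Sdot0 * resp
    return out if np.ndim(t_min) else float(out[0])


def rr_ct(p: RRParams, Ct_r: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Reference-region tissue curve from the reference tissue's own curve.

    ``Ct = (Ktrans/Ktrans_r) [Ct_r + (Ktrans_r/ve_r - Ktrans/ve)
    int_0^t Ct_r(u) exp(-(Ktrans/ve)(t-u)) du]``, trapezoidal quadrature.
    When tissue and reference parameters coincide the integral coefficient
    vanishes and ``Ct = Ct_r`` identically.
    """
    Ct_r = np.asarray(Ct_r, dtype=float)
    t = np.asarray(t_min, dtype=float)
    kep = p.Ktrans / p.ve
    integral = _trapz_exp_convolve(Ct_r, t, kep)
    coeff = p.Ktrans_r / p.ve_r - p.Ktrans / p.ve
    return (p.Ktrans / p.Ktrans_r) * (Ct_r + coeff * integral)
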