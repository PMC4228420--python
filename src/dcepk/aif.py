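"""Arterial input function (AIF) representations.

Two forms are supported: the classic population bi-exponential plasma curve

    Cp(t) = D * sum_i a_i exp(-m_i t)

with dose D (mmol/kg), amplitudes a_i (kg/L) and rates m_i (1/min), and a
sampled curve imported from an external measurement.  Sampled whole-blood
curves are converted to plasma via the hematocrit, Cp = Cb / (1 - Hct).

The default constants are the standard population values commonly used with
the bi-exponential plasma model (literature values, configurable); the time
origin of every AIF is the instant of contrast injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BiexpAIF",
    "SampledAIF",
    "default_population_aif",
    "biexp_cp",
    "blood_to_plasma",
    "resample_aif",
    "save_sampled_aif",
    "load_sampled_aif",
]

# Weinmann/Tofts population constants for Gd-DTPA plasma clearance
POPULATION_AMPLITUDES = (3.99, 4.78)   # kg/L
POPULATION_RATES = (0.144, 0.0111)     # 1/min


@dataclass(frozen=True)
class BiexpAIF:
    """Bi-exponential population plasma curve.

    Terms are stored in canonical order (descending rate, i.e. the fast
    distribution phase first).
    """

    D: float = 0.2                                     # mmol/kg
    amplitudes: tuple[float, ...] = POPULATION_AMPLITUDES
    rates: tuple[float, ...] = POPULATION_RATES

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("dose must be non-negative")
        if len(self.amplitudes) != len(self.rates):
            raise ValueError("amplitudes and rates must pair up")
        if any(a <= 0 for a in self.amplitudes) or any(m <= 0 for m in self.rates):
            raise ValueError("amplitudes and rates must be positive")
        order = np.argsort(self.rates)[::-1]
        object.__setattr__(self, "amplitudes",
                           tuple(self.amplitudes[i] for i in order))
        object.__setattr__(self, "rates", tuple(self.rates[i] for i in order))

    def cp_minutes(self, t_min) -> np.ndarray:
        """Plasma concentration (mM) at ``t_min`` minutes since injection."""
        t = np.asarray(t_min, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        for a, m in zip(self.amplitudes, self.rates):
            out = out + np.where(pos, self.D * a * np.exp(-m * np.where(pos, t, 0.0)), 0.0)
        return out


def default_population_aif(D: float = 0.2) -> BiexpAIF:
    return BiexpAIF(D=D)


def biexp_cp(aif: BiexpAIF, t_seconds) -> np.ndarray | float:
    """Cp (mM) at ``t_seconds`` seconds since injection; 0 for t < 0."""
    t = np.asarray(t_seconds, dtype=float)
    out = aif.cp_minutes(t / 60.0)
    return float(out) if np.ndim(t_seconds) == 0 else out


def blood_to_plasma(Cb, hematocrit: float):
    """Whole-blood -> plasma concentration: Cp = Cb / (1 - Hct)."""
    if not 0 <= hematocrit < 1:
        raise ValueError("hematocrit must lie in [0, 1)")
    Cb = np.asarray(Cb, dtype=float)
    out = Cb / (1.0 - hematocrit)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SampledAIF:
    """A measured input function: Cp (mM) at sample times (s since injection)."""

    times: np.ndarray
    Cp: np.ndarray
    is_blood: bool = False
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        Cp = np.asarray(self.Cp, dtype=float)
        if times.shape != Cp.shape or times.ndim != 1:
            raise ValueError("times and Cp must be equal-length 1D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(Cp < 0):
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must lie in [0, 1)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "Cp", Cp)

    def plasma(self) -> "SampledAIF":
        """Return a plasma-concentration version of this AIF."""
        if not self.is_blood:
            return self
        return SampledAIF(self.times, blood_to_plasma(self.Cp, self.hematocrit),
                          is_blood=False, hematocrit=self.hematocrit)

    def cp_minutes(self, t_min) -> np.ndarray:
        """Interpolated plasma Cp at ``t_min`` minutes since injection."""
        p = self.plasma()
        t = np.asarray(t_min, dtype=float) * 60.0
        return np.interp(t, p.times, p.Cp, left=0.0, right=float(p.Cp[-1]))


def resample_aif(aif: SampledAIF, frame_times) -> SampledAIF:
    """Resample onto the acquisition frame grid (seconds since injection).

    Linear interpolation inside the sampled span, 0 before the first sample
    and the last value held beyond the last sample.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    p = aif.plasma()
    Cp = np.interp(frame_times, p.times, p.Cp, left=0.0, right=float(p.Cp[-1]))
    return SampledAIF(frame_times, Cp, is_blood=False, hematocrit=aif.hematocrit)


def save_sampled_aif(aif: SampledAIF, path) -> None:
    """Write a two-column text file (time_s, Cp_mM) with '#' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# sampled AIF\n# columns: time_s Cp_mM\n")
        fh.write(f"# is_blood: {int(aif.is_blood)}  hematocrit: {aif.hematocrit:.6g}\n")
        for t, c in zip(aif.times, aif.Cp):
            fh.write(f"{t:.10g} {c:.10g}\n")


def load_sampled_aif(path) -> SampledAIF:
    path = Path(path)
    is_blood, hct = False, 0.45
    times, Cp = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "is_blood:" in line:
                toks = line.replace("#", "").split()
                is_blood = bool(int(toks[toks.index("is_blood:") + 1]))
                if "hematocrit:" in toks:
                    hct = float(toks[toks.index("hematocrit:") + 1])
            continue
        t, c = line.split()[:2]
        times.append(float(t))
        Cp.append(float(c))
    return SampledAIF(np.array(times), np.array(Cp), is_blood=is_blood, hematocrit=hct)
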