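"""The central in-memory container for a dynamic series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import AcquisitionParams

__all__ = ["DCESeries"]


@dataclass
class DCESeries:
    """A 4D dynamic contrast-enhanced series.

    ``data`` is ordered X-Y-Z-time; ``frame_times`` are seconds on the
    acquisition clock and must be uniformly spaced.  The injection instant
    is ``frame_times[acq.injection_frame]``.
    """

    data: np.ndarray
    frame_times: np.ndarray
    acq: AcquisitionParams
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, time)")
        if self.frame_times.shape != (self.data.shape[3],):
            raise ValueError("frame_times length must match the time axis")
        dt = np.diff(self.frame_times)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]):
            raise ValueError("frame times must be uniformly spaced")
        if self.acq.injection_frame >= self.n_frames:
            raise ValueError("injection_frame beyond the series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def frame_interval(self) -> float:
        """Seconds per frame."""
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def injection_time(self) -> float:
        """Seconds on the acquisition clock at which injection occurs."""
        return float(self.frame_times[self.acq.injection_frame])

    def minutes_since_injection(self) -> np.ndarray:
        """Model time axis: minutes relative to the injection instant."""
        return (self.frame_times - self.injection_time) / 60.0

    def slice_yx(self, z: int) -> np.ndarray:
        """One Z-slice as (Y, X, time), the display/mask orientation."""
        return np.transpose(self.data[:, :, z, :], (1, 0, 2))
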