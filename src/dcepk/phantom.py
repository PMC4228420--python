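"""Digital reference phantom generator for validating the analysis chain.

Builds synthetic dynamic series in the style of the public QIBA DCE-MRI
digital reference objects: a tissue region tiled with 10 x 10 pixel
patches, one per combination of ground-truth pharmacokinetic parameters,
plus a vascular strip along the bottom carrying the whole-blood input
signal.  Tissue curves are produced by the chosen compartmental model and
the configured bi-exponential plasma input, converted to T1 via the
relaxivity relation and to signal with the exact sequence equation, so the
calibration and fitting code can be validated end to end against known
truth without any external download.

Two ready-made specifications mirror the published validation objects:

* single-compartment set — SPGR, 30 (Ktrans, ve) combinations on a
  50 x 60 px tissue region, 10 min at 0.5 s/frame, injection at 60 s;
* extended set — SPGR at a lower flip angle and equilibrium amplitude,
  108 (Ktrans, ve, vp) combinations on a 180 x 60 px region (printed as
  60 x 180), 3.5 min at 0.5 s/frame, injection at 5 s, 20-row strip.

Noise is zero-mean Gaussian with standard deviation expressed as a
fraction of the per-pixel baseline signal, always seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aif import BiexpAIF, default_population_aif
from .containers import DCESeries
from .pk_models import ExtToftsParams, ToftsParams, ext_tofts_ct, tofts_ct_analytic
from .signal_model import (AcquisitionParams, RelaxationParams,
                           spgr_signal, spin_echo_signal, t1_from_concentration)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_tofts_spec",
    "default_ext_tofts_spec",
    "generate",
    "add_gaussian_noise",
]

TOFTS_KTRANS_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35)   # 1/min
TOFTS_VE_GRID = (0.01, 0.05, 0.1, 0.2, 0.5)
EXT_KTRANS_GRID = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2)      # 1/min
EXT_VE_GRID = (0.1, 0.2, 0.5)
EXT_VP_GRID = (0.001, 0.005, 0.01, 0.02, 0.05, 0.1)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic validation object."""

    model: str                                  # "tofts" | "ext_tofts"
    Ktrans_values: tuple[float, ...]
    ve_values: tuple[float, ...]
    vp_values: tuple[float, ...] = ()
    patch_size: int = 10
    acq: AcquisitionParams = AcquisitionParams("spgr", TR=5.0, flip_angle=30.0,
                                               frame_interval=0.5,
                                               injection_frame=120)
    T10_tissue: float = 1000.0                  # ms
    T10_blood: float = 1440.0                   # ms
    hematocrit: float = 0.45
    r1: float = 4.5                             # 1/(s mM)
    duration: float = 600.0                     # s
    injection_time: float = 60.0                # s
    aif: BiexpAIF = field(default_factory=default_population_aif)
    s0: float = 1000.0                          # equilibrium amplitude, a.u.
    noise_sigma_fraction: float = 0.0           # of per-pixel baseline
    seed: int = 0
    vascular_strip_rows: int = 10
    quantize_signals: bool = False              # round to integers if set

    def __post_init__(self) -> None:
        if self.model not in ("tofts", "ext_tofts"):
            raise ValueError("model must be 'tofts' or 'ext_tofts'")
        if not self.Ktrans_values or not self.ve_values:
            raise ValueError("parameter grids must be non-empty")
        if self.model == "ext_tofts" and not self.vp_values:
            raise ValueError("extended model needs a vp grid")
        for v in self.ve_values + self.vp_values:
            if not 0 <= v <= 1:
                raise ValueError("fractional volumes must lie in [0, 1]")
        if self.duration <= self.injection_time:
            raise ValueError("duration must exceed the injection time")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.acq.frame_interval))

    @property
    def n_patch_rows(self) -> int:
        if self.model == "tofts":
            return len(self.ve_values)
        return len(self.ve_values) * len(self.vp_values)

    @property
    def n_patch_cols(self) -> int:
        return len(self.Ktrans_values)

    @property
    def tissue_shape_yx(self) -> tuple[int, int]:
        return (self.n_patch_rows * self.patch_size,
                self.n_patch_cols * self.patch_size)


def default_tofts_spec(noise_sigma_fraction: float = 0.0,
                       seed: int = 0) -> PhantomSpec:
    """The single-compartment validation object (30 patches, 50 x 60 px)."""
    return PhantomSpec(
        model="tofts",
        Ktrans_values=TOFTS_KTRANS_GRID, ve_values=TOFTS_VE_GRID,
        acq=AcquisitionParams("spgr", TR=5.0, flip_angle=30.0,
                              frame_interval=0.5, injection_frame=120),
        duration=600.0, injection_time=60.0, s0=1000.0,
        noise_sigma_fraction=noise_sigma_fraction, seed=seed,
        vascular_strip_rows=10)


def default_ext_tofts_spec(noise_sigma_fraction: float = 0.0,
                           seed: int = 0) -> PhantomSpec:
    """The extended-model validation object (108 patches, 180 x 60 px)."""
    return PhantomSpec(
        model="ext_tofts",
        Ktrans_values=EXT_KTRANS_GRID, ve_values=EXT_VE_GRID,
        vp_values=EXT_VP_GRID,
        acq=AcquisitionParams("spgr", TR=5.0, flip_angle=25.0,
                              frame_interval=0.5, injection_frame=10),
        duration=210.0, injection_time=5.0, s0=250.0,
        noise_sigma_fraction=noise_sigma_fraction, seed=seed,
        vascular_strip_rows=20)


@dataclass
class PhantomTruth:
    """Ground-truth parameter planes over the tissue region (rows = Y)."""

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray | None
    tissue_mask: np.ndarray     # full-image (Y, X) boolean
    vascular_mask: np.ndarray
    spec: PhantomSpec


def _patch_params(spec: PhantomSpec):
    """Yield (row, col, params) over the patch grid.

    Rows run over ve ascending top-to-bottom (extended set: ve outer,
    vp inner); columns over Ktrans ascending left-to-right.
    """
    for col, kt in enumerate(spec.Ktrans_values):
        if spec.model == "tofts":
            for row, ve in enumerate(spec.ve_values):
                yield row, col, ToftsParams(kt, ve)
        else:
            for i, ve in enumerate(spec.ve_values):
                for j, vp in enumerate(spec.vp_values):
                    yield i * len(spec.vp_values) + j, col, \
                        ExtToftsParams(kt, ve, vp)


def _signal(spec: PhantomSpec, T1: np.ndarray) -> np.ndarray:
    if spec.acq.sequence_kind == "spgr":
        return spgr_signal(spec.s0, T1, spec.acq.TR, spec.acq.flip_angle)
    return spin_echo_signal(spec.s0, T1, spec.acq.TR)


def generate(spec: PhantomSpec) -> tuple[DCESeries, PhantomTruth]:
    """Synthesize the phantom series together with its ground truth.

    Per tissue pixel: tissue concentration from the spec's model and AIF,
    T1(t) from the relaxivity relation, then the exact sequence signal.
    Vascular pixels carry the whole-blood signal, ``Cb = (1 - Hct) Cp``,
    with the blood T10.  Pre-injection frames sit exactly at baseline.
    """
    nF = spec.n_frames
    dt = spec.acq.frame_interval
    frame_times = np.arange(nF) * dt
    inj_frame = spec.acq.injection_frame
    if abs(frame_times[inj_frame] - spec.injection_time) > 1e-9:
        raise ValueError("injection_frame and injection_time disagree")
    t_min = (frame_times - spec.injection_time) / 60.0

    ps = spec.patch_size
    ny_t, nx = spec.tissue_shape_yx
    ny = ny_t + spec.vascular_strip_rows
    relax_t = RelaxationParams(spec.r1, spec.T10_tissue)
    relax_b = RelaxationParams(spec.r1, spec.T10_blood)

    plane = np.empty((ny, nx, nF))  # (Y, X, T)
    kt_plane = np.empty((ny_t, nx))
    ve_plane = np.empty((ny_t, nx))
    vp_plane = np.empty((ny_t, nx)) if spec.model == "ext_tofts" else None

    for row, col, p in _patch_params(spec):
        if spec.model == "tofts":
            Ct = tofts_ct_analytic(p, spec.aif, t_min)
        else:
            Ct = ext_tofts_ct(p, spec.aif, t_min)
        S = _signal(spec, t1_from_concentration(Ct, relax_t))
        ys, xs = slice(row * ps, (row + 1) * ps), slice(col * ps, (col + 1) * ps)
        plane[ys, xs, :] = S
        kt_plane[ys, xs] = p.Ktrans
        ve_plane[ys, xs] = p.ve
        if vp_plane is not None:
            vp_plane[ys, xs] = p.vp

    # vascular strip: whole-blood concentration at the blood T10
    Cb = (1.0 - spec.hematocrit) * spec.aif.cp_minutes(t_min)
    Sb = _signal(spec, t1_from_concentration(Cb, relax_b))
    plane[ny_t:, :, :] = Sb

    if spec.quantize_signals:
        plane = np.round(plane)

    data = np.transpose(plane, (1, 0, 2))[:, :, np.newaxis, :]  # (X, Y, 1, T)
    series = DCESeries(data, frame_times, spec.acq,
                       provenance=f"synthetic {spec.model} phantom")
    if spec.noise_sigma_fraction > 0:
        series = add_gaussian_noise(series, spec.noise_sigma_fraction, spec.seed)

    tissue_mask = np.zeros((ny, nx), dtype=bool)
    tissue_mask[:ny_t, :] = True
    vascular_mask = ~tissue_mask
    truth = PhantomTruth(kt_plane, ve_plane, vp_plane,
                         tissue_mask, vascular_mask, spec)
    return series, truth


def add_gaussian_noise(series: DCESeries, sigma_fraction: float,
                       seed: int) -> DCESeries:
    """Add i.i.d. zero-mean Gaussian noise, sigma as a fraction of the
    per-pixel baseline mean; reproducible for a fixed seed."""
    if sigma_fraction < 0:
        raise ValueError("sigma_fraction must be non-negative")
    if sigma_fraction == 0:
        return DCESeries(series.data.copy(), series.frame_times.copy(),
                         series.acq, series.provenance)
    baseline = series.data[..., :series.acq.injection_frame].mean(axis=-1)
    sigma = sigma_fraction * baseline[..., np.newaxis]
    rng = np.random.default_rng(seed)
    noisy = series.data + rng.standard_normal(series.data.shape) * sigma
    return DCESeries(noisy, series.frame_times.copy(), series.acq,
                     provenance=series.provenance +
                     f" + gaussian noise sigma={sigma_fraction:g} seed={seed}")
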