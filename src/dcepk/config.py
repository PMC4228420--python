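"""Analysis configuration files (TOML or YAML).

The file mirrors the parameter tabs of an interactive session:

```toml
[mr_signal]
sequence_kind = "spgr"   # or "spin_echo"
TR = 5.0                 # ms
flip_angle = 30.0        # degrees
frame_interval = 0.5     # s

[ca]
injection_frame = 120
r1 = 4.5                 # 1/(s mM)
T10 = 1000.0             # ms
dose = 0.2               # mmol/kg

[aif]                    # either bi-exponential constants ...
a = [3.99, 4.78]         # kg/L
m = [0.144, 0.0111]      # 1/min
# file = "aif.txt"       # ... or a sampled two-column file

[rr]
Ktrans_r = 0.1           # 1/min
ve_r = 0.1

[fit]
bin_factor = 1
ftol = 1e-8
xtol = 1e-8
max_iter = 200
# init.Ktrans = 0.1      # per-parameter overrides
# bounds.ve = [1e-6, 1.0]
```
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .aif import BiexpAIF, SampledAIF, load_sampled_aif
from .fitting import ConfigurationError, FitConfig
from .signal_model import AcquisitionParams, RelaxationParams

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Parsed configuration; blocks absent from the file are None."""

    acq: AcquisitionParams | None = None
    relax: RelaxationParams | None = None
    aif: BiexpAIF | SampledAIF | None = None
    dose: float = 0.2
    rr_constants: tuple[float, float] | None = None
    fit: FitConfig | None = None
    bin_factor: int = 1

    def require(self, block: str):
        value = {"mr_signal": self.acq, "ca": self.relax, "aif": self.aif,
                 "rr": self.rr_constants}.get(block)
        if value is None:
            raise ConfigurationError(f"configuration is missing the [{block}] block")
        return value


def load_config(path) -> AnalysisConfig:
    """Load a TOML (``.toml``) or YAML (``.yaml``/``.yml``) config file."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        doc = yaml.safe_load(path.read_text()) or {}
    else:
        doc = tomllib.loads(path.read_text())

    cfg = AnalysisConfig()
    ca = doc.get("ca", {})
    sig = doc.get("mr_signal")
    if sig is not None:
        cfg.acq = AcquisitionParams(
            sequence_kind=sig.get("sequence_kind", "spgr"),
            TR=float(sig["TR"]),
            flip_angle=float(sig.get("flip_angle", 90.0)),
            frame_interval=float(sig.get("frame_interval", 1.0)),
            injection_frame=int(ca.get("injection_frame", 1)))
    if "r1" in ca:
        cfg.relax = RelaxationParams(r1=float(ca["r1"]),
                                     T10=float(ca.get("T10", 1000.0)))
    cfg.dose = float(ca.get("dose", 0.2))

    aif_block = doc.get("aif")
    if aif_block is not None:
        if "file" in aif_block:
            aif_path = Path(aif_block["file"])
            if not aif_path.is_absolute():
                aif_path = path.parent / aif_path
            cfg.aif = load_sampled_aif(aif_path)
        else:
            cfg.aif = BiexpAIF(
                D=float(aif_block.get("D", cfg.dose)),
                amplitudes=tuple(aif_block.get("a", (3.99, 4.78))),
                rates=tuple(aif_block.get("m", (0.144, 0.0111))))

    rr = doc.get("rr")
    if rr is not None:
        cfg.rr_constants = (float(rr["Ktrans_r"]), float(rr["ve_r"]))

    fit = doc.get("fit", {})
    cfg.fit = FitConfig(
        ftol=float(fit.get("ftol", 1e-8)),
        xtol=float(fit.get("xtol", 1e-8)),
        gtol=float(fit.get("gtol", 1e-8)),
        max_iter=int(fit.get("max_iter", 200)),
        init={k: float(v) for k, v in fit.get("init", {}).items()},
        bounds={k: (float(v[0]), float(v[1]))
                for k, v in fit.get("bounds", {}).items()})
    cfg.bin_factor = int(fit.get("bin_factor", 1))
    return cfg
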