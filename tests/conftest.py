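import numpy as np
import pytest

import dcepk as d


@pytest.fixture(scope="session")
def relax():
    return d.RelaxationParams(r1=4.5, T10=1000.0)


@pytest.fixture(scope="session")
def aif():
    return d.default_population_aif(D=0.2)


@pytest.fixture(scope="session")
def tofts_phantom():
    """Noise-free single-compartment validation object (session-wide)."""
    spec = d.default_tofts_spec()
    series, truth = d.generate(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def ext_phantom():
    """Noise-free extended-model validation object (session-wide)."""
    spec = d.default_ext_tofts_spec()
    series, truth = d.generate(spec)
    return spec, series, truth


@pytest.fixture()
def tiny_spec():
    """A small, fast phantom for I/O and CLI tests."""
    return d.PhantomSpec(
        model="tofts", Ktrans_values=(0.1, 0.2), ve_values=(0.2, 0.5),
        patch_size=2,
        acq=d.AcquisitionParams("spgr", TR=5.0, flip_angle=30.0,
                                frame_interval=0.5, injection_frame=10),
        duration=30.0, injection_time=5.0, vascular_strip_rows=2)


def patch_means(plane: np.ndarray, patch: int = 10) -> np.ndarray:
    """Ground-truth planes are constant per patch; pick each patch's value."""
    return plane[::patch, ::patch]
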