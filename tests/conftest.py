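import numpy as np
import pytest

from coldkin import evb
from coldkin.kinetic_models import HeatCapacityParams, TwoStateParams


@pytest.fixture(scope="session")
def two_state_fit():
    """Published two-state dead-end fit for the psychrophilic amylase."""
    return TwoStateParams(dH3=10.2, dS3=-0.00925, dHeq=32.0, dSeq=0.10746)


@pytest.fixture(scope="session")
def heat_capacity_fit():
    """Published activation heat-capacity fit to the same rate curve."""
    return HeatCapacityParams(dH0=-6.2, dS0=-0.06576, dCp=-1.13, T0=298.0)


@pytest.fixture(scope="session")
def scan_temps():
    """The standard eight-temperature ladder, 278-313 K in 5 K steps."""
    return np.arange(278.0, 314.0, 5.0)


@pytest.fixture(scope="session")
def marcus_system():
    """Equal harmonic diabats (k=40, d=1 A), uncoupled: lambda = 20 kcal/mol."""
    return evb.EVBSystem(
        evb.HarmonicSurface(40.0, 0.0), evb.HarmonicSurface(40.0, 1.0), 0.0
    )


@pytest.fixture(scope="session")
def coupled_system():
    """Same diabats with a 1 kcal/mol constant coupling."""
    return evb.EVBSystem(
        evb.HarmonicSurface(40.0, 0.0), evb.HarmonicSurface(40.0, 1.0), 1.0
    )


@pytest.fixture(scope="session")
def fast_protocol():
    """Short mapping protocol adequate for the toy Marcus systems."""
    return evb.MappingProtocol(
        n_windows=21, steps_per_window=3000, equilibration_steps=400, bin_width=0.5
    )


@pytest.fixture(scope="session")
def marcus_replicates(marcus_system, fast_protocol):
    """Eight replicate sampled profiles of the uncoupled Marcus system."""
    out = []
    for seed in range(8):
        fep = evb.run_fep(marcus_system, 298.15, fast_protocol, seed)
        prof, dia = evb.build_profiles(
            fep.windows, 298.15, bin_width=fast_protocol.bin_width,
            G_lambda=fep.G_lambda,
        )
        out.append((fep, prof, dia))
    return out
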