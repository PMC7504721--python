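import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sprscreen import (ArtifactModel, CompoundProfile, InjectionSchedule,
                       KineticModel, SurfaceDef)


@pytest.fixture
def c1r_surface() -> SurfaceDef:
    """Full-length 92 kDa ligand immobilized at 9200 RU (fragment of MW
    276 Da then has a theoretical Rmax of 27.6 RU)."""
    return SurfaceDef(name="C1r", ligand_mw=92000.0, immobilization=9200.0)


@pytest.fixture
def schedule() -> InjectionSchedule:
    return InjectionSchedule()


@pytest.fixture
def quiet() -> ArtifactModel:
    """Noise- and artifact-free instrument."""
    return ArtifactModel(noise_sd=0.0, excl_coeffs=(0.0, 0.0, 0.0))


@pytest.fixture
def clean_binder() -> CompoundProfile:
    return CompoundProfile(
        compound_id="CMP-T1", mw=276.0,
        kinetics=KineticModel.from_equilibrium(480e-6, kd_rate=1.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
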