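import dataclasses

import numpy as np
import pytest

from fibropet.imaging_core import AcquisitionMeta, ROIMask, VolumeGrid
from fibropet.phantom import KineticParams, PhantomConfig


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small thorax grid for fast unit tests (CT 32^2x24 @ 0.5 mm)."""
    return PhantomConfig(
        ct_shape=(32, 32, 24),
        ct_spacing_mm=0.5,
        pet_shape=(16, 16, 12),
        pet_spacing_mm=1.0,
    )


@pytest.fixture(scope="session")
def tiny_config_noisefree(tiny_config) -> PhantomConfig:
    return dataclasses.replace(tiny_config, ct_noise=False)


@pytest.fixture(scope="session")
def kinetics() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    return AcquisitionMeta(injected_activity_MBq=5.0, tracer_amount_nmol=1.5)


def make_ct(values, spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(values=np.asarray(values, dtype=float), spacing=spacing,
                      modality="CT")


def make_pet(values, spacing=(1.0, 1.0, 1.0), start=15.0, duration=10.0) -> VolumeGrid:
    return VolumeGrid(values=np.asarray(values, dtype=float), spacing=spacing,
                      modality="PET", frame_start_min=start,
                      frame_duration_min=duration)


def full_mask(shape, label="roi") -> ROIMask:
    return ROIMask(np.ones(shape, dtype=bool), label=label)
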