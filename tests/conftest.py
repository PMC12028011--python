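import numpy as np
import pytest

from bpfuse.data_model import (
    BpMriCase,
    ClinicalRecord,
    SequenceKind,
    SequenceVolume,
)
from bpfuse.encoder import EncoderSpec
from bpfuse.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_phantom_config() -> PhantomConfig:
    """A very small cohort for fast IO / pipeline tests."""
    return PhantomConfig(
        n_cases=10,
        prevalence=0.5,
        volume_shape=(8, 24, 24),
        spacing=(3.0, 1.0, 1.0),
        gland_semiaxes_mm=(8.0, 9.0, 9.0),
        lesion_radius_mm=(3.0, 5.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_config):
    cases, truth = generate_cohort(tiny_phantom_config)
    return cases, truth


@pytest.fixture(scope="session")
def desk_encoder_spec() -> EncoderSpec:
    return EncoderSpec(stage_widths=(4, 8), blocks_per_stage=(1, 1), dropout=0.2,
                       in_channels=1)


def make_case(case_id="c0", shape=(6, 12, 12), spacing=(3.0, 1.0, 1.0), label=0,
              seed=0, with_mask=True) -> BpMriCase:
    rng = np.random.default_rng(seed)
    volumes = {
        kind: SequenceVolume(
            voxels=rng.normal(100.0, 10.0, size=shape).astype(np.float32),
            spacing=spacing,
            kind=kind,
            case_id=case_id,
        )
        for kind in SequenceKind
    }
    mask = None
    if with_mask:
        mask = np.zeros(shape, dtype=np.uint8)
        mask[1:-1, 3:-3, 3:-3] = 1
    clinical = ClinicalRecord(age=64.0, psa=7.2, site="site_a", field_strength=3.0,
                              manufacturer="vendor_x")
    return BpMriCase(case_id=case_id, volumes=volumes, clinical=clinical,
                     label=label, gland_mask=mask)


@pytest.fixture
def simple_case() -> BpMriCase:
    return make_case()
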