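import numpy as np
import pytest

from msdisrupt.architecture import (
    DI_CA_13,
    MONO_C_18,
    default_architecture,
)
from msdisrupt.readproc import build_read_table
from msdisrupt.simulate import SimConfig, StutterModel, generate_library

NO_STUTTER = StutterModel(r0=0.0)


@pytest.fixture(scope="session")
def mono_arch():
    return default_architecture(MONO_C_18)


@pytest.fixture(scope="session")
def ca_arch():
    return default_architecture(DI_CA_13)


@pytest.fixture(scope="session")
def clean_ca_library(ca_arch):
    """Error-free disrupted CA library: all knobs at zero except conversion."""
    cfg = SimConfig(
        arch=ca_arch,
        n_templates=60,
        conversion_rate=0.66,
        first_copies_per_template=4.0,
        reads_per_first_copy=6.0,
        stutter=NO_STUTTER,
        seq_sub_rate=0.0,
        dropout_slope=0.0,
        seed=11,
    )
    pairs, truth = generate_library(cfg)
    reads = build_read_table(pairs, ca_arch)
    return cfg, pairs, truth, reads


@pytest.fixture
def rng():
    return np.random.default_rng(0)
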