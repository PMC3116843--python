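import pytest

from mirmeth.synth import (
    DEMETHYLATED_SAMPLE,
    REFERENCE_SAMPLE,
    WorldConfig,
    generate_expression,
    generate_mbd_reads,
    generate_qpcr,
    generate_world,
)


@pytest.fixture(scope="session")
def default_config():
    return WorldConfig(seed=7)


@pytest.fixture(scope="session")
def zero_noise_config():
    return WorldConfig(seed=7, replicate_cv=0.0, qpcr_ct_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise_world(zero_noise_config):
    return generate_world(zero_noise_config)


@pytest.fixture(scope="session")
def zero_noise_inputs(zero_noise_config, zero_noise_world):
    cfg, world = zero_noise_config, zero_noise_world
    m = world.manifest
    return {
        "world": world,
        "manifest": m,
        "config": cfg,
        "ref_reads": generate_mbd_reads(m, cfg, REFERENCE_SAMPLE),
        "demeth_reads": generate_mbd_reads(m, cfg, DEMETHYLATED_SAMPLE),
        "expression": generate_expression(m, cfg),
        "qpcr": generate_qpcr(m, cfg),
    }
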