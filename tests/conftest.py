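"""Shared fixtures: tiny synthetic cohorts and desk-scale configs.

Everything is generated programmatically at session scope so the slowest
pieces (volume rendering) run once.
"""

import numpy as np
import pytest

from thcpred import CohortConfig, NetworkConfig, generate_cohort


TINY_SHAPE = (16, 16, 8)


@pytest.fixture(scope="session")
def tiny_cohort():
    """40 patients, 16x16x8 volumes, strong planted signal."""
    cfg = CohortConfig(
        n_patients=40, volume_shape=TINY_SHAPE, prevalence=0.5,
        signal_strength=5.0, noise_sd=0.05, seed=11,
    )
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """40 patients with no label signal at all."""
    cfg = CohortConfig(
        n_patients=40, volume_shape=TINY_SHAPE, prevalence=0.5,
        signal_strength=0.0, noise_sd=0.05, seed=13,
    )
    return generate_cohort(cfg), cfg


@pytest.fixture()
def tiny_net_config():
    """A network config small enough for second-scale training."""
    return NetworkConfig(
        volume_shape=TINY_SHAPE,
        encoder_channels=(4, 8, 16),
        bottleneck_dim=16,
        fc_widths=(16, 8),
        epochs=2,
        batch_size=8,
        seed=3,
    )
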