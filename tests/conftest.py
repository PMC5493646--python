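import numpy as np
import pytest

from eigensig import SimConfig, generate_batches, two_step_merge


@pytest.fixture(scope="session")
def study_cohort():
    """Default study conditions: 4 batches x 20 samples, 500 genes,
    20 planted genes shifted by 2 log2 units, batch offsets of scale 3."""
    config = SimConfig(seed=11)
    batches, truth = generate_batches(config)
    return config, batches, truth


@pytest.fixture(scope="session")
def merged_cohort(study_cohort):
    _, batches, truth = study_cohort
    merged, report = two_step_merge(batches)
    return merged, report, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Lighter cohort (200 genes) for diagnostics that do not need
    signature selection to succeed."""
    config = SimConfig(
        n_batches=4,
        genes_per_batch=200,
        samples_per_batch=(20, 20, 20, 20),
        n_planted_genes=20,
        effect_size=1.5,
        batch_shift_scale=3.0,
        noise_sd=0.5,
        seed=7,
    )
    batches, truth = generate_batches(config)
    return config, batches, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
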