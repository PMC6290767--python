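import numpy as np
import pytest

from exomir import (
    ContrastSpec,
    generate_counts,
    run_contrast,
    default_discovery_design,
)
from exomir.preprocess import filter_low_abundance, qc_filter_samples


@pytest.fixture(scope="session")
def gbm_hc_contrast():
    return ContrastSpec("GBM", "HC")


@pytest.fixture(scope="session")
def default_cohort():
    """The frozen 12v12 synthetic cohort with the 26 planted effects,
    QC'd and abundance-filtered."""
    design = default_discovery_design(seed=42)
    matrix, meta, truth = generate_counts(design)
    filtered = filter_low_abundance(qc_filter_samples(matrix))
    return filtered, meta, truth


@pytest.fixture(scope="session")
def default_de_records(default_cohort, gbm_hc_contrast):
    matrix, meta, _ = default_cohort
    return run_contrast(matrix, meta, gbm_hc_contrast)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
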