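import numpy as np
import pandas as pd
import pytest

from silacnet import (
    ComplexSpec,
    GeneratorConfig,
    RatioMatrix,
    SampleDesign,
    generate_dataset,
    make_signature_library,
)


@pytest.fixture
def design():
    return SampleDesign()


@pytest.fixture
def library(design):
    return make_signature_library(design)


@pytest.fixture
def default_generator_config(library):
    return GeneratorConfig(
        complex_specs=tuple(library),
        n_background=300,
        noise_cv=0.2,
        seed=0,
    )


@pytest.fixture
def noiseless_dataset(design, library):
    config = GeneratorConfig(
        complex_specs=tuple(library),
        n_background=50,
        noise_cv=0.0,
        apply_detection=False,
        seed=0,
    )
    return generate_dataset(design, config)


@pytest.fixture
def noisy_dataset(design, default_generator_config):
    return generate_dataset(design, default_generator_config)


def random_ratio_matrix(design, n_proteins, seed=0, missing_fraction=0.0):
    """Strictly positive random ratio matrix with optional MCAR missingness."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(0.0, 0.5, size=(n_proteins, design.n_samples))
    if missing_fraction > 0:
        mask = rng.random(values.shape) < missing_fraction
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(
        values,
        index=[f"p{i:04d}" for i in range(n_proteins)],
        columns=design.sample_names,
    )
    return RatioMatrix(values=frame, design=design)
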