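from dataclasses import replace

import numpy as np
import pytest

from heartprint.records import preprocess
from heartprint.synth import sample_population, synthesize_record

FS = 500.0


@pytest.fixture(scope="session")
def population():
    """Five synthetic subjects with default (noisy) parameters."""
    return sample_population(5, seed=42)


@pytest.fixture(scope="session")
def clean_records(population):
    """One noise-free, wander-free 20 s record per subject."""
    return [
        synthesize_record(replace(p, noise_sd=0.0, wander_amp=0.0),
                          20.0, FS, seed=7)
        for p in population
    ]


@pytest.fixture(scope="session")
def noisy_records(population):
    return [synthesize_record(p, 20.0, FS, seed=7) for p in population]


@pytest.fixture(scope="session")
def clean_preprocessed(clean_records):
    return [preprocess(r) for r in clean_records]
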