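import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from va_validate import (
    CauseList,
    GeneratorConfig,
    SymptomDictionary,
    VADataset,
    generate_dataset,
    generate_probbase,
)


@pytest.fixture
def abc_causes():
    return CauseList("adult", ("A", "B", "C"))


@pytest.fixture
def small_dict():
    return SymptomDictionary(("s1", "s2", "s3"), (False, False, True))


@pytest.fixture
def toy_dataset(abc_causes, small_dict):
    """Four records, three symptoms, one missing cell."""
    return VADataset(
        record_ids=np.array(["r1", "r2", "r3", "r4"], dtype=object),
        module="adult",
        sites=np.array(["site_1"] * 4, dtype=object),
        gold_causes=np.array(["A", "A", "B", "C"], dtype=object),
        symptoms=np.array(
            [[1, 0, 1],
             [1, 1, 0],
             [0, 1, -1],
             [0, 0, 0]], dtype=np.int8),
        cause_list=abc_causes,
        symptom_dict=small_dict,
    )


@pytest.fixture
def separable_config():
    """Noise-free, fully separable generator: each record equals its cause row."""
    return GeneratorConfig(
        module="adult", n_causes=6, n_symptoms=30, n_records=1200,
        signature_strength=1.0, background_rate=0.0, signature_size=3,
        noise_eps=0.0, missing_rate=0.0, hce_fraction=0.2, n_sites=2, seed=11,
    )


@pytest.fixture
def separable_dataset(separable_config):
    pb = generate_probbase(separable_config)
    return generate_dataset(pb, separable_config), pb
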