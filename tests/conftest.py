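import numpy as np
import pytest

import ecgfuse as ef
from ecgfuse.synthetic_data import zero_noise


def make_sources(profiles, n_records=2, n_beats=80, seed0=100):
    """Materialize in-memory DatabaseSources from generator profiles."""
    sources = []
    for k, p in enumerate(profiles):
        recs = [
            ef.generate_record(p, n_beats, seed=seed0 * (k + 1) + i,
                               record_id=f"r{i}")
            for i in range(n_records)
        ]
        sources.append(
            ef.DatabaseSource(
                name=p.name,
                records=[(r, a) for r, a, _ in recs],
                lead_priority=[p.lead],
            )
        )
    return sources


@pytest.fixture(scope="session")
def class_map():
    return ef.build_class_map()


@pytest.fixture(scope="session")
def clean_sources():
    """3-database corpus with all stochastic distortion off."""
    return make_sources([zero_noise(p) for p in ef.default_profiles()])


@pytest.fixture(scope="session")
def noisy_sources():
    """3-database corpus under the default (low-noise) study conditions."""
    return make_sources(ef.default_profiles())


@pytest.fixture(scope="session")
def clean_dataset(clean_sources):
    return ef.integrate(clean_sources, preprocessor="self").dataset


@pytest.fixture()
def record360():
    rec, ann, labels = ef.generate_record(
        zero_noise(ef.default_profiles()[0]), 15, seed=42
    )
    return rec, ann, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
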