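"""Shared fixtures: small synthetic bundles generated at test time."""

import numpy as np
import pytest

from relnose.signal_io import DatasetBundle, Sample
from relnose.synthgas import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle() -> DatasetBundle:
    """A cheap, well-separated 5-class bundle of [240, 8] samples (short
    breath-style recordings, equal-interval reduction path)."""
    config = SynthConfig(
        n_classes=5, samples_per_class=[8, 8, 8, 8, 8], n_points=1200,
        gas_on=150, gas_off=900, rise_tau=120.0, decay_tau=180.0,
        noise_sd=0.02, separation=1.5, class_prefix="unit", role="meta_test",
        seed=123)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def tiny_bundle() -> DatasetBundle:
    """Even smaller 4-class bundle for training-loop mechanics."""
    config = SynthConfig(
        n_classes=4, samples_per_class=[6, 6, 6, 6], n_points=1000,
        gas_on=120, gas_off=750, rise_tau=100.0, decay_tau=150.0,
        noise_sd=0.02, separation=1.5, class_prefix="tiny", role="meta_test",
        seed=321)
    return generate_dataset(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def make_sample(matrix, label="a", source="meta_test") -> Sample:
    return Sample(np.asarray(matrix, dtype=float), label=label, source=source)
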