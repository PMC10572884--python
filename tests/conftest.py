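"""Shared fixtures: small phantom cohorts and session-scoped trained models.

Training fixtures are session-scoped because CPU training, while fast at
the tiny preset, is the dominant cost of the suite; several tests share
one trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from scintiseg.experiment import (
    ExperimentConfig,
    dataset_from_phantoms,
    train_model,
)
from scintiseg.experiment import _otsu_labels, _two_class_labels  # test-internal reuse
from scintiseg.network import build_double_unet, tiny_config
from scintiseg.phantom import PhantomConfig, generate_cohort


TINY_VIEW = (64, 64)


def tiny_phantom_config(**overrides) -> PhantomConfig:
    """High-contrast desk-scale phantom settings used across the suite."""
    defaults = dict(
        view_shape=TINY_VIEW,
        n_lesions=2,
        lesion_sigma_frac=(0.03, 0.05),
        artifact_flags=frozenset({"bladder", "injection_site"}),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 positive + 4 negative 64x64 phantoms."""
    return generate_cohort(8, 4, base_seed=7, config=tiny_phantom_config())


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return dataset_from_phantoms(tiny_cohort, "tiny")


@pytest.fixture(scope="session")
def overfit_config():
    return ExperimentConfig(
        n_folds=2,
        iterations=200,
        iteration_unit="steps",
        learning_rate=3e-3,
        batch_size=4,
        nm_method="otsu",
        network=tiny_config(),
        seed=3,
        use_validation=False,
    )


@pytest.fixture(scope="session")
def trained_three_class(tiny_dataset, overfit_config):
    """Tiny three-class Double U-Net overfit on the 8 positive phantoms
    (Otsu NM labels, ~200 steps)."""
    from scintiseg.experiment import _fold_network_config

    positives = list(tiny_dataset.positives)
    maps = _otsu_labels(positives)
    model = build_double_unet(_fold_network_config(overfit_config, 3, 1))
    train_model(model, [s.image for s in positives], maps, overfit_config)
    return model


@pytest.fixture(scope="session")
def trained_two_class(tiny_dataset, overfit_config):
    """Tiny two-class (background vs metastasis) model trained on positives
    only — the prerequisite model for negative mining."""
    from dataclasses import replace

    from scintiseg.experiment import _fold_network_config

    cfg = replace(overfit_config, nm_method="none", iterations=150)
    positives = list(tiny_dataset.positives)
    maps = _two_class_labels(positives)
    model = build_double_unet(_fold_network_config(cfg, 2, 2))
    train_model(model, [s.image for s in positives], maps, cfg)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
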