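"""Cross-validation harness: fold hygiene, protocol wiring, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from scintiseg.evaluation import aggregate_folds
from scintiseg.experiment import (
    DatasetSpec,
    ExperimentConfig,
    ExperimentConfigError,
    Sample,
    dataset_from_phantoms,
    make_folds,
    run_cv,
    run_transfer,
)
from scintiseg.network import tiny_config
from scintiseg.phantom import generate_cohort

from conftest import tiny_phantom_config


def small_spec(n_pos=10, n_neg=3, seed=50):
    cohort = generate_cohort(n_pos, n_neg, seed, tiny_phantom_config())
    return dataset_from_phantoms(cohort, "t")


@pytest.fixture(scope="module")
def spec10():
    return small_spec()


def fast_config(**overrides):
    defaults = dict(
        n_folds=2,
        iterations=25,
        iteration_unit="steps",
        learning_rate=3e-3,
        batch_size=4,
        nm_method="otsu",
        network=tiny_config(),
        seed=5,
        use_validation=False,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


class TestMakeFolds:
    def test_each_positive_in_exactly_one_test_fold(self, spec10):
        cfg = fast_config(n_folds=5)
        folds = make_folds(spec10, cfg)
        seen = [i for f in folds for i in f.test]
        assert sorted(seen) == list(range(10))

    def test_no_leakage_within_folds(self, spec10):
        for f in make_folds(spec10, fast_config(n_folds=5)):
            assert not (set(f.train) & set(f.test))
            assert not (set(f.validation) & set(f.test))
            assert not (set(f.train) & set(f.validation))

    def test_split_ratio_8_1_1(self):
        spec = small_spec(n_pos=100, n_neg=0)
        cfg = fast_config(n_folds=10, use_validation=True)
        for f in make_folds(spec, cfg):
            assert len(f.test) == 10
            assert len(f.validation) == 10
            assert len(f.train) == 80

    def test_add_negatives_appends_all_to_training_only(self, spec10):
        with_neg = make_folds(spec10, fast_config(add_negatives=True))
        without = make_folds(spec10, fast_config(add_negatives=False))
        for fw, fo in zip(with_neg, without):
            assert fw.train_negatives == (0, 1, 2)
            assert fo.train_negatives == ()
            # negatives change training composition only: test sets identical
            assert fw.test == fo.test
            assert fw.train == fo.train

    def test_same_seed_same_folds(self, spec10):
        a = make_folds(spec10, fast_config())
        b = make_folds(spec10, fast_config())
        assert a == b

    def test_different_seed_different_folds(self, spec10):
        a = make_folds(spec10, fast_config(seed=5))
        b = make_folds(spec10, fast_config(seed=6))
        assert any(fa.test != fb.test for fa, fb in zip(a, b))

    def test_too_few_positives(self, spec10):
        with pytest.raises(ExperimentConfigError):
            make_folds(spec10, fast_config(n_folds=11))

    def test_negative_with_lesions_rejected(self):
        bad = Sample(image=np.zeros((8, 8)), m_mask=np.ones((8, 8), bool))
        with pytest.raises(ExperimentConfigError):
            DatasetSpec(positives=(), negatives=(bad,))


class TestRunCV:
    def test_smoke_run_emits_valid_records(self, spec10):
        results = run_cv(spec10, fast_config())
        assert [r.fold_id for r in results] == [1, 2]
        for r in results:
            assert 0.0 <= r.metrics.precision <= 100.0
            assert 0.0 <= r.metrics.sensitivity <= 100.0
            assert 0.0 <= r.metrics.f1 <= 100.0
        agg = aggregate_folds(results)
        assert 0.0 <= agg.f1 <= 100.0

    def test_seeded_determinism(self, spec10):
        cfg = fast_config(iterations=10)
        a = run_cv(spec10, cfg)
        b = run_cv(spec10, cfg)
        assert [r.metrics for r in a] == [r.metrics for r in b]

    def test_baseline_two_class_protocol(self, spec10):
        # nm_method "none" trains the original binary task
        results = run_cv(spec10, fast_config(iterations=10, nm_method="none"))
        assert len(results) == 2
        for r in results:
            assert r.counts is not None

    def test_mining_protocol_smoke(self, spec10):
        cfg = fast_config(iterations=10, nm_method="mining", mining_iterations=10)
        results = run_cv(spec10, cfg)
        assert len(results) == 2

    def test_validation_checkpoint_path_runs(self, spec10):
        cfg = fast_config(iterations=20, use_validation=True)
        results = run_cv(spec10, cfg)
        assert len(results) == 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ExperimentConfigError):
            ExperimentConfig(nm_method="magic").validate()
        with pytest.raises(ExperimentConfigError):
            ExperimentConfig(iterations=0).validate()


class TestYamlConfig:
    def test_round_trip_from_yaml(self, tmp_path):
        from scintiseg.experiment import config_from_yaml

        p = tmp_path / "exp.yaml"
        p.write_text(
            "n_folds: 2\n"
            "iterations: 40\n"
            "iteration_unit: steps\n"
            "nm_method: otsu\n"
            "loss: focal_tversky\n"
            "loss_config: {alpha: 0.3, beta: 0.7, gamma: 0.75}\n"
            "network: {input_shape: [64, 64], encoder_widths: [8, 16, 32]}\n"
            "seed: 4\n"
        )
        cfg = config_from_yaml(p)
        assert cfg.n_folds == 2
        assert cfg.loss == "focal_tversky"
        assert cfg.network.encoder_widths == (8, 16, 32)
        assert cfg.loss_config.beta == 0.7


class TestTransfer:
    def test_init_state_seeds_fold_models(self, spec10):
        from scintiseg.network import build_double_unet

        donor = build_double_unet(tiny_config(seed=77))
        state = donor.state_dict()
        # a 0-ish budget fine-tune keeps weights near the donor: verify the
        # loading path by checking run_cv accepts and uses the state
        results = run_cv(spec10, fast_config(iterations=1), init_state=state)
        assert len(results) == 2

    def test_two_phase_pipeline_deterministic(self):
        pre = small_spec(n_pos=6, n_neg=2, seed=60)
        fine = small_spec(n_pos=6, n_neg=2, seed=61)
        cfg = fast_config(iterations=8)
        a = run_transfer(pre, fine, cfg)
        b = run_transfer(pre, fine, cfg)
        assert [r.metrics for r in a] == [r.metrics for r in b]

    def test_transfer_requires_three_class(self):
        pre = small_spec(n_pos=6, n_neg=0, seed=60)
        with pytest.raises(ExperimentConfigError):
            run_transfer(pre, pre, fast_config(nm_method="none"))
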