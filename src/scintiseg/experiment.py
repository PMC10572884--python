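"""Cross-validation training harness.

Implements the experimental protocol around the segmentation model:
k-fold cross-validation with an 8:1:1 train/validation/test split of the
positive samples, optional augmentation of every fold's *training* set with
the lesion-free negative cohort, label construction per fold by either NM
route (Otsu thresholding or negative mining), and a two-phase transfer
variant that pre-trains on one cohort and fine-tunes per fold on another.

All randomness (fold splits, weight init, batch shuffling) derives from one
master seed by fixed arithmetic, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import labeling
from .evaluation import FoldResult, aggregate_folds, confusion, metrics_from_counts
from .labeling import LabelMap, encode_three_class, make_nm_mask_otsu
from .losses import LossConfig, masked_multiclass_loss
from .network import DoubleUNet, NetworkConfig, build_double_unet, predict
from .nn import Adam

__all__ = [
    "Sample",
    "DatasetSpec",
    "ExperimentConfig",
    "FoldAssignment",
    "make_folds",
    "train_model",
    "run_cv",
    "run_transfer",
    "dataset_from_phantoms",
    "config_from_yaml",
]

logger = logging.getLogger(__name__)


class ExperimentConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Sample:
    """One training/evaluation image with its binary metastasis annotation."""

    image: np.ndarray  # (H, W) intensities in [0, 255]
    m_mask: np.ndarray  # (H, W) bool
    sample_id: str = ""

    @property
    def is_positive(self) -> bool:
        return bool(self.m_mask.any())


@dataclass(frozen=True)
class DatasetSpec:
    """Positive (lesion-bearing) and negative (lesion-free) cohorts."""

    positives: tuple[Sample, ...]
    negatives: tuple[Sample, ...] = ()
    cohort_tag: str = ""

    def __post_init__(self):
        for s in self.negatives:
            if s.m_mask.any():
                raise ExperimentConfigError(
                    f"negative sample {s.sample_id!r} has a nonempty M mask"
                )


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol hyperparameters.

    ``iterations`` counts epochs over the fold's training set by default
    (``iteration_unit="epochs"``); set ``iteration_unit="steps"`` to count
    optimiser steps instead, which is the natural unit for desk-scale runs.
    """

    n_folds: int = 10
    split_ratio: tuple[int, int, int] = (8, 1, 1)
    learning_rate: float = 1e-4
    batch_size: int = 4
    iterations: int = 500
    iteration_unit: str = "epochs"  # "epochs" | "steps"
    nm_method: str = "otsu"  # "none" | "otsu" | "mining"
    add_negatives: bool = False
    loss: str = "dice"  # "dice" | "focal_tversky"
    loss_config: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    mining_iterations: int | None = None  # defaults to ``iterations``
    eval_averaging: str = "micro"  # "micro" | "macro"
    use_validation: bool = True
    max_restarts: int = 2  # seeded re-inits after an M-class training collapse
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 1:
            raise ExperimentConfigError("n_folds must be >= 1")
        if any(r <= 0 for r in self.split_ratio):
            raise ExperimentConfigError("split ratios must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.iterations < 1:
            raise ExperimentConfigError("hyperparameters must be positive")
        if self.nm_method not in ("none", "otsu", "mining"):
            raise ExperimentConfigError(f"unknown nm_method {self.nm_method!r}")
        if self.iteration_unit not in ("epochs", "steps"):
            raise ExperimentConfigError(f"unknown iteration_unit {self.iteration_unit!r}")
        if self.loss not in ("dice", "focal_tversky"):
            raise ExperimentConfigError(f"unknown loss {self.loss!r}")


@dataclass(frozen=True)
class FoldAssignment:
    """Index sets of one fold (indices into ``spec.positives`` /
    ``spec.negatives``)."""

    fold_id: int
    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    train_negatives: tuple[int, ...] = ()

    def assert_no_leakage(self) -> None:
        tr, va, te = set(self.train), set(self.validation), set(self.test)
        if (tr & te) or (va & te) or (tr & va):
            raise ExperimentConfigError(f"fold {self.fold_id}: overlapping splits")


def _derive_seed(master: int, *salts: int) -> int:
    s = master % (2**31)
    for salt in salts:
        s = (s * 1_000_003 + salt * 7919 + 23) % (2**31)
    return s


def make_folds(spec: DatasetSpec, config: ExperimentConfig) -> list[FoldAssignment]:
    """Partition the positives into ``n_folds`` disjoint test sets; split the
    remainder of each fold train:validation per ``split_ratio``; optionally
    attach every negative to each fold's training set."""
    config.validate()
    n_pos = len(spec.positives)
    if n_pos < config.n_folds:
        raise ExperimentConfigError(
            f"{n_pos} positives cannot fill {config.n_folds} folds"
        )
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    perm = rng.permutation(n_pos)
    test_sets = np.array_split(perm, config.n_folds)
    tr_r, va_r, _ = config.split_ratio
    folds = []
    all_negs = tuple(range(len(spec.negatives))) if config.add_negatives else ()
    for k, test in enumerate(test_sets, start=1):
        rest = np.array([i for i in perm if i not in set(test.tolist())])
        fold_rng = np.random.default_rng(_derive_seed(config.seed, 2, k))
        rest = fold_rng.permutation(rest)
        n_val = max(1, int(round(len(rest) * va_r / (tr_r + va_r)))) if config.use_validation else 0
        fold = FoldAssignment(
            fold_id=k,
            train=tuple(int(i) for i in rest[n_val:]),
            validation=tuple(int(i) for i in rest[:n_val]),
            test=tuple(int(i) for i in test.tolist()),
            train_negatives=all_negs,
        )
        fold.assert_no_leakage()
        folds.append(fold)
    return folds


# -- label construction ------------------------------------------------------

def _two_class_labels(samples: list[Sample]) -> list[np.ndarray]:
    """Binary protocol: class 0 = everything else, class 1 = metastasis."""
    return [s.m_mask.astype(np.uint8) for s in samples]


def _otsu_labels(samples: list[Sample]) -> list[np.ndarray]:
    out = []
    for s in samples:
        nm = make_nm_mask_otsu(s.image, s.m_mask)
        out.append(encode_three_class(nm, s.m_mask).classes)
    return out


def _mining_labels(
    samples: list[Sample], miner: DoubleUNet
) -> list[np.ndarray]:
    positives = [s for s in samples if s.is_positive]
    negatives = [s for s in samples if not s.is_positive]
    nm_pos = labeling.mine_positive_masks(
        miner, [s.image for s in positives], [s.m_mask for s in positives]
    )
    nm_neg = labeling.mine_negative_masks(miner, [s.image for s in negatives])
    by_id = {}
    for s, nm in zip(positives + negatives, list(nm_pos) + list(nm_neg)):
        by_id[id(s)] = encode_three_class(nm, s.m_mask).classes
    return [by_id[id(s)] for s in samples]


# -- training ----------------------------------------------------------------

def _one_hot_batch(class_maps: list[np.ndarray], n_classes: int) -> np.ndarray:
    stack = np.stack(class_maps)
    return np.eye(n_classes, dtype=np.float32)[stack].transpose(0, 3, 1, 2)


def train_model(
    model: DoubleUNet,
    images: list[np.ndarray],
    class_maps: list[np.ndarray],
    config: ExperimentConfig,
    val_images: list[np.ndarray] | None = None,
    val_class_maps: list[np.ndarray] | None = None,
    dual_output: bool | None = None,
) -> dict:
    """Train ``model`` in place; returns a history dict.

    When a validation set is given, validation loss is tracked every
    training epoch (or every ``max(total_steps // 10, 1)`` steps in step
    mode) and the best-scoring weights are restored at the end.
    """
    n_classes = model.config.n_classes
    n = len(images)
    if n == 0:
        raise ExperimentConfigError("no training images")
    dual = model.config.dual_output if dual_output is None else dual_output
    x_all = np.stack([np.asarray(im, dtype=np.float32) for im in images])[:, None]
    y_all = _one_hot_batch(class_maps, n_classes)
    if val_images:
        xv = np.stack([np.asarray(im, dtype=np.float32) for im in val_images])[:, None]
        yv = _one_hot_batch(val_class_maps, n_classes)
    rng = np.random.default_rng(_derive_seed(config.seed, 3, model.config.seed))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    if config.iteration_unit == "epochs":
        total_steps = config.iterations * steps_per_epoch
    else:
        total_steps = config.iterations
    eval_every = steps_per_epoch if config.iteration_unit == "epochs" else max(
        total_steps // 10, 1
    )

    def batch_loss(xb, yb):
        out1, out2 = model.forward(xb)
        loss = masked_multiclass_loss(yb, out2, config.loss_config, base=config.loss)
        if dual:
            loss = (
                loss
                + masked_multiclass_loss(yb, out1, config.loss_config, base=config.loss)
            ) * 0.5
        return loss

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    order = rng.permutation(n)
    pos = 0
    for step in range(total_steps):
        if pos + config.batch_size > n and n >= config.batch_size:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + config.batch_size]
        if idx.size == 0:
            order = rng.permutation(n)
            pos = 0
            idx = order[: config.batch_size]
        pos += config.batch_size
        opt.zero_grad()
        loss = batch_loss(x_all[idx], y_all[idx])
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.data))
        if val_images and (step + 1) % eval_every == 0:
            vl = float(batch_loss(xv, yv).data)
            history["val_loss"].append(vl)
            if vl < best_val:
                best_val = vl
                best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


# -- evaluation --------------------------------------------------------------

def _evaluate(
    model: DoubleUNet, samples: list[Sample], config: ExperimentConfig
) -> tuple:
    positive_class = model.config.n_classes - 1
    counts = None
    per_image = []
    for s in samples:
        pred = predict(model, s.image)
        truth = np.where(s.m_mask, positive_class, 0).astype(np.uint8)
        c = confusion(pred.argmax_classes, truth, positive_class=positive_class)
        per_image.append(metrics_from_counts(c))
        counts = c if counts is None else counts + c
    if config.eval_averaging == "macro":
        return aggregate_folds(per_image), counts
    return metrics_from_counts(counts), counts


# -- protocol runners --------------------------------------------------------

def _fold_network_config(config: ExperimentConfig, n_classes: int, salt: int) -> NetworkConfig:
    return replace(
        config.network,
        n_classes=n_classes,
        seed=_derive_seed(config.seed, 4, salt),
    )


def _build_fold_labels(
    train_samples: list[Sample], config: ExperimentConfig, fold_id: int
) -> tuple[list[np.ndarray], int]:
    """Class maps for the fold's training (and validation) samples, plus the
    class count of the protocol."""
    if config.nm_method == "none":
        return _two_class_labels(train_samples), 2
    if config.nm_method == "otsu":
        return _otsu_labels(train_samples), 3
    # negative mining: train a two-class miner on this fold's positive
    # training samples only (no leakage), then harvest its false positives
    miner_cfg = _fold_network_config(config, 2, 100 + fold_id)
    miner = build_double_unet(miner_cfg)
    miner_iters = config.mining_iterations or config.iterations
    positives = [s for s in train_samples if s.is_positive]
    train_model(
        miner,
        [s.image for s in positives],
        _two_class_labels(positives),
        replace(config, iterations=miner_iters),
    )
    return _mining_labels(train_samples, miner), 3


def run_cv(
    spec: DatasetSpec,
    config: ExperimentConfig,
    init_state: dict | None = None,
) -> list[FoldResult]:
    """Run the full cross-validation protocol and return per-fold metrics.

    ``init_state`` (a model state dict) seeds every fold's weights, which is
    how the transfer protocol warm-starts fine-tuning.
    """
    config.validate()
    folds = make_folds(spec, config)
    results = []
    for fold in folds:
        train_samples = [spec.positives[i] for i in fold.train]
        val_samples = [spec.positives[i] for i in fold.validation]
        neg_samples = [spec.negatives[i] for i in fold.train_negatives]
        fit_samples = train_samples + neg_samples
        try:
            class_maps, n_classes = _build_fold_labels(fit_samples, config, fold.fold_id)
            val_maps = None
            val_imgs = None
            if val_samples and config.use_validation:
                if config.nm_method == "none":
                    val_maps = _two_class_labels(val_samples)
                else:
                    val_maps = _otsu_labels(val_samples)
                val_imgs = [s.image for s in val_samples]
            model = None
            # small overlap-trained networks occasionally collapse into an
            # all-background basin at unlucky initialisations; detect the
            # degenerate fit on the training set and retry from a different
            # derived seed (deterministic, bounded)
            for attempt in range(config.max_restarts + 1):
                model = build_double_unet(
                    _fold_network_config(
                        config, n_classes, fold.fold_id + 1000 * attempt
                    )
                )
                if init_state is not None:
                    model.load_state_dict(init_state)
                history = train_model(
                    model,
                    [s.image for s in fit_samples],
                    class_maps,
                    config,
                    val_images=val_imgs,
                    val_class_maps=val_maps,
                )
                if not np.isfinite(history["train_loss"][-1]):
                    raise FloatingPointError("training diverged")
                if not _m_class_collapsed(model, train_samples):
                    break
                logger.warning(
                    "fold %d: M-class collapse on the training set "
                    "(attempt %d); retrying with a new init seed",
                    fold.fold_id,
                    attempt + 1,
                )
        except FloatingPointError:
            logger.warning("fold %d diverged; recording empty metrics", fold.fold_id)
            results.append(
                FoldResult(fold.fold_id, metrics_from_counts(confusion(
                    np.zeros((1, 1)), np.zeros((1, 1))
                )))
            )
            continue
        test_samples = [spec.positives[i] for i in fold.test]
        metrics, counts = _evaluate(model, test_samples, config)
        results.append(FoldResult(fold.fold_id, metrics, counts))
    return results


def _m_class_collapsed(model: DoubleUNet, train_positives: list[Sample]) -> bool:
    """True when the trained model finds no metastasis pixel at all on its
    own positive training samples — the signature of the degenerate basin."""
    if not train_positives:
        return False
    positive_class = model.config.n_classes - 1
    tp = 0
    for s in train_positives:
        pred = predict(model, s.image)
        tp += int(np.count_nonzero((pred.argmax_classes == positive_class) & s.m_mask))
    return tp == 0


def run_transfer(
    pretrain_spec: DatasetSpec,
    finetune_spec: DatasetSpec,
    config: ExperimentConfig,
    pretrain_config: ExperimentConfig | None = None,
) -> list[FoldResult]:
    """Two-phase protocol: one pre-training pass over the full pre-training
    cohort (Otsu NM masks, negatives included), then per-fold fine-tuning on
    the target cohort starting from the pre-trained weights."""
    config.validate()
    pre_cfg = pretrain_config or config
    pre_samples = list(pretrain_spec.positives) + list(pretrain_spec.negatives)
    class_maps, n_classes = _build_fold_labels(
        pre_samples, replace(pre_cfg, nm_method="otsu"), 0
    )
    pre_model = build_double_unet(_fold_network_config(pre_cfg, n_classes, 0))
    train_model(pre_model, [s.image for s in pre_samples], class_maps, pre_cfg)
    state = pre_model.state_dict()
    if config.nm_method == "none":
        raise ExperimentConfigError(
            "transfer requires a three-class protocol (otsu or mining)"
        )
    return run_cv(finetune_spec, config, init_state=state)


def config_from_yaml(path) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML mapping.  Nested ``network`` and
    ``loss_config`` mappings populate NetworkConfig / LossConfig; list-valued
    fields are coerced to the tuple/frozenset types the dataclasses use."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "network" in raw:
        net = raw["network"]
        for key in ("input_shape", "encoder_widths", "aspp_rates"):
            if key in net:
                net[key] = tuple(net[key])
        raw["network"] = NetworkConfig(**net)
    if "loss_config" in raw:
        lc = raw["loss_config"]
        if "excluded_classes" in lc:
            lc["excluded_classes"] = frozenset(lc["excluded_classes"])
        raw["loss_config"] = LossConfig(**lc)
    for key in ("split_ratio",):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = ExperimentConfig(**raw)
    cfg.validate()
    return cfg


# -- glue --------------------------------------------------------------------

def dataset_from_phantoms(samples, cohort_tag: str = "") -> DatasetSpec:
    """Build a DatasetSpec from phantom samples, using each AP view and its
    lesion mask directly (no two-view preprocessing; phantom views at small
    shapes are already network-sized)."""
    positives = []
    negatives = []
    for i, ph in enumerate(samples):
        s = Sample(
            image=ph.ap_view.astype(np.float32),
            m_mask=ph.lesion_mask_ap.astype(bool),
            sample_id=f"{cohort_tag}-{i:03d}",
        )
        (positives if s.is_positive else negatives).append(s)
    return DatasetSpec(
        positives=tuple(positives), negatives=tuple(negatives), cohort_tag=cohort_tag
    )
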